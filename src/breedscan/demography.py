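"""Convert mutation-scaled coalescent estimates to interpretable units.

Sequence-based demographic samplers report population sizes, divergence
times and migration rates scaled by the per-site mutation rate:
theta = 4 * Ne * mu_gen, tau = T * mu_year (per-site, per-year), and a
migration rate expressed relative to mu. With a calibrated per-year
mutation rate mu_year and a generation time g the conversions are

    Ne      = theta / (4 * mu_year * g)
    T_years = tau / mu_year
    2Nm     = mig * theta_target / 2

The 2Nm convention (the sampler's mutation-scaled migration rate times the
receiving population's theta over two) is surfaced in output metadata
because different samplers differ here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MCMCTrace

#: Calibrated per-site per-year mutation rate for the dog lineage.
DEFAULT_MU_YEAR = 2.2e-9
#: Generation time in years.
DEFAULT_GEN_TIME = 3.0


@dataclass
class DemogEstimate:
    """Mutation-scaled inputs and their calendar/count conversions."""

    theta: float
    tau: float
    mig: float
    mu_year: float
    gen_time: float
    ne: float
    t_years: float
    two_nm: float
    migration_convention: str = "2Nm = mig * theta_target / 2"


def scale_estimates(theta: float, tau: float, mig: float = 0.0,
                    mu_year: float = DEFAULT_MU_YEAR,
                    gen_time: float = DEFAULT_GEN_TIME) -> DemogEstimate:
    """Scale (theta, tau, mig) into Ne individuals, years, and 2Nm."""
    if mu_year <= 0 or gen_time <= 0:
        raise ValueError("mutation rate and generation time must be positive")
    if theta < 0 or tau < 0 or mig < 0:
        raise ValueError("mutation-scaled parameters must be non-negative")
    return DemogEstimate(
        theta=theta, tau=tau, mig=mig, mu_year=mu_year, gen_time=gen_time,
        ne=theta / (4.0 * mu_year * gen_time),
        t_years=tau / mu_year,
        two_nm=mig * theta / 2.0,
    )


def unscale(est: DemogEstimate) -> tuple:
    """Inverse of :func:`scale_estimates`: recover (theta, tau, mig)."""
    theta = est.ne * 4.0 * est.mu_year * est.gen_time
    tau = est.t_years * est.mu_year
    mig = 2.0 * est.two_nm / theta if theta > 0 else 0.0
    return theta, tau, mig


def years_from_tau(tau, mu_year: float = DEFAULT_MU_YEAR):
    """Calendar years for a per-site mutation-scaled divergence time."""
    return np.asarray(tau, dtype=float) / mu_year


def ne_from_theta(theta, mu_year: float = DEFAULT_MU_YEAR,
                  gen_time: float = DEFAULT_GEN_TIME):
    """Effective number of diploid individuals for a mutation-scaled theta."""
    return np.asarray(theta, dtype=float) / (4.0 * mu_year * gen_time)


def two_nm(mig, theta_target):
    """Population-scaled migrants per generation, 2Nm = mig * theta / 2."""
    return np.asarray(mig, dtype=float) * np.asarray(theta_target, dtype=float) / 2.0


@dataclass
class TraceSummary:
    """Posterior summary of a pooled trace.

    ``summary``: per-parameter mean and central 95% interval (linear
    interpolation quantiles). ``replicate_means``: replicate x parameter
    means for a between-chain consistency check. ``divergent`` flags
    parameters whose between-replicate variance is large relative to the
    within-replicate variance (split-chain style R-hat > 1.1).
    """

    summary: pd.DataFrame
    replicate_means: pd.DataFrame
    divergent: dict


def summarize_trace(trace: MCMCTrace) -> TraceSummary:
    """Posterior mean, 2.5%/97.5% quantiles and replicate consistency.

    Raises when fewer than 10 pooled samples remain: no meaningful
    interval can be formed.
    """
    x = trace.samples
    if len(x) < 10:
        raise ValueError(f"only {len(x)} retained samples; need at least 10")
    qs = x.quantile([0.025, 0.975], interpolation="linear")
    summary = pd.DataFrame({
        "mean": x.mean(),
        "q2.5": qs.loc[0.025],
        "q97.5": qs.loc[0.975],
    })
    rep_means = x.groupby(trace.replicate).mean()
    rep_means.index.name = "replicate"
    divergent = {}
    for p in x.columns:
        divergent[p] = _rhat_flag(x[p].to_numpy(), trace.replicate)
    return TraceSummary(summary=summary, replicate_means=rep_means,
                        divergent=divergent)


def _rhat_flag(values: np.ndarray, replicate: np.ndarray,
               threshold: float = 1.1) -> bool:
    reps = np.unique(replicate)
    if len(reps) < 2:
        return False
    groups = [values[replicate == r] for r in reps]
    if any(len(g) < 2 for g in groups):
        return False
    n = min(len(g) for g in groups)
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return bool(B > 0)
    rhat = np.sqrt(((n - 1) / n * W + B / n) / W)
    return bool(rhat > threshold)
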