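"""From mutation-scaled MCMC traces to calendar years, Ne and 2Nm.

Generates five replicate synthetic trace files centered on a truth of
8,300-year and 31,700-year splits, pools them through the loader
(removing burn-in per replicate), and scales the posterior means with the
calibrated mutation rate (2.2e-9 per site per year) and a 3-year
generation time.
"""

import tempfile

import breedscan as bs

MU = 2.2e-9
theta_indig = 4 * 25_000 * MU * 3.0
truth = {
    "theta_indigenous": theta_indig,
    "tau_chow_split": 8_300 * MU,
    "tau_wolf_split": 31_700 * MU,
    "m_indigenous_chow": 2 * 0.5 / theta_indig,  # 2Nm = 0.5
}

with tempfile.TemporaryDirectory() as d:
    paths = bs.make_trace(truth, seed=5, n_iter=1_000_000, sample_every=10,
                          n_replicates=5, outdir=d)
    trace = bs.read_mcmc_trace(paths, burn_in=200_000, thinning=10)
    summ = bs.summarize_trace(trace)

mean = summ.summary["mean"]
print(summ.summary.to_string())
print(f"\nchow split:  {float(bs.years_from_tau(mean['tau_chow_split'])):8.0f} years")
print(f"wolf split:  {float(bs.years_from_tau(mean['tau_wolf_split'])):8.0f} years")
print(f"indigenous Ne: {float(bs.ne_from_theta(mean['theta_indigenous'])):8.0f}")
print(f"2Nm (indig<->chow): "
      f"{float(bs.two_nm(mean['m_indigenous_chow'], mean['theta_indigenous'])):.3f}")
print("\nPosterior means divided by the mutation rate give calendar years; "
      "theta/(4*mu*g) gives diploid effective sizes.")
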