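"""Windowed diversity, Weir-Cockerham F_ST, PBS, and LD decay statistics.

The windowed scans run on a :class:`~breedscan.intervals.WindowGrid`
(1 Mb / 200 kb for heterozygosity, 100 kb / 20 kb for F_ST / PBS by
convention in this package) and return tidy DataFrames with one row per
window. Windows without enough usable data are flagged undefined (NaN
value, ``defined == False``) rather than silently set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import WindowGrid
from .panel import GenotypePanel, allele_stats

#: F_ST upper clamp applied before the -log(1 - F_ST) branch-length transform.
FST_EPS = 1e-9


# ---------------------------------------------------------------------------
# Heterozygosity

def window_heterozygosity(panel: GenotypePanel, grid: WindowGrid,
                          min_depth: int = 0) -> pd.DataFrame:
    """Per-sample fraction of heterozygous genotypes in each window.

    A site contributes for a sample iff its genotype is called and, when
    ``min_depth > 0``, its read depth in that sample is >= min_depth (the
    rule used for restriction-site data, whose coverage is non-uniform).

    Returns a long-format DataFrame with columns chrom, start, end, sample,
    n_used, n_het, het; ``het`` is NaN for windows with no usable site.
    """
    if min_depth > 0 and panel.depth is None:
        raise ValueError("min_depth > 0 requires per-sample depth data")
    usable = panel.geno >= 0
    if min_depth > 0:
        usable &= panel.depth >= min_depth
    is_het = (panel.geno == 1) & usable

    rows = []
    for chrom, lo, hi in _window_site_ranges(panel, grid):
        win_usable = usable[lo:hi]
        win_het = is_het[lo:hi]
        n_used = win_usable.sum(axis=0)
        n_het = win_het.sum(axis=0)
        for j, sample in enumerate(panel.sample_ids):
            het = n_het[j] / n_used[j] if n_used[j] > 0 else np.nan
            rows.append((chrom[0], chrom[1], chrom[2], sample,
                         int(n_used[j]), int(n_het[j]), het))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample",
                                       "n_used", "n_het", "het"])


def _window_site_ranges(panel: GenotypePanel, grid: WindowGrid):
    """Yield ((chrom, start, end), lo, hi) site-index ranges per window."""
    windows = grid.windows()
    for chrom, sub in windows.groupby("chrom", sort=True):
        idx = panel.chrom_sites(chrom)
        pos = panel.pos[idx]
        base = idx[0] if len(idx) else 0
        for _, w in sub.iterrows():
            lo = base + np.searchsorted(pos, w["start"], side="left")
            hi = base + np.searchsorted(pos, w["end"], side="left")
            yield (chrom, int(w["start"]), int(w["end"])), int(lo), int(hi)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST

def wc_site_components(panel: GenotypePanel, idx_a: np.ndarray,
                       idx_b: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components for two populations.

    Returns (a, d, usable): the among-population component ``a``, the total
    ``d = a + b + c``, and a boolean mask of sites with >= 2 called diploids
    in each population. The windowed "weighted" estimate is
    ``sum(a) / sum(d)`` over the usable sites of a window.
    """
    r = 2.0
    n_a_, p_a, h_a = allele_stats(panel.geno, idx_a)
    n_b_, p_b, h_b = allele_stats(panel.geno, idx_b)
    usable = (n_a_ >= 2) & (n_b_ >= 2)
    nA = n_a_.astype(float)
    nB = n_b_.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * p_a + nB * p_b) / (r * nbar)
        s2 = (nA * (p_a - pbar) ** 2 + nB * (p_b - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * h_a + nB * h_b) / (r * nbar)
        inner = pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
        d = a + b + c
    a = np.where(usable, a, 0.0)
    d = np.where(usable, d, 0.0)
    return np.nan_to_num(a), np.nan_to_num(d), usable


def wc_fst_window(panel: GenotypePanel, pop_a: str, pop_b: str,
                  grid: WindowGrid, min_snps: int = 10) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST between two populations.

    The per-window estimate is the weighted ratio-of-sums of the 1984
    variance components over the SNPs in the window. Windows with fewer
    than ``min_snps`` usable SNPs (or a zero total-variance denominator)
    are flagged undefined.

    Returns a DataFrame with columns chrom, start, end, n_snps, fst_raw,
    fst (clamped to [0, 1 - 1e-9]) and defined.
    """
    idx_a = panel.sample_indices(pop_a)
    idx_b = panel.sample_indices(pop_b)
    a, d, usable = wc_site_components(panel, idx_a, idx_b)
    informative = usable & (d != 0)

    rows = []
    for (chrom, start, end), lo, hi in _window_site_ranges(panel, grid):
        n_snps = int(informative[lo:hi].sum())
        sum_a = a[lo:hi].sum()
        sum_d = d[lo:hi].sum()
        if n_snps >= min_snps and sum_d > 0:
            raw = sum_a / sum_d
            rows.append((chrom, start, end, n_snps, raw,
                         float(np.clip(raw, 0.0, 1.0 - FST_EPS)), True))
        else:
            rows.append((chrom, start, end, n_snps, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "fst_raw", "fst", "defined"])


def mean_fst(panel: GenotypePanel, pop_a: str, pop_b: str) -> float:
    """Genome-wide Weir-Cockerham F_ST (single ratio-of-sums over all sites)."""
    idx_a = panel.sample_indices(pop_a)
    idx_b = panel.sample_indices(pop_b)
    a, d, usable = wc_site_components(panel, idx_a, idx_b)
    denom = d[usable].sum()
    if denom == 0:
        return float("nan")
    return float(a[usable].sum() / denom)


# ---------------------------------------------------------------------------
# PBS

def pbs(fst_focal_sister, fst_focal_out, fst_sister_out, clamp: bool = True):
    """Population branch statistic for the focal population.

    PBS = (T_fs + T_fo - T_so) / 2 with T = -log(1 - F_ST) (natural log).
    Accepts scalars or arrays. With ``clamp=True`` each F_ST is clipped to
    [0, 1 - 1e-9] first; with ``clamp=False`` an F_ST >= 1 raises (infinite
    branch length).
    """
    f1 = np.asarray(fst_focal_sister, dtype=float)
    f2 = np.asarray(fst_focal_out, dtype=float)
    f3 = np.asarray(fst_sister_out, dtype=float)
    if clamp:
        f1, f2, f3 = (np.clip(f, 0.0, 1.0 - FST_EPS) for f in (f1, f2, f3))
    elif np.any(f1 >= 1) or np.any(f2 >= 1) or np.any(f3 >= 1):
        raise ValueError("F_ST >= 1 gives an infinite branch length")
    t1 = -np.log1p(-f1)
    t2 = -np.log1p(-f2)
    t3 = -np.log1p(-f3)
    out = (t1 + t2 - t3) / 2.0
    return float(out) if out.ndim == 0 else out


def pbs_scan(panel: GenotypePanel, focal: str, sister: str, outgroup: str,
             grid: WindowGrid, min_snps: int = 10) -> pd.DataFrame:
    """Windowed PBS scan for the focal population.

    Computes the three pairwise windowed F_ST tracks and combines them with
    :func:`pbs`. A window is undefined whenever any pairwise F_ST there is.

    Returns a DataFrame with chrom, start, end, n_snps (min over the three
    pairs), t_focal_sister, t_focal_out, t_sister_out, pbs and defined.
    """
    for pop in (focal, sister, outgroup):
        if len(panel.sample_indices(pop)) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
    fs = wc_fst_window(panel, focal, sister, grid, min_snps)
    fo = wc_fst_window(panel, focal, outgroup, grid, min_snps)
    so = wc_fst_window(panel, sister, outgroup, grid, min_snps)

    defined = fs["defined"] & fo["defined"] & so["defined"]
    t_fs = -np.log1p(-fs["fst"].to_numpy())
    t_fo = -np.log1p(-fo["fst"].to_numpy())
    t_so = -np.log1p(-so["fst"].to_numpy())
    vals = (t_fs + t_fo - t_so) / 2.0
    out = fs[["chrom", "start", "end"]].copy()
    out["n_snps"] = np.minimum.reduce([fs["n_snps"], fo["n_snps"], so["n_snps"]])
    out["t_focal_sister"] = np.where(defined, t_fs, np.nan)
    out["t_focal_out"] = np.where(defined, t_fo, np.nan)
    out["t_sister_out"] = np.where(defined, t_so, np.nan)
    out["pbs"] = np.where(defined, vals, np.nan)
    out["defined"] = defined
    return out


# ---------------------------------------------------------------------------
# Linkage disequilibrium

def pairwise_r2(panel: GenotypePanel, max_dist: int = 500_000,
                samples=None) -> pd.DataFrame:
    """Genotype-correlation r^2 for all same-chromosome SNP pairs within range.

    Uses the phase-free composite (Rogers-Huff) estimator: the squared
    Pearson correlation of alt-dosage vectors over the samples non-missing
    at both sites. Pairs where either site is monomorphic in the used
    sample set are skipped (r^2 undefined there).

    Returns a DataFrame with columns chrom, pos_i, pos_j, dist, r2 for
    0 < dist <= max_dist.
    """
    if samples is None:
        cols = np.arange(panel.n_samples)
    elif isinstance(samples, str):
        cols = panel.sample_indices(samples)
    else:
        cols = np.array([panel.sample_ids.index(s) for s in samples])
    g = panel.geno[:, cols].astype(float)
    g[g < 0] = np.nan

    chroms, pis, pjs, dists, r2s = [], [], [], [], []
    for chrom in np.unique(panel.chrom.astype(str)):
        idx = panel.chrom_sites(chrom)
        pos = panel.pos[idx]
        G = g[idx]
        for k in range(len(idx)):
            hi = np.searchsorted(pos, pos[k] + max_dist, side="right")
            js = np.arange(k + 1, hi)
            js = js[pos[js] > pos[k]]  # distance must be > 0
            if not len(js):
                continue
            x = G[k]
            Y = G[js]
            mask = ~np.isnan(x) & ~np.isnan(Y)
            n = mask.sum(axis=1)
            xm = np.where(mask, x, 0.0)
            ym = np.where(mask, Y, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sx = xm.sum(axis=1)
                sy = ym.sum(axis=1)
                sxx = (xm * xm).sum(axis=1)
                syy = (ym * ym).sum(axis=1)
                sxy = (xm * ym).sum(axis=1)
                cov = sxy - sx * sy / n
                vx = sxx - sx * sx / n
                vy = syy - sy * sy / n
                r2 = cov * cov / (vx * vy)
            ok = (n >= 2) & (vx > 0) & (vy > 0)
            chroms.extend([chrom] * int(ok.sum()))
            pis.extend(np.repeat(pos[k], ok.sum()))
            pjs.extend(pos[js[ok]])
            dists.extend(pos[js[ok]] - pos[k])
            r2s.extend(r2[ok])
    return pd.DataFrame({"chrom": chroms, "pos_i": pis, "pos_j": pjs,
                         "dist": np.array(dists, dtype=np.int64),
                         "r2": np.array(r2s, dtype=float)})


@dataclass
class LDProfile:
    """Mean r^2 per distance bin plus the scalar H statistic.

    ``bins`` has columns bin (1-based), lo, hi, mean_r2, n_pairs; bin k
    covers distances ((k-1)*bin_width, k*bin_width]. ``H`` is the sum of
    per-bin means — an area-under-the-curve analog of overall LD — with
    empty bins contributing 0 (they stay NaN in ``bins``).
    """

    bins: pd.DataFrame
    bin_width: int
    max_dist: int
    H: float

    @property
    def n_bins(self) -> int:
        return self.max_dist // self.bin_width


def ld_profile(pairs: pd.DataFrame, bin_width: int = 5_000,
               max_dist: int = 500_000) -> LDProfile:
    """Bin r^2 values by pair distance and summarize with the H statistic.

    With the defaults this yields 500 kb / 5 kb = 100 bins; H ranges from 0
    (no LD anywhere) to n_bins (perfect LD in every bin).
    """
    if max_dist % bin_width != 0:
        raise ValueError("bin_width must divide max_dist")
    n_bins = max_dist // bin_width
    d = pairs["dist"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    keep = (d > 0) & (d <= max_dist)
    # bin k (1-based) covers ((k-1)*bw, k*bw]: a pair at exactly 5 kb is bin 1
    bin_idx = np.ceil(d[keep] / bin_width).astype(int) - 1
    sums = np.bincount(bin_idx, weights=r2[keep], minlength=n_bins)
    counts = np.bincount(bin_idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "lo": np.arange(n_bins) * bin_width,
        "hi": np.arange(1, n_bins + 1) * bin_width,
        "mean_r2": means,
        "n_pairs": counts,
    })
    return LDProfile(bins=bins, bin_width=bin_width, max_dist=max_dist,
                     H=float(np.nansum(means)))
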