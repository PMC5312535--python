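import numpy as np
import pytest

from breedscan import MISSING, GenotypePanel


def build_panel(geno, pops, pos=None, chrom="chr1", depth=None):
    """Construct a small panel from a sites x samples dosage matrix."""
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    sample_ids = [f"s{i}" for i in range(n_samples)]
    if pos is None:
        pos = np.arange(n_sites) * 10 + 100
    chroms = np.full(n_sites, chrom, dtype=object) if isinstance(chrom, str) \
        else np.asarray(chrom, dtype=object)
    return GenotypePanel(
        sample_ids=sample_ids,
        pop_labels=dict(zip(sample_ids, pops)),
        chrom=chroms,
        pos=np.asarray(pos),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        geno=geno,
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture
def panel_factory():
    return build_panel


# ---------------------------------------------------------------------------
# Independent oracles (plain-formula / brute-force implementations kept
# deliberately separate from the package's vectorized code paths).

def wc_fst_oracle_single_snp(dosages_a, dosages_b):
    """Weir-Cockerham (1984) single-SNP estimator, scalar arithmetic.

    Returns (a, d) — the among-population component and the total a+b+c —
    so callers can form either the single-SNP ratio or a ratio of sums.
    Missing dosages (< 0) must be removed by the caller.
    """
    r = 2.0
    n = [float(len(dosages_a)), float(len(dosages_b))]
    p = [sum(dosages_a) / (2 * n[0]), sum(dosages_b) / (2 * n[1])]
    h = [sum(1 for g in dosages_a if g == 1) / n[0],
         sum(1 for g in dosages_b if g == 1) / n[1]]
    nbar = (n[0] + n[1]) / r
    nc = (r * nbar - (n[0] ** 2 + n[1] ** 2) / (r * nbar)) / (r - 1)
    pbar = (n[0] * p[0] + n[1] * p[1]) / (r * nbar)
    s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n[0] * h[0] + n[1] * h[1]) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, a + b + c


def interval_bp_set(iv):
    """Brute-force base-pair set of an interval collection."""
    return {(c, p) for c, s, e in iv.intervals() for p in range(s, e)}
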