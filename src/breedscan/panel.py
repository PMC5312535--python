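"""The shared genotype container used by every statistic in the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing diploid genotype.
MISSING: int = -1


@dataclass
class GenotypePanel:
    """Sample x site diploid genotype matrix with population labels.

    Genotypes are stored as alt-allele dosages in {0, 1, 2} with
    :data:`MISSING` (-1) for uncalled cells. Sites are biallelic SNPs only
    and sorted by (chrom, pos); positions are 0-based (VCF input is
    converted at the reader).

    Attributes
    ----------
    sample_ids : list of str
    pop_labels : dict mapping sample id -> population name
    chrom : (n_sites,) array of chromosome names
    pos : (n_sites,) int array, 0-based
    ref, alt : (n_sites,) arrays of alleles
    geno : (n_sites, n_samples) int8 array of dosages
    depth : optional (n_sites, n_samples) int array of per-sample read depth
    """

    sample_ids: list
    pop_labels: dict
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.pos), len(self.sample_ids)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.pos)} sites x {len(self.sample_ids)} samples")
        valid = np.isin(self.geno, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype dosages must be in {0, 1, 2, MISSING}")
        missing_labels = [s for s in self.sample_ids if s not in self.pop_labels]
        if missing_labels:
            raise ValueError(f"samples without a population label: {missing_labels}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.geno.shape:
                raise ValueError("depth must have the same shape as geno")
        # enforce (chrom, pos) sort order
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self._reorder(order)

    def _reorder(self, order: np.ndarray) -> None:
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.ref = self.ref[order]
        self.alt = self.alt[order]
        self.geno = self.geno[order]
        if self.depth is not None:
            self.depth = self.depth[order]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def populations(self) -> list:
        return sorted(set(self.pop_labels.values()))

    def sample_indices(self, pop: str) -> np.ndarray:
        """Column indices of the samples belonging to population ``pop``."""
        idx = np.array([i for i, s in enumerate(self.sample_ids)
                        if self.pop_labels[s] == pop], dtype=np.int64)
        if len(idx) == 0:
            raise KeyError(f"no samples with population label {pop!r}")
        return idx

    def chrom_sites(self, chrom: str) -> np.ndarray:
        """Row indices of all sites on ``chrom`` (contiguous, sorted)."""
        return np.flatnonzero(self.chrom == chrom)

    def subset_sites(self, mask_or_idx) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            pop_labels=dict(self.pop_labels),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            geno=self.geno[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    def copy(self) -> "GenotypePanel":
        return self.subset_sites(np.arange(self.n_sites))

    def chrom_lengths(self, pad: int = 1) -> dict:
        """Approximate chromosome lengths from the largest site position."""
        out = {}
        for chrom in np.unique(self.chrom.astype(str)):
            sel = self.chrom == chrom
            out[chrom] = int(self.pos[sel].max()) + pad
        return out


def allele_stats(geno: np.ndarray, sample_idx: np.ndarray):
    """Per-site called-diploid count, alt-allele frequency and het frequency.

    Returns (n_called, p_alt, h_obs); p_alt and h_obs are NaN where no
    genotype is called.
    """
    g = geno[:, sample_idx]
    called = g >= 0
    n = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    het = ((g == 1) & called).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h
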