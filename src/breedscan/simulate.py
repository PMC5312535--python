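"""Synthetic inputs with the statistical structure the pipeline assumes.

The central generator is a three-population coalescent model of a breed
origin: an ancestral canid population from which wolves and the ancestral
dog population diverge (default 31,700 years ago), a later split of a
focal breed (chow) from its source indigenous-dog population (default
8,300 years ago), a small ancestral dog population with rapid expansion of
the indigenous lineage after the breed split, a mild bottleneck on the
breed branch, and low symmetric migration (2Nm <= 1) among contemporary
populations. Selection is emulated by a deterministic frequency transform
on neutral output rather than a forward simulation — sufficient to
exercise the PBS scan and intersection machinery, and documented as such.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .panel import MISSING, GenotypePanel
from .radseq import DigestConfig

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Coalescent panel

@dataclass
class SweepConfig:
    """A planted selective sweep: position, proxy strength and target population."""

    position: int
    target: str = "chow"
    chrom: str | None = None
    strength: float = 0.95
    radius: int = 100_000


@dataclass
class SimConfig:
    """Three-population demographic model and sampling design.

    Split times are in years and converted to generations with
    ``gen_time``; the wolf split must not predate the chow split.
    Population sizes are diploid effective sizes per epoch; migration is
    expressed in 2Nm units (migrants per generation into each recipient)
    and applied symmetrically among the three contemporary populations.
    """

    seed: int = 0
    n_wolf: int = 10
    n_indigenous: int = 15
    n_chow: int = 10
    wolf_split_years: float = 31_700.0
    chow_split_years: float = 8_300.0
    ne_root: float = 25_000.0
    ne_wolf: float = 20_000.0
    ne_dog_ancestral: float = 5_000.0
    ne_indigenous: float = 25_000.0
    ne_chow: float = 3_000.0
    migration_2nm: float = 0.5
    mu_year: float = 2.2e-9
    gen_time: float = 3.0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    recomb_rate: float = 1e-8
    sweep: SweepConfig | None = None

    def __post_init__(self) -> None:
        if self.wolf_split_years < self.chow_split_years:
            raise ValueError("wolf split must be at least as old as the chow split")
        if min(self.ne_root, self.ne_wolf, self.ne_dog_ancestral,
               self.ne_indigenous, self.ne_chow) <= 0:
            raise ValueError("population sizes must be positive")
        if self.migration_2nm < 0:
            raise ValueError("migration must be non-negative")

    @property
    def mu_gen(self) -> float:
        return self.mu_year * self.gen_time


def _demography(cfg: SimConfig):
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="wolf", initial_size=cfg.ne_wolf)
    dem.add_population(name="indigenous", initial_size=cfg.ne_indigenous)
    dem.add_population(name="chow", initial_size=cfg.ne_chow)
    dem.add_population(name="dog_anc", initial_size=cfg.ne_dog_ancestral)
    dem.add_population(name="root", initial_size=cfg.ne_root)
    if cfg.migration_2nm > 0:
        sizes = {"wolf": cfg.ne_wolf, "indigenous": cfg.ne_indigenous,
                 "chow": cfg.ne_chow}
        for recv, n_recv in sizes.items():
            for src in sizes:
                if src != recv:
                    dem.set_migration_rate(recv, src,
                                           cfg.migration_2nm / (2.0 * n_recv))
    # a split at time 0 would deactivate the sampled populations; an
    # epsilon-generation split is equivalent to panmixia for all statistics
    eps = 1e-6
    t_chow = max(cfg.chow_split_years / cfg.gen_time, eps)
    t_wolf = max(cfg.wolf_split_years / cfg.gen_time, t_chow + eps)
    dem.add_population_split(time=t_chow, derived=["indigenous", "chow"],
                             ancestral="dog_anc")
    dem.add_population_split(time=t_wolf, derived=["dog_anc", "wolf"],
                             ancestral="root")
    dem.sort_events()
    return dem


def simulate_panel(cfg: SimConfig) -> GenotypePanel:
    """Coalescent-simulated biallelic SNP panel under the three-population model.

    Chromosomes are simulated independently (named chr1..chrN) and sites
    with more than two alleles are dropped. Deterministic under
    ``cfg.seed``; if ``cfg.sweep`` is set, the sweep transform is applied
    to the neutral output with a seed derived from the same stream.
    """
    import msprime

    if min(cfg.n_wolf, cfg.n_indigenous, cfg.n_chow) <= 0:
        raise ValueError("every population needs at least one sample")
    dem = _demography(cfg)
    samples = [
        msprime.SampleSet(cfg.n_wolf, population="wolf", ploidy=2),
        msprime.SampleSet(cfg.n_indigenous, population="indigenous", ploidy=2),
        msprime.SampleSet(cfg.n_chow, population="chow", ploidy=2),
    ]
    n_ind = cfg.n_wolf + cfg.n_indigenous + cfg.n_chow
    sample_ids = ([f"wolf_{i}" for i in range(cfg.n_wolf)]
                  + [f"indigenous_{i}" for i in range(cfg.n_indigenous)]
                  + [f"chow_{i}" for i in range(cfg.n_chow)])
    pop_labels = {s: s.rsplit("_", 1)[0] for s in sample_ids}

    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_chrom + 1)
    seeds = seeds % (2**31 - 2) + 1
    chroms, poss, refs, alts, genos = [], [], [], [], []
    for c in range(cfg.n_chrom):
        ts = msprime.sim_ancestry(
            samples=samples, demography=dem,
            sequence_length=cfg.chrom_length,
            recombination_rate=cfg.recomb_rate,
            random_seed=int(seeds[2 * c]))
        mts = msprime.sim_mutations(ts, rate=cfg.mu_gen,
                                    random_seed=int(seeds[2 * c + 1]))
        name = f"chr{c + 1}"
        for var in mts.variants():
            if len(var.alleles) != 2:
                continue
            g = var.genotypes  # haploid calls, individuals contiguous
            dosage = g[0::2] + g[1::2]
            chroms.append(name)
            poss.append(int(var.site.position))
            refs.append(var.alleles[0])
            alts.append(var.alleles[1])
            genos.append(dosage.astype(np.int8))
    panel = GenotypePanel(
        sample_ids=sample_ids, pop_labels=pop_labels,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        geno=(np.array(genos, dtype=np.int8).reshape(len(poss), n_ind)
              if poss else np.empty((0, n_ind), dtype=np.int8)),
    )
    if cfg.sweep is not None:
        panel = plant_sweep(panel, cfg.sweep, seed=int(seeds[-1]))
    return panel


def plant_sweep(panel: GenotypePanel, sweep: SweepConfig,
                seed: int = 0) -> GenotypePanel:
    """Drive target-population allele frequencies toward fixation near a locus.

    Within ``radius`` of the sweep position, each target individual's
    genotype is replaced by the homozygote of the locally major allele with
    probability ``strength`` (full strength on a core plateau of
    radius/5 around the center, exponentially decaying outside it). Other
    populations are untouched; the transform is deterministic under seed.
    """
    chrom = sweep.chrom or str(panel.chrom[0])
    on_chrom = panel.chrom_sites(chrom)
    pos = panel.pos[on_chrom]
    lo = sweep.position - sweep.radius
    hi = sweep.position + sweep.radius
    if sweep.position < 0 or sweep.position > pos.max() + sweep.radius:
        raise ValueError("sweep position outside the simulated sequence")
    out = panel.copy()
    if sweep.strength <= 0:
        return out
    rng = np.random.default_rng(seed)
    target = out.sample_indices(sweep.target)
    # broad full-strength plateau with a fast tail: hitchhiking affects
    # the whole swept region, not just the beneficial site
    core = sweep.radius / 2.0
    decay = sweep.radius / 6.0
    sel = on_chrom[(pos >= lo) & (pos <= hi)]
    for i in sel:
        dist = abs(int(out.pos[i]) - sweep.position)
        intensity = (sweep.strength if dist <= core
                     else sweep.strength * np.exp(-(dist - core) / decay))
        g = out.geno[i, target]
        called = g >= 0
        if not called.any():
            continue
        # swept allele: drawn proportional to its target-population
        # frequency, emulating fixation of one hitchhiking haplotype
        # (an allele at intermediate frequency elsewhere can be swept,
        # which is what makes the branch-specific signal)
        freq = g[called].sum() / (2.0 * called.sum())
        hom = 2 if rng.random() < freq else 0
        flip = rng.random(len(target)) < intensity
        g = np.where(flip & called, hom, g)
        out.geno[i, target] = g
    return out


# ---------------------------------------------------------------------------
# Toy genomes for the locus cascade

@dataclass
class ToyGenome:
    """A generated reference with planted cut sites and annotation tracks.

    ``expected`` is the ground-truth terminal status of every planted
    locus, computed by an independent brute-force predicate evaluator at
    generation time (no depth/coverage dimension; see make_depth_table).
    """

    seqs: dict
    tracks: dict
    cut_sites: list
    expected: pd.DataFrame
    cfg: DigestConfig

    def write(self, outdir) -> dict:
        """Write FASTA + per-track BED files; returns the paths."""
        from .io import write_intervals
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "toy_genome.fa"
        with open(fasta, "w") as fh:
            for name in sorted(self.seqs):
                fh.write(f">{name}\n")
                seq = self.seqs[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths = {"fasta": fasta}
        for name, iv in self.tracks.items():
            p = outdir / f"{name}.bed"
            write_intervals(iv, p)
            paths[name] = p
        return paths


_DEFAULT_TRACK_COUNTS = {"cpg": 3, "repeat": 4, "gap": 2, "exon": 3, "cne": 3}


def make_toy_genome(seed: int, n_chrom: int = 1, length: int = 200_000,
                    n_sites: int = 20, tracks_spec: dict | None = None,
                    cfg: DigestConfig = DigestConfig(),
                    n_runs: int = 1) -> ToyGenome:
    """Random toy reference with planted cut sites, tracks and ground truth.

    Spurious motif occurrences are destroyed by single-base edits so the
    digest finds exactly the planted sites. ``tracks_spec`` maps a track
    name to either a count of random intervals or an explicit list of
    (chrom, start, end); ``n_runs`` N-runs of 50 bp are written into each
    chromosome sequence (loci touching them are edge-rejected).
    """
    rng = np.random.default_rng(seed)
    if tracks_spec is None:
        tracks_spec = dict(_DEFAULT_TRACK_COUNTS)
    m = len(cfg.motif)
    footprint = 2 * cfg.flank + m
    if n_sites * footprint * 3 > length * n_chrom:
        raise ValueError("cannot pack that many loci into the genome")

    seqs = {}
    sites = []
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    per_chrom = _split_counts(rng, n_sites, n_chrom)
    for name, k in zip(chrom_names, per_chrom):
        arr = rng.choice(4, size=length)
        seq = list("".join(_BASES[arr]))
        # N runs (possible edge rejections)
        for _ in range(n_runs):
            s = int(rng.integers(0, length - 50))
            seq[s:s + 50] = "N" * 50
        planted = _plant_positions(rng, k, length, m)
        for p in planted:
            seq[p:p + m] = cfg.motif
            sites.append((name, int(p)))
        seq = _destroy_spurious("".join(seq), cfg.motif, planted, rng)
        seqs[name] = seq

    tracks = {}
    for tname, spec in tracks_spec.items():
        if isinstance(spec, int):
            recs = []
            for _ in range(spec * n_chrom):
                chrom = chrom_names[int(rng.integers(0, n_chrom))]
                w = int(rng.integers(100, 2000))
                s = int(rng.integers(0, length - w))
                recs.append((chrom, s, s + w))
            tracks[tname] = IntervalSet.from_records(tname, recs).merged()
        else:
            tracks[tname] = IntervalSet.from_records(tname, spec).merged()

    expected = _brute_force_expected(seqs, sorted(sites), tracks, cfg)
    return ToyGenome(seqs=seqs, tracks=tracks, cut_sites=sorted(sites),
                     expected=expected, cfg=cfg)


def _split_counts(rng, total, parts):
    counts = [total // parts] * parts
    for i in range(total % parts):
        counts[i] += 1
    return counts


def _plant_positions(rng, k, length, m):
    positions = []
    tries = 0
    while len(positions) < k and tries < 10_000:
        p = int(rng.integers(10, length - m - 10))
        if all(abs(p - q) >= 50 for q in positions):
            positions.append(p)
        tries += 1
    if len(positions) < k:
        raise ValueError("infeasible packing of cut sites")
    return sorted(positions)


def _destroy_spurious(seq: str, motif: str, planted, rng) -> str:
    """Edit single bases so the only motif occurrences are the planted ones."""
    m = len(motif)
    protected = set()
    for p in planted:
        protected.update(range(p, p + m))
    chars = list(seq)
    for _ in range(1000):
        hits = []
        s = "".join(chars)
        start = s.find(motif)
        while start != -1:
            if start not in planted:
                hits.append(start)
            start = s.find(motif, start + 1)
        if not hits:
            return "".join(chars)
        for h in hits:
            editable = [i for i in range(h, h + m) if i not in protected]
            i = editable[len(editable) // 2]
            old = chars[i]
            chars[i] = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "N"}[old]
    raise RuntimeError("could not destroy spurious motif occurrences")


def _brute_force_expected(seqs, sites, tracks, cfg: DigestConfig) -> pd.DataFrame:
    """Independent plain-loop evaluation of every cascade predicate."""
    m = len(cfg.motif)
    rows = []
    statuses = {}
    for chrom, pos in sites:
        seq = seqs[chrom]
        s, e = pos - cfg.flank, pos + m + cfg.flank
        ts_, te_ = s + cfg.trim, e - cfg.trim
        status = None
        if s < 0 or e > len(seq) or "N" in seq[s:e].upper():
            status = "edge"
        if status is None:
            for name in ("cpg", "repeat", "gap"):
                if name in tracks and any(
                        c == chrom and st < te_ and en > ts_
                        for c, st, en in tracks[name].intervals()):
                    status = name
                    break
        if status is None and "exon" in tracks:
            gaps = [max(0, st - te_, ts_ - en)
                    for c, st, en in tracks["exon"].intervals() if c == chrom]
            if gaps and min(gaps) < cfg.exon_dist:
                status = "exon"
        if status is None and "cne" in tracks:
            gaps = [max(0, st - te_, ts_ - en)
                    for c, st, en in tracks["cne"].intervals() if c == chrom]
            if gaps and min(gaps) <= cfg.cne_dist:
                status = "cne"
        statuses[(chrom, pos)] = status
    # greedy spacing walk over surviving loci, per chromosome, left to right
    last = {}
    for chrom, pos in sites:
        if statuses[(chrom, pos)] is not None:
            continue
        prev = last.get(chrom)
        if prev is not None and pos - prev < cfg.spacing:
            statuses[(chrom, pos)] = "spacing"
        else:
            last[chrom] = pos
    for chrom, pos in sites:
        r = statuses[(chrom, pos)]
        rows.append((chrom, pos, "pass" if r is None else "rejected", r or ""))
    return pd.DataFrame(rows, columns=["chrom", "cut_site", "status", "reason"])


# ---------------------------------------------------------------------------
# Depth tables

def make_depth_table(loci, samples, seed: int, mean_depth: float = 36.0,
                     dropout: float = 0.0, dispersion: float = 100.0,
                     cfg: DigestConfig = DigestConfig()) -> pd.DataFrame:
    """Per-sample per-base depth over the flank footprints of the given loci.

    Depths are negative-binomial (gamma-Poisson) with the given mean and
    dispersion (variance = mean + mean^2/dispersion; the default emulates a
    deeply but non-uniformly covered restriction site at ~36x). With
    probability ``dropout``, a (locus, sample) pair is dropped entirely
    (depth 0 across its footprint). Deterministic under seed.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must be in [0, 1]")
    from scipy import stats

    rng = np.random.default_rng(seed)
    m = len(cfg.motif)
    p = dispersion / (dispersion + mean_depth)
    table = {}
    for locus in loci:
        chrom = locus.chrom
        cut = locus.cut_site
        footprint = np.concatenate([
            np.arange(cut - cfg.flank, cut),
            np.arange(cut + m, cut + m + cfg.flank),
        ])
        footprint = footprint[footprint >= 0]
        depths = stats.nbinom.rvs(dispersion, p,
                                  size=(len(footprint), len(samples)),
                                  random_state=rng)
        drop = rng.random(len(samples)) < dropout
        depths[:, drop] = 0
        for row, pos in enumerate(footprint):
            table[(chrom, int(pos))] = depths[row]
    keys = sorted(table)
    df = pd.DataFrame({"chrom": [k[0] for k in keys],
                       "pos": [k[1] for k in keys]})
    mat = np.array([table[k] for k in keys]).reshape(len(keys), len(samples))
    for j, s in enumerate(samples):
        df[s] = mat[:, j]
    return df


# ---------------------------------------------------------------------------
# Synthetic MCMC traces

def make_trace(truth: dict, seed: int, n_iter: int = 5_200_000,
               sample_every: int = 10, n_replicates: int = 5,
               noise: float = 0.05, phi: float = 0.9,
               outdir=None):
    """Autocorrelated (AR(1)) trace files centered on the truth values.

    Each replicate file has a leading ``Sample`` iteration column and one
    column per parameter; rows are pre-thinned every ``sample_every``
    iterations (the on-disk dialect the loader expects by default).
    ``noise`` is the stationary relative standard deviation; with
    ``noise=0`` every sample equals the truth. Returns DataFrames, or file
    paths when ``outdir`` is given.
    """
    rng = np.random.default_rng(seed)
    n_rows = n_iter // sample_every
    out = []
    for r in range(n_replicates):
        data = {"Sample": np.arange(n_rows) * sample_every}
        for name, value in truth.items():
            sigma = noise * value
            if sigma == 0:
                data[name] = np.full(n_rows, float(value))
            else:
                from scipy.signal import lfilter

                z = rng.standard_normal(n_rows) * sigma * np.sqrt(1 - phi**2)
                e = lfilter([1.0], [1.0, -phi], z)  # AR(1) from zero state
                data[name] = value + e
        df = pd.DataFrame(data)
        if outdir is not None:
            path = Path(outdir) / f"trace_rep{r + 1}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
            out.append(path)
        else:
            out.append(df)
    return out
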