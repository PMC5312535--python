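"""Readers and writers for the formats the pipeline touches.

VCF is read with cyvcf2 and written as plain VCF 4.2 text; BED/GFF3 and the
tab-delimited score/trace tables go through pandas. All coordinates are
normalized to the package's internal 0-based half-open convention at this
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .panel import MISSING, GenotypePanel

log = logging.getLogger(__name__)

_ITERATION_COLS = {"sample", "iter", "iteration", "state", "gen"}


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path, pop_map: dict, on_unlabeled: str = "error") -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    Multi-allelic and non-SNP records are dropped (counts logged), genotypes
    become alt dosages with ``./.`` mapped to MISSING, and per-sample DP is
    kept as the depth matrix when present at every retained site.

    Parameters
    ----------
    path : str or Path
    pop_map : dict
        sample id -> population label. Must cover every retained sample.
    on_unlabeled : {"error", "drop"}
        What to do with VCF samples absent from ``pop_map``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unlabeled = [s for s in samples if s not in pop_map]
    if unlabeled and on_unlabeled == "error":
        raise KeyError(f"samples missing from pop_map: {unlabeled}")
    keep_cols = np.array([i for i, s in enumerate(samples) if s not in unlabeled])
    kept_samples = [samples[i] for i in keep_cols]
    if not kept_samples:
        raise ValueError("no samples remain after applying pop_map")

    chroms, poss, refs, alts, genos, depths = [], [], [], [], [], []
    n_multi = n_nonsnp = 0
    has_depth = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or rec.ALT[0] not in "ACGT":
            n_nonsnp += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = rec.gt_types[keep_cols].astype(np.int8)
        g[g == 3] = MISSING
        genos.append(g)
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)  # to 0-based
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            has_depth = False
        elif has_depth:
            d = dp[keep_cols, 0].astype(np.int64)
            depths.append(np.where(d < 0, 0, d))
    if n_multi or n_nonsnp:
        log.info("read_vcf(%s): dropped %d multi-allelic and %d non-SNP records",
                 path, n_multi, n_nonsnp)
    panel = GenotypePanel(
        sample_ids=kept_samples,
        pop_labels={s: pop_map[s] for s in kept_samples},
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        geno=np.array(genos, dtype=np.int8).reshape(len(poss), len(kept_samples)),
        depth=(np.array(depths) if (has_depth and len(depths) == len(poss) and depths)
               else None),
    )
    panel.n_dropped_multiallelic = n_multi
    panel.n_dropped_nonsnp = n_nonsnp
    return panel


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as minimal VCF 4.2 (GT and, when present, DP)."""
    has_dp = panel.depth is not None
    fmt = "GT:DP" if has_dp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom, length in sorted(panel.chrom_lengths().items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for i in range(panel.n_sites):
            cells = []
            for j in range(panel.n_samples):
                gt = _GT_STR[int(panel.geno[i, j])]
                if has_dp:
                    gt += f":{int(panel.depth[i, j])}"
                cells.append(gt)
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i] + 1}\t.\t{panel.ref[i]}\t"
                     f"{panel.alt[i]}\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Interval tracks

def read_intervals(path, format: str, name: str, feature: str | None = None,
                   merge: bool = True) -> IntervalSet:
    """Read a BED (0-based half-open) or GFF3 (1-based inclusive) track.

    Coordinates are normalized to 0-based half-open; overlapping intervals
    are merged within the track unless ``merge=False`` (id-carrying tracks
    such as gene annotations should not be merged).

    Parameters
    ----------
    format : {"bed", "gff3"}
    feature : str, optional
        For GFF3, keep only rows whose type column equals this value.
    """
    fmt = format.lower()
    if fmt == "bed":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "id"],
                         dtype={0: str}, engine="python",
                         on_bad_lines="error") if _bed_has_name(path) else \
             pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={0: str}, engine="python")
    elif fmt == "gff3":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                          names=["chrom", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attrs"],
                          dtype={"chrom": str})
        if feature is not None:
            raw = raw[raw["type"] == feature]
        df = pd.DataFrame({
            "chrom": raw["chrom"],
            "start": raw["start"].astype(np.int64) - 1,  # 1-based inclusive -> 0-based half-open
            "end": raw["end"].astype(np.int64),
            "id": raw["attrs"].map(_gff3_id),
        })
    else:
        raise ValueError(f"unknown interval format {format!r} (use 'bed' or 'gff3')")
    iv = IntervalSet(name, df)
    return iv.merged() if merge else iv


def _bed_has_name(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.split()) >= 4
    return False


def _gff3_id(attrs) -> str | None:
    if not isinstance(attrs, str):
        return None
    for part in attrs.split(";"):
        if part.startswith("ID="):
            return part[3:]
        if part.startswith("Name="):
            return part[5:]
    return None


def write_intervals(iv: IntervalSet, path) -> None:
    """Write an IntervalSet as BED3 (or BED4 when ids are present)."""
    cols = ["chrom", "start", "end"] + (["id"] if "id" in iv.df.columns else [])
    iv.df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Score tracks (e.g. output of a composite-likelihood sweep scan)

@dataclass
class ScoreTrack:
    """Positional or windowed scores (PBS, CLR, ...), sorted by coordinate.

    ``df`` has columns chrom, start, end, score; a positional track uses
    1-bp intervals [pos, pos+1).
    """

    df: pd.DataFrame
    kind: str = "custom"

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if not np.isfinite(df["score"]).all():
            raise ValueError("scores must be finite")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


_POS_ALIASES = ("position", "location", "pos")
_SCORE_ALIASES = ("likelihood-ratio", "likelihood_ratio", "lr", "clr", "score")


def read_score_track(path, kind: str = "clr", chrom: str = "chr1") -> ScoreTrack:
    """Read a tab-delimited per-position score table.

    Expects a header with a position column and a likelihood-ratio column
    (the dialect emitted by per-position sweep scanners); extra columns are
    ignored. Rows are sorted by position, with a warning when the input was
    unsorted.

    Parameters
    ----------
    chrom : str
        Chromosome label to attach (these files are typically per-chromosome
        and carry no chromosome column of their own).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().strip(): c for c in df.columns}
    pos_col = next((cols[a] for a in _POS_ALIASES if a in cols), None)
    score_col = next((cols[a] for a in _SCORE_ALIASES if a in cols), None)
    if pos_col is None or score_col is None:
        raise ValueError(f"could not find position/likelihood-ratio columns in {list(df.columns)}")
    pos = pd.to_numeric(df[pos_col], errors="raise").astype(np.int64)
    score = pd.to_numeric(df[score_col], errors="raise").astype(float)
    if not pos.is_monotonic_increasing:
        log.warning("read_score_track(%s): positions unsorted; sorting", path)
    chrom_col = cols.get("chrom") or cols.get("chromosome")
    chrom_vals = df[chrom_col].astype(str) if chrom_col else chrom
    out = pd.DataFrame({"chrom": chrom_vals, "start": pos, "end": pos + 1, "score": score})
    return ScoreTrack(out, kind=kind)


# ---------------------------------------------------------------------------
# MCMC traces

@dataclass
class MCMCTrace:
    """Pooled MCMC samples from one or more replicate chains.

    ``samples`` holds only the parameter columns; ``replicate`` assigns each
    row to the chain it came from. ``burn_in`` and ``thinning`` are in
    iterations and record how the rows relate to raw MCMC iterations.
    """

    samples: pd.DataFrame
    replicate: np.ndarray
    burn_in: int
    thinning: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.samples.to_numpy(dtype=float)).all():
            raise ValueError("trace samples must be finite")
        self.replicate = np.asarray(self.replicate, dtype=np.int64)
        if len(self.replicate) != len(self.samples):
            raise ValueError("replicate ids must match sample rows")

    @property
    def param_names(self) -> list:
        return list(self.samples.columns)

    @property
    def n_replicates(self) -> int:
        return len(np.unique(self.replicate))


def read_mcmc_trace(paths, burn_in: int = 0, thinning: int = 1,
                    pre_thinned: bool = True) -> MCMCTrace:
    """Read and pool tab-delimited MCMC trace files.

    Burn-in rows are removed per replicate before pooling. A leading
    iteration-index column (named Sample/Iteration/...) is recognised and
    dropped. All files must share identical parameter columns.

    Parameters
    ----------
    burn_in : int
        Number of MCMC *iterations* to discard from the start of each chain.
    thinning : int
        The chain's sampling interval in iterations.
    pre_thinned : bool
        If True (the usual on-disk dialect) each row already represents one
        retained sample every ``thinning`` iterations, so ``burn_in //
        thinning`` rows are dropped. If False the file holds every iteration
        and thinning is applied on load.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames, reps = [], []
    columns = None
    for r, p in enumerate(paths):
        df = pd.read_csv(p, sep="\t")
        first = df.columns[0]
        if first.lower().strip() in _ITERATION_COLS:
            df = df.drop(columns=[first])
        if columns is None:
            columns = list(df.columns)
        elif list(df.columns) != columns:
            raise ValueError(
                f"trace {p} columns {list(df.columns)} do not match {columns}")
        if pre_thinned:
            df = df.iloc[burn_in // max(thinning, 1):]
        else:
            df = df.iloc[burn_in::max(thinning, 1)]
        frames.append(df.astype(float))
        reps.append(np.full(len(df), r))
    return MCMCTrace(samples=pd.concat(frames, ignore_index=True),
                     replicate=np.concatenate(reps) if reps else np.array([]),
                     burn_in=burn_in, thinning=thinning)
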