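"""Candidate sweep-region selection: top-quantile windows from two
independent score tracks, their base-pair intersection, and gene overlap.

The two tracks are typically a PBS window scan computed in-package and an
ingested composite-likelihood (CLR) position track from an external sweep
scanner. Requiring a region to rank in the top quantile of both scans is a
conservative intersection filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet, WindowGrid


def _as_score_df(track) -> pd.DataFrame:
    """Accept a ScoreTrack, a PBS-scan DataFrame or any chrom/start/end/score frame."""
    df = getattr(track, "df", track)
    if "score" not in df.columns:
        if "pbs" in df.columns:
            df = df.rename(columns={"pbs": "score"})
        else:
            raise ValueError("track needs a 'score' (or 'pbs') column")
    return df[["chrom", "start", "end", "score"]]


def windowize_scores(track, grid: WindowGrid, agg: str = "mean"):
    """Aggregate a positional score track onto a window grid.

    Each window's score is the ``agg`` ("mean" or "max") of the positional
    scores falling inside it; windows containing no score are dropped
    (undefined). Used to put an ingested per-position CLR track on the same
    grid as a PBS scan before quantile selection.
    """
    df = _as_score_df(track)
    rows = []
    for _, w in grid.windows().iterrows():
        sel = df[(df["chrom"] == w["chrom"]) & (df["start"] >= w["start"])
                 & (df["start"] < w["end"])]
        if len(sel):
            val = sel["score"].max() if agg == "max" else sel["score"].mean()
            rows.append((w["chrom"], int(w["start"]), int(w["end"]), float(val)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def top_quantile_windows(track, q: float, name: str = "top") -> IntervalSet:
    """Windows whose score ranks in the top fraction ``q`` of defined entries.

    The threshold is the ``ceil(q * n)``-th largest defined score and the
    selection keeps every window scoring >= it, so ties at the threshold
    are all included and the output for q1 < q2 nests inside the q2 output.
    Undefined (NaN) entries are excluded from both the ranking and the
    denominator.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    df = _as_score_df(track)
    scores = df["score"].to_numpy(dtype=float)
    defined = np.isfinite(scores)
    n = int(defined.sum())
    if n == 0:
        raise ValueError("all track entries are undefined")
    k = math.ceil(q * n)
    if k == 0:
        return IntervalSet(name, df.iloc[0:0][["chrom", "start", "end"]])
    threshold = np.sort(scores[defined])[::-1][k - 1]
    sel = df[defined & (scores >= threshold)]
    return IntervalSet(name, sel[["chrom", "start", "end"]])


@dataclass
class CandidateRegions:
    """Merged candidate intervals with bookkeeping from the dual-scan intersection."""

    regions: IntervalSet
    covered_bp: int
    genome_fraction: float | None


def intersect_and_merge(a: IntervalSet, b: IntervalSet,
                        genome_length: int | None = None) -> CandidateRegions:
    """Base-pair intersection of two interval sets, merged into candidate regions.

    ``genome_fraction`` is covered_bp / genome_length (the sum of chromosome
    lengths, e.g. from a FASTA index) when a genome length is supplied.
    Raises if the two sets live on entirely disjoint chromosome namespaces,
    which indicates mismatched references rather than a biological absence
    of overlap.
    """
    if len(a) and len(b) and not (a.chroms & b.chroms):
        raise ValueError(
            f"no shared chromosomes between the two sets: "
            f"{sorted(a.chroms)} vs {sorted(b.chroms)}")
    merged = a.intersect(b, name="candidate")
    covered = merged.covered_bp
    frac = covered / genome_length if genome_length else None
    return CandidateRegions(regions=merged, covered_bp=covered, genome_fraction=frac)


def genes_in_regions(regions: IntervalSet, genes: IntervalSet) -> list:
    """Ids of genes overlapping any candidate region by >= 1 bp (sorted, unique)."""
    if "id" not in genes.df.columns or genes.df["id"].isna().any():
        raise ValueError("gene intervals must carry ids")
    merged = regions.merged()
    hits = set()
    for _, g in genes.df.iterrows():
        if merged.overlaps(g["chrom"], int(g["start"]), int(g["end"])):
            hits.add(g["id"])
    return sorted(hits)


def candidate_gene_pathway_overlap(gene_ids, gene_lists: dict) -> pd.DataFrame:
    """Intersect candidate genes with named reference gene lists.

    ``gene_lists`` maps a list name (e.g. "tooth_development",
    "pigmentation") to an iterable of gene ids. Returns one row per list
    with the intersection and its size; empty reference lists produce an
    empty intersection (and a warning-level log would be appropriate in a
    pipeline context).
    """
    cand = set(gene_ids)
    rows = []
    for name, ids in gene_lists.items():
        shared = sorted(cand & set(ids))
        rows.append((name, len(set(ids)), len(shared), ",".join(shared)))
    return pd.DataFrame(rows, columns=["list", "n_list", "n_shared", "shared_ids"])
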