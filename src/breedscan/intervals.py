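"""Genomic interval sets and sliding-window grids.

All coordinates in this package are 0-based half-open. Formats that use
other conventions (VCF, GFF3) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_NAMES = ("exon", "cne", "cpg", "repeat", "gap", "gene", "custom")


@dataclass
class IntervalSet:
    """A named set of genomic intervals, 0-based half-open.

    Parameters
    ----------
    name : str
        Track label (e.g. ``exon``, ``cne``, ``cpg``, ``repeat``, ``gap``,
        ``gene`` or anything else).
    df : pandas.DataFrame
        Columns ``chrom`` (str), ``start`` (int), ``end`` (int) and an
        optional ``id`` column. Sorted on construction.
    """

    name: str
    df: pd.DataFrame = field(default_factory=lambda: _empty_df())

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires a '{col}' column")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]]
            raise ValueError(f"intervals with start >= end: {bad.head().to_dict('records')}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_records(cls, name: str, records) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, id]) tuples."""
        rows = list(records)
        if not rows:
            return cls(name, _empty_df())
        has_id = len(rows[0]) > 3
        cols = ["chrom", "start", "end"] + (["id"] if has_id else [])
        return cls(name, pd.DataFrame(rows, columns=cols))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> set:
        return set(self.df["chrom"].unique())

    def intervals(self):
        """Iterate (chrom, start, end) tuples in sorted order."""
        return list(zip(self.df["chrom"], self.df["start"], self.df["end"]))

    def merged(self) -> "IntervalSet":
        """Union of the intervals: overlapping/adjacent intervals merged per chrom."""
        out = []
        for chrom, sub in self.df.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:  # overlap or adjacency
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e))
        return IntervalSet.from_records(self.name, out)

    @property
    def covered_bp(self) -> int:
        """Total number of base pairs covered (after merging)."""
        m = self.merged().df
        return int((m["end"] - m["start"]).sum())

    def intersect(self, other: "IntervalSet", name: str | None = None) -> "IntervalSet":
        """Base-pair-level intersection with another set; output is merged."""
        a = self.merged().df
        b = other.merged().df
        out = []
        for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
            sa = a[a["chrom"] == chrom]
            sb = b[b["chrom"] == chrom]
            ia = ib = 0
            As, Ae = sa["start"].to_numpy(), sa["end"].to_numpy()
            Bs, Be = sb["start"].to_numpy(), sb["end"].to_numpy()
            while ia < len(As) and ib < len(Bs):
                s = max(As[ia], Bs[ib])
                e = min(Ae[ia], Be[ib])
                if s < e:
                    out.append((chrom, int(s), int(e)))
                if Ae[ia] < Be[ib]:
                    ia += 1
                else:
                    ib += 1
        return IntervalSet.from_records(name or f"{self.name}&{other.name}", out)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval on chrom by >= 1 bp."""
        sub = self.df[self.df["chrom"] == chrom]
        if not len(sub):
            return False
        return bool(((sub["start"] < end) & (sub["end"] > start)).any())

    def distance(self, chrom: str, start: int, end: int) -> float:
        """Gap in bp between [start, end) and the nearest interval on chrom.

        0 if overlapping; ``inf`` if the track has no interval on chrom.
        """
        sub = self.df[self.df["chrom"] == chrom]
        if not len(sub):
            return float("inf")
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        gaps = np.maximum(0, np.maximum(s - end, start - e))
        return float(gaps.min())


def _empty_df() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


@dataclass
class WindowGrid:
    """Sliding-window grid: 0-based half-open windows [k*step, k*step + size).

    Windows are clipped at the chromosome end; every start position strictly
    inside the chromosome yields a window.
    """

    window_size: int
    step_size: int
    chrom_lengths: dict

    def __post_init__(self) -> None:
        if self.step_size > self.window_size:
            raise ValueError("step_size must be <= window_size")
        if self.window_size <= 0 or self.step_size <= 0:
            raise ValueError("window and step sizes must be positive")

    def windows(self) -> pd.DataFrame:
        """DataFrame of all windows with columns chrom, start, end."""
        rows = []
        for chrom in sorted(self.chrom_lengths):
            length = int(self.chrom_lengths[chrom])
            start = 0
            while start < length:
                rows.append((chrom, start, min(start + self.window_size, length)))
                start += self.step_size
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))
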