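"""Neutral-locus selection for demographic inference from RAD data.

The cascade mirrors how restriction-site loci are prepared for multi-locus
coalescent samplers: an in-silico digest of the reference at the enzyme
motif (SpeI, A^CTAGT), extraction of the two flanks joined across the
motif and end-trimmed, removal of loci near functional or problematic
annotation (CpG islands, repeats, assembly gaps, exons, conserved
noncoding elements), a per-individual coverage requirement over the
flanks, and spacing thinning so retained loci evolve independently.

The pipeline applies filters in the fixed order
digest -> extract -> annotation -> coverage -> thin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet

#: Annotation tracks the filter understands, in the order they are checked.
ANNOTATION_ORDER = ("cpg", "repeat", "gap", "exon", "cne")


@dataclass
class DigestConfig:
    """Constants of the locus-selection cascade.

    Defaults give 2*flank + len(motif) - 2*trim = 200 bp loci, a depth >= 5
    per-base per-individual coverage rule, >= 10 kb (inclusive) distance to
    exons, > 100 bp (strict) distance to conserved noncoding elements, and
    one locus per 100 kb.
    """

    motif: str = "ACTAGT"
    flank: int = 100
    trim: int = 3
    min_depth: int = 5
    exon_dist: int = 10_000
    cne_dist: int = 100
    spacing: int = 100_000

    def __post_init__(self) -> None:
        if min(self.flank, self.trim, self.min_depth,
               self.exon_dist, self.cne_dist, self.spacing) <= 0:
            raise ValueError("all DigestConfig values must be positive")
        if 2 * self.trim >= 2 * self.flank + len(self.motif):
            raise ValueError("trim removes the whole locus")

    @property
    def locus_length(self) -> int:
        return 2 * self.flank + len(self.motif) - 2 * self.trim


@dataclass
class RADLocus:
    """One restriction-site locus with its filter status.

    ``cut_site`` is the 0-based start of the motif occurrence;
    ``start``/``end`` bound the retained (trimmed) sequence, which has
    length ``DigestConfig.locus_length`` (200 at defaults). ``status`` is
    "pass" or "rejected"; ``reason`` names the first failing filter
    (edge, cpg, repeat, gap, exon, cne, coverage, spacing).
    """

    chrom: str
    cut_site: int
    start: int = 0
    end: int = 0
    sequence: str = ""
    status: str = "pass"
    reason: str | None = None

    def reject(self, reason: str) -> None:
        self.status = "rejected"
        self.reason = reason

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _get_sequences(genome):
    """Accept a FASTA path or a mapping name -> sequence string."""
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta
        fa = Fasta(str(genome))
        return {name: str(fa[name][:]) for name in fa.keys()}
    return dict(genome)


def find_cut_sites(genome, motif: str = "ACTAGT"):
    """All forward-strand occurrences of the motif, as (chrom, 0-based pos).

    Case-insensitive; positions containing N never match. ACTAGT is its own
    reverse complement, so for this enzyme a forward-strand scan already
    covers both strands.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError("motif must be a non-empty string over A/C/G/T")
    seqs = _get_sequences(genome)
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise ValueError("empty genome")
    out = []
    for chrom in sorted(seqs):
        seq = seqs[chrom].upper()
        start = seq.find(motif)
        while start != -1:
            out.append((chrom, start))
            start = seq.find(motif, start + 1)
    return out


def extract_locus(genome, site, cfg: DigestConfig = DigestConfig()) -> RADLocus:
    """Extract the joined, trimmed flank sequence around one cut site.

    The raw locus is upstream flank + motif + downstream flank; ``trim``
    bases are then removed from each end. A locus is rejected (reason
    "edge") when a full flank would run past the contig boundary or the
    raw region overlaps an N run — rejection is a status, never an error.
    """
    seqs = _get_sequences(genome)
    chrom, pos = site
    seq = seqs[chrom].upper()
    m = len(cfg.motif)
    raw_start = pos - cfg.flank
    raw_end = pos + m + cfg.flank
    locus = RADLocus(chrom=chrom, cut_site=pos,
                     start=raw_start + cfg.trim, end=raw_end - cfg.trim)
    if raw_start < 0 or raw_end > len(seq):
        locus.reject("edge")
        return locus
    raw = seq[raw_start:raw_end]
    if "N" in raw:
        locus.reject("edge")
        return locus
    locus.sequence = raw[cfg.trim:len(raw) - cfg.trim]
    return locus


def filter_by_annotation(loci, tracks: dict,
                         cfg: DigestConfig = DigestConfig()):
    """Reject loci that overlap or sit too close to annotation tracks.

    ``tracks`` maps track names (any subset of cpg/repeat/gap/exon/cne; an
    absent track imposes no constraint) to IntervalSets. A locus is
    rejected when its trimmed interval overlaps cpg/repeat/gap by >= 1 bp,
    lies closer than ``exon_dist`` (strictly; distance >= 10 kb passes) to
    an exon, or within ``cne_dist`` (inclusively; distance > 100 bp passes)
    of a conserved noncoding element. Distances are end-gaps in bp with
    overlap counting as 0. Only currently passing loci are examined;
    modification is in place and the list is returned for chaining.
    """
    unknown = set(tracks) - set(ANNOTATION_ORDER)
    if unknown:
        raise KeyError(f"unknown annotation track(s): {sorted(unknown)}")
    for locus in loci:
        if not locus.passed:
            continue
        for name in ANNOTATION_ORDER:
            if name not in tracks:
                continue
            track = tracks[name]
            if name in ("cpg", "repeat", "gap"):
                if track.overlaps(locus.chrom, locus.start, locus.end):
                    locus.reject(name)
                    break
            elif name == "exon":
                if track.distance(locus.chrom, locus.start, locus.end) < cfg.exon_dist:
                    locus.reject("exon")
                    break
            else:  # cne
                if track.distance(locus.chrom, locus.start, locus.end) <= cfg.cne_dist:
                    locus.reject("cne")
                    break
    return loci


def filter_by_coverage(loci, depth: pd.DataFrame, samples,
                       cfg: DigestConfig = DigestConfig()):
    """Require depth >= min_depth at every flank base in every sample.

    ``depth`` is a per-base table with columns chrom, pos (0-based) and one
    column per sample; positions absent from the table count as depth 0.
    The footprint checked is both full (untrimmed) flanks:
    [cut - flank, cut) and [cut + len(motif), cut + len(motif) + flank).
    """
    missing = [s for s in samples if s not in depth.columns]
    if missing:
        raise KeyError(f"samples missing from depth table: {missing}")
    m = len(cfg.motif)
    by_chrom = {}
    for chrom, sub in depth.groupby("chrom"):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos)
        by_chrom[chrom] = (pos[order], sub[list(samples)].to_numpy()[order])
    for locus in loci:
        if not locus.passed:
            continue
        if locus.chrom not in by_chrom:
            locus.reject("coverage")
            continue
        pos, mat = by_chrom[locus.chrom]
        want = np.concatenate([
            np.arange(locus.cut_site - cfg.flank, locus.cut_site),
            np.arange(locus.cut_site + m, locus.cut_site + m + cfg.flank),
        ])
        idx = np.searchsorted(pos, want)
        ok = (idx < len(pos)) & (pos[np.minimum(idx, len(pos) - 1)] == want)
        if not ok.all() or (mat[idx[ok]] < cfg.min_depth).any():
            locus.reject("coverage")
    return loci


def thin_loci(loci, spacing: int = 100_000):
    """Greedy left-to-right spacing walk: one locus per ``spacing`` bp.

    Per chromosome, a passing locus is kept iff its cut site is >= spacing
    from the last kept cut site; all other passing loci are rejected
    (reason "spacing"). The greedy walk guarantees that no two retained
    loci are closer than ``spacing``.
    """
    last_kept: dict = {}
    for locus in sorted(loci, key=lambda l: (l.chrom, l.cut_site)):
        if not locus.passed:
            continue
        prev = last_kept.get(locus.chrom)
        if prev is not None and locus.cut_site - prev < spacing:
            locus.reject("spacing")
        else:
            last_kept[locus.chrom] = locus.cut_site
    return loci


def run_locus_pipeline(genome, tracks: dict | None = None,
                       cfg: DigestConfig = DigestConfig(),
                       depth: pd.DataFrame | None = None,
                       samples=None):
    """Full cascade: digest -> extract -> annotation -> coverage -> thin."""
    sites = find_cut_sites(genome, cfg.motif)
    seqs = _get_sequences(genome)
    loci = [extract_locus(seqs, s, cfg) for s in sites]
    if tracks:
        filter_by_annotation(loci, tracks, cfg)
    if depth is not None:
        if samples is None:
            raise ValueError("coverage filtering requires a sample list")
        filter_by_coverage(loci, depth, samples, cfg)
    thin_loci(loci, cfg.spacing)
    return loci


def export_loci(loci, fasta_path=None, bed_path=None, audit_path=None):
    """Write passing loci as FASTA/BED and a full audit table; return counts.

    The audit table has one row per digested site with its terminal status
    and reason, so reason counts always sum to the total locus count.
    """
    passing = [l for l in loci if l.passed]
    if fasta_path is not None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        records = [SeqRecord(Seq(l.sequence),
                             id=f"{l.chrom}:{l.cut_site}",
                             description=f"{l.chrom}:{l.start}-{l.end}")
                   for l in passing]
        SeqIO.write(records, str(fasta_path), "fasta")
    if bed_path is not None:
        from .io import write_intervals
        write_intervals(IntervalSet.from_records(
            "rad_loci", [(l.chrom, l.start, l.end) for l in passing]), bed_path)
    audit = pd.DataFrame(
        [(l.chrom, l.cut_site, l.start, l.end, l.status, l.reason or "")
         for l in loci],
        columns=["chrom", "cut_site", "start", "end", "status", "reason"])
    if audit_path is not None:
        audit.to_csv(audit_path, sep="\t", index=False)
    counts = audit.groupby(audit["reason"].where(audit["status"] == "rejected",
                                                 "pass")).size().to_dict()
    return audit, counts
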