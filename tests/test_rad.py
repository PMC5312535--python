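import numpy as np
import pandas as pd
import pytest

import breedscan as bs
from breedscan import DigestConfig

MOTIF = "ACTAGT"
COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMP)[::-1]


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def plant(seq, positions):
    s = list(seq)
    for p in positions:
        s[p:p + 6] = MOTIF
    return "".join(s)


class TestFindCutSites:
    def test_no_motif_empty(self):
        assert bs.find_cut_sites({"chr1": "AAAA" * 100}) == []

    def test_planted_sites_found_exactly(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 1000).replace(MOTIF, "AAAAAA")
        seq = plant(seq, [100, 400, 850])
        assert bs.find_cut_sites({"chr1": seq}) == \
            [("chr1", 100), ("chr1", 400), ("chr1", 850)]

    def test_palindromic_motif_mirrors_under_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = plant(random_seq(rng, 500).replace(MOTIF, "CCCCCC"), [50, 300])
        fwd = {p for _, p in bs.find_cut_sites({"c": seq})}
        rev = {p for _, p in bs.find_cut_sites({"c": revcomp(seq)})}
        assert rev == {len(seq) - 6 - p for p in fwd}

    def test_case_insensitive_and_n_never_matches(self):
        assert bs.find_cut_sites({"c": "actagt"}) == [("c", 0)]
        assert bs.find_cut_sites({"c": "ACTAGN" + "ACTANT"}) == []

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            bs.find_cut_sites({"c": ""})

    def test_fasta_path_input(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nAAAACTAGTAAA\n")
        assert bs.find_cut_sites(fa) == [("chr1", 3)]


class TestExtractLocus:
    def test_interior_site_yields_200_bp(self):
        rng = np.random.default_rng(2)
        seq = plant(random_seq(rng, 1000).replace(MOTIF, "AAAAAA"), [500])
        locus = bs.extract_locus({"c": seq}, ("c", 500))
        assert locus.passed
        assert len(locus.sequence) == 200
        assert locus.end - locus.start == 200

    def test_site_near_contig_start_edge_rejected(self):
        seq = plant("A" * 500, [50])
        locus = bs.extract_locus({"c": seq}, ("c", 50))
        assert locus.status == "rejected"
        assert locus.reason == "edge"

    def test_n_run_in_flank_edge_rejected(self):
        seq = plant("A" * 300 + "N" * 10 + "A" * 300, [400])
        locus = bs.extract_locus({"c": seq}, ("c", 400))
        assert locus.reason == "edge"

    def test_sequence_equals_slicing_oracle(self):
        rng = np.random.default_rng(3)
        seq = plant(random_seq(rng, 800).replace(MOTIF, "AAAAAA"), [350])
        locus = bs.extract_locus({"c": seq}, ("c", 350))
        # oracle: direct slice [pos-100+3, pos+6+100-3)
        assert locus.sequence == seq[350 - 97:350 + 103].upper()


class TestAnnotationFilter:
    def _locus(self, cut=5000, chrom="c"):
        seq = plant("A" * 20_000, [cut])
        return bs.extract_locus({chrom: seq}, (chrom, cut))

    def test_empty_tracks_all_pass(self):
        loci = [self._locus(c) for c in (1000, 5000, 9000)]
        bs.filter_by_annotation(loci, {})
        assert all(l.passed for l in loci)

    def test_one_bp_repeat_overlap_rejected(self):
        locus = self._locus()
        track = bs.IntervalSet.from_records("repeat",
                                            [("c", locus.end - 1, locus.end + 50)])
        bs.filter_by_annotation([locus], {"repeat": track})
        assert locus.reason == "repeat"

    def test_exon_distance_inclusive_threshold(self):
        # "at least 10 kb" from exons: 10,000 passes, 9,999 is rejected
        for gap, passes in ((10_000, True), (9_999, False)):
            locus = self._locus()
            exon = bs.IntervalSet.from_records(
                "exon", [("c", locus.end + gap, locus.end + gap + 100)])
            bs.filter_by_annotation([locus], {"exon": exon})
            assert locus.passed == passes, gap

    def test_cne_distance_strict_threshold(self):
        # "more than 100 bp away" from CNEs: 101 passes, 100 is rejected
        for gap, passes in ((101, True), (100, False)):
            locus = self._locus()
            cne = bs.IntervalSet.from_records(
                "cne", [("c", locus.end + gap, locus.end + gap + 10)])
            bs.filter_by_annotation([locus], {"cne": cne})
            assert locus.passed == passes, gap

    def test_unknown_track_rejected(self):
        with pytest.raises(KeyError):
            bs.filter_by_annotation([self._locus()], {"enhancer": None})

    def test_predicates_are_order_independent(self):
        # the annotation checks are independent predicates: filtering with
        # all tracks at once matches sequential single-track passes in
        # reverse order (only the recorded reason depends on check order)
        rng = np.random.default_rng(4)
        cuts = sorted(rng.choice(np.arange(200, 19_000), 12, replace=False))
        tracks = {
            name: bs.IntervalSet.from_records(name, [
                ("c", int(s), int(s) + 300)
                for s in rng.integers(0, 19_000, size=3)])
            for name in ("cpg", "repeat", "gap", "exon", "cne")
        }
        combined = [self._locus(int(c)) for c in cuts]
        bs.filter_by_annotation(combined, tracks)
        sequential = [self._locus(int(c)) for c in cuts]
        for name in ("cne", "exon", "gap", "repeat", "cpg"):
            bs.filter_by_annotation(sequential, {name: tracks[name]})
        assert [l.passed for l in combined] == [l.passed for l in sequential]


class TestThinning:
    def _loci(self, cuts, chrom="c"):
        return [bs.RADLocus(chrom=chrom, cut_site=c, start=c - 97, end=c + 103)
                for c in cuts]

    def test_single_locus_kept(self):
        loci = self._loci([500])
        bs.thin_loci(loci)
        assert loci[0].passed

    def test_greedy_walk_example(self):
        loci = self._loci([0, 50_000, 120_000])
        bs.thin_loci(loci, spacing=100_000)
        assert [l.passed for l in loci] == [True, False, True]
        assert loci[1].reason == "spacing"

    def test_kept_loci_pairwise_spaced(self):
        rng = np.random.default_rng(5)
        loci = self._loci(sorted(rng.choice(10**6, 200, replace=False)))
        bs.thin_loci(loci, spacing=100_000)
        kept = [l.cut_site for l in loci if l.passed]
        assert all(b - a >= 100_000 for a, b in zip(kept, kept[1:]))

    def test_rejected_loci_do_not_shadow_neighbors(self):
        loci = self._loci([0, 50_000])
        loci[0].reject("coverage")
        bs.thin_loci(loci, spacing=100_000)
        assert loci[1].passed


class TestCoverageFilter:
    def _depth_table(self, loci, samples, value, cfg=DigestConfig()):
        rows = []
        for l in loci:
            for pos in list(range(l.cut_site - cfg.flank, l.cut_site)) + \
                    list(range(l.cut_site + 6, l.cut_site + 6 + cfg.flank)):
                rows.append([l.chrom, pos] + [value] * len(samples))
        return pd.DataFrame(rows, columns=["chrom", "pos"] + samples)

    def _loci(self, cuts):
        return [bs.RADLocus(chrom="c", cut_site=c, start=c - 97, end=c + 103)
                for c in cuts]

    def test_depth_exactly_five_everywhere_passes(self):
        loci = self._loci([500])
        samples = ["s1", "s2"]
        bs.filter_by_coverage(loci, self._depth_table(loci, samples, 5), samples)
        assert loci[0].passed

    def test_one_base_below_threshold_in_one_sample_rejects(self):
        loci = self._loci([500])
        samples = ["s1", "s2"]
        table = self._depth_table(loci, samples, 9)
        table.loc[37, "s2"] = 4
        bs.filter_by_coverage(loci, table, samples)
        assert loci[0].reason == "coverage"

    def test_missing_sample_rejected(self):
        loci = self._loci([500])
        table = self._depth_table(loci, ["s1"], 9)
        with pytest.raises(KeyError):
            bs.filter_by_coverage(loci, table, ["s1", "ghost"])

    def test_matches_brute_force_all_bases_all_samples(self):
        rng = np.random.default_rng(6)
        loci = self._loci([500, 1000, 1500, 2000])
        samples = ["s1", "s2", "s3"]
        table = self._depth_table(loci, samples, 9)
        holes = rng.choice(len(table), size=5, replace=False)
        for h in holes:
            table.loc[h, rng.choice(samples)] = int(rng.integers(0, 5))
        expected = []
        for l in loci:  # brute force: every base of both flanks, every sample
            sub = table[(table["chrom"] == l.chrom)
                        & (((table["pos"] >= l.cut_site - 100) & (table["pos"] < l.cut_site))
                           | ((table["pos"] >= l.cut_site + 6)
                              & (table["pos"] < l.cut_site + 106)))]
            expected.append(bool((sub[samples].to_numpy() >= 5).all()))
        bs.filter_by_coverage(loci, table, samples)
        assert [l.passed for l in loci] == expected


class TestExport:
    def _loci(self):
        loci = [bs.RADLocus(chrom="c", cut_site=i * 1000, start=i * 1000 - 97,
                            end=i * 1000 + 103, sequence="A" * 200)
                for i in range(1, 11)]
        for i, reason in zip((0, 2, 4, 6, 7, 8), ("edge", "cpg", "exon",
                                                  "coverage", "spacing", "cne")):
            loci[i].reject(reason)
        return loci

    def test_fasta_and_audit_bookkeeping(self, tmp_path):
        from Bio import SeqIO
        loci = self._loci()
        audit, counts = bs.export_loci(
            loci, fasta_path=tmp_path / "l.fa", bed_path=tmp_path / "l.bed",
            audit_path=tmp_path / "l.tsv")
        assert len(audit) == 10
        assert counts["pass"] == 4
        assert sum(counts.values()) == 10
        assert len(list(SeqIO.parse(tmp_path / "l.fa", "fasta"))) == 4

    def test_empty_pass_set_still_audited(self, tmp_path):
        loci = self._loci()
        for l in loci:
            if l.passed:
                l.reject("coverage")
        audit, counts = bs.export_loci(loci, fasta_path=tmp_path / "e.fa")
        assert len(audit) == 10
        assert "pass" not in counts

    def test_every_site_has_exactly_one_terminal_status(self):
        audit, _ = bs.export_loci(self._loci())
        assert audit["status"].isin(["pass", "rejected"]).all()
        assert (audit.groupby(["chrom", "cut_site"]).size() == 1).all()


def test_pipeline_applies_coverage_before_thinning():
    # two sites 50 kb apart; the left one fails coverage. If thinning ran
    # first it would knock out the right one, leaving nothing; the fixed
    # order digest->extract->annotation->coverage->thin keeps the right one.
    rng = np.random.default_rng(7)
    seq = random_seq(rng, 60_000).replace(MOTIF, "AAAAAA")
    seq = plant(seq, [1000, 51_000])
    samples = ["s1"]
    rows = []
    for cut, depth in ((1000, 2), (51_000, 9)):
        for pos in list(range(cut - 100, cut)) + list(range(cut + 6, cut + 106)):
            rows.append(["chr1", pos, depth])
    table = pd.DataFrame(rows, columns=["chrom", "pos", "s1"])
    loci = bs.run_locus_pipeline({"chr1": seq}, {}, DigestConfig(spacing=100_000),
                                 depth=table, samples=samples)
    status = {l.cut_site: (l.status, l.reason) for l in loci}
    assert status[1000] == ("rejected", "coverage")
    assert status[51_000] == ("pass", None)


def test_digest_config_validation():
    with pytest.raises(ValueError):
        DigestConfig(trim=0)
    with pytest.raises(ValueError):
        DigestConfig(flank=2, trim=5)
    assert DigestConfig().locus_length == 200
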