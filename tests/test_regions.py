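import numpy as np
import pytest

from conftest import detect
from promspec.regions import (
    MotifCatalogEntry,
    RegularRegion,
    catalog,
    coverage_fraction,
    length_histogram,
    count_occurrences,
    mean_coverage_fraction,
)
from promspec.repeats import RepeatInterval
from promspec.seqio import PromoterRecord, reverse_complement
from promspec.synth import plant_regular


def region(pid, s, e, seq=""):
    return RegularRegion(
        promoter_id=pid, s=s, e=e, quaternary=seq, binary="", n_support=e - s + 1
    )


class TestDetectRegions:
    def test_planted_20mer_recovered(self):
        rec, truth = plant_regular(1000, [("C" * 20, 500)], seed=3)
        regs = detect(rec)
        assert len(regs) == 1
        (s, e, _), r = truth[0], regs[0]
        overlap = max(0, min(e, r.e) - max(s, r.s) + 1)
        assert overlap >= 0.9 * 20

    def test_null_background_quiet(self):
        hits = 0
        for seed in range(20):
            rec, _ = plant_regular(300, [], seed=1000 + seed)
            if detect(rec):
                hits += 1
        assert hits <= 1

    def test_minimum_length_seven(self):
        tracts = [("C" * n, pos) for n, pos in zip((4, 5, 6, 7), (100, 250, 400, 550))]
        rec, _ = plant_regular(1000, tracts, seed=11)
        regs = detect(rec)
        # runs of 4-6 produce nothing; the 7-run is reported at length 7
        assert [r.length for r in regs] == [7]
        assert (regs[0].s, regs[0].e) == (550, 556)
        assert regs[0].quaternary == "C" * 7

    def test_deterministic(self):
        rec, _ = plant_regular(500, [("C" * 10, 200)], seed=9)
        a = [(r.s, r.e) for r in detect(rec)]
        b = [(r.s, r.e) for r in detect(rec)]
        assert a == b

    def test_revcomp_duality(self):
        rec, _ = plant_regular(1000, [("CTAATTTTTGTATTTTTAG", 500)], seed=7)
        fwd = detect(rec)
        rc_rec = PromoterRecord(id="rc", sequence=reverse_complement(rec.sequence))
        rev = detect(rc_rec)
        L = rec.L
        mirrored = sorted((L + 1 - r.e, L + 1 - r.s) for r in rev)
        assert mirrored == sorted((r.s, r.e) for r in fwd)
        rev_seqs = sorted(reverse_complement(r.quaternary) for r in rev)
        assert rev_seqs == sorted(r.quaternary for r in fwd)

    def test_support_within_tolerance(self):
        rec, _ = plant_regular(1000, [("C" * 12, 300), ("C" * 20, 700)], seed=2)
        for r in detect(rec):
            assert abs(r.n_support - r.length) <= 0.3 * r.length

    def test_regions_sorted_and_disjoint(self):
        tracts = [("C" * 10, 100), ("C" * 14, 400), ("C" * 9, 800)]
        rec, _ = plant_regular(1000, tracts, seed=6)
        regs = detect(rec)
        assert [r.s for r in regs] == sorted(r.s for r in regs)
        for a, b in zip(regs, regs[1:]):
            assert a.e < b.s


class TestCoverage:
    def test_simple_fraction(self):
        assert coverage_fraction([region("p", 101, 200)], 1000) == pytest.approx(0.1)

    def test_no_regions(self):
        assert coverage_fraction([], 500) == 0.0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            coverage_fraction([region("p", 1, 10), region("p", 5, 20)], 100)

    def test_planted_total(self):
        tracts = [("C" * 10, 100), ("C" * 14, 400), ("C" * 20, 800)]
        rec, truth = plant_regular(1000, tracts, seed=6)
        regs = detect(rec)
        frac = coverage_fraction(regs, rec.L)
        planted = sum(e - s + 1 for s, e, _ in truth)
        assert frac == pytest.approx(planted / rec.L, abs=0.01)

    def test_mean_coverage(self):
        regs = {"a": [region("a", 1, 100)], "b": []}
        assert mean_coverage_fraction(regs, {"a": 1000, "b": 1000}) == pytest.approx(0.05)


class TestLengthHistogram:
    def test_counts(self):
        regs = [region("p", 1, 7), region("p", 10, 16), region("p", 20, 28)]
        assert length_histogram(regs) == {7: 2, 9: 1}

    def test_empty(self):
        assert length_histogram([]) == {}

    def test_planted_mode(self):
        tracts = [("C" * 9, p) for p in (100, 300, 500, 700, 900)]
        rec, _ = plant_regular(1100, tracts, seed=8)
        hist = length_histogram(detect(rec))
        assert max(hist, key=hist.get) == 9


class TestCatalog:
    def make_cluster(self, motif, n_with, n_total, L=60):
        recs = []
        for i in range(n_total):
            base = "ATGA" * (L // 4)
            if i < n_with:
                base = base[: 10] + motif + base[10 + len(motif) :]
            recs.append(PromoterRecord(id=f"p{i}", sequence=base))
        return recs

    def test_promoter_pct(self):
        motif = "CCCCCCC"
        recs = self.make_cluster(motif, 4, 10)
        regions_by = {"p0": [region("p0", 11, 17, motif)]}
        entries = catalog(regions_by, recs)
        entry = next(e for e in entries if e.sequence == motif)
        assert entry.n_promoters == 4
        assert entry.promoter_pct == pytest.approx(0.4)
        assert entry.mean_copies >= 1.0

    def test_pct_in_transposon(self):
        motif = "GGGGGGG"
        seq = "ATCA" * 5 + motif + "TTAC" * 5 + motif + "AATC" * 5
        recs = [
            PromoterRecord(id="p0", sequence=seq),
            PromoterRecord(id="p1", sequence=seq),
        ]
        # p0's two occurrences inside a repeat; p1's outside; 3 of 4 inside
        ivs = [
            RepeatInterval("p0", 1, len(seq), "AluY"),
            RepeatInterval("p1", 21, 27, "AluY"),
        ]
        regions_by = {"p0": [region("p0", 21, 27, motif)]}
        entries = catalog(regions_by, recs, repeat_intervals=ivs)
        entry = next(e for e in entries if e.sequence == motif)
        assert entry.pct_in_transposon == pytest.approx(0.75)

    def test_na_without_annotation(self):
        motif = "CCCCCCC"
        recs = self.make_cluster(motif, 2, 4)
        entries = catalog({"p0": [region("p0", 11, 17, motif)]}, recs)
        assert all(e.pct_in_transposon is None for e in entries)

    def test_overlapping_occurrences_counted(self):
        assert count_occurrences("AA", "AAAA") == [1, 2, 3]
        assert count_occurrences("CG", "CGCGCG") == [1, 3, 5]

    def test_forward_reverse_companionship(self):
        """Clusters carrying one element on opposite strands catalogue
        reverse-complement companion motifs."""
        element = "CTAATTTTTGTATTTTTAG"
        fwd_recs, rev_recs = [], []
        fwd_regions, rev_regions = {}, {}
        for i in range(6):
            rec, _ = plant_regular(
                400, [(element, 150)], seed=100 + i, record_id=f"f{i}"
            )
            fwd_recs.append(rec)
            fwd_regions[rec.id] = detect(rec)
            rc = PromoterRecord(
                id=f"r{i}", sequence=reverse_complement(rec.sequence)
            )
            rev_recs.append(rc)
            rev_regions[rc.id] = detect(rc)
        top_f = catalog(fwd_regions, fwd_recs, top_k=15)
        top_r = catalog(rev_regions, rev_recs, top_k=15)
        assert top_f and top_r
        assert {reverse_complement(e.sequence) for e in top_f} == {
            e.sequence for e in top_r
        }

    def test_ranking_ties_lexicographic(self):
        entries = catalog(
            {
                "p0": [region("p0", 1, 7, "AAAAAAA")],
                "p1": [region("p1", 1, 7, "TTTTTTT")],
            },
            [
                PromoterRecord(id="p0", sequence="AAAAAAAGG"),
                PromoterRecord(id="p1", sequence="TTTTTTTGG"),
            ],
        )
        assert [e.sequence for e in entries] == ["AAAAAAA", "TTTTTTT"]
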