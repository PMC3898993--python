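"""Alignment tests, including an independent brute-force oracle.

The oracle enumerates every monotone alignment path explicitly (no dynamic
programming) and scores it with EMBOSS conventions: +5/-4 substitutions, a
run of g gaps costs gap_open + g * gap_extend, and runs of gaps at either
end of either sequence are free when end gaps are enabled.
"""

import itertools

import numpy as np
import pytest

from promspec.alignment import (
    ScoringScheme,
    SimilarityMatrix,
    align_pair,
    align_score,
    null_threshold,
    reshuffle,
    similarity_matrix,
)
from promspec.seqio import PromoterRecord

GO, GE = 20.0, 0.5


def _score_ops(a, b, ops, end_gaps_free):
    """Score one explicit alignment path (list of 'D'/'U'/'L' moves)."""
    i = j = 0
    subs = 0.0
    for op in ops:
        if op == "D":
            subs += 5.0 if a[i] == b[j] else -4.0
            i += 1
            j += 1
        elif op == "U":
            i += 1
        else:
            j += 1
    # group gap runs and decide which are terminal for the gapped sequence
    runs = [(op, len(list(g))) for op, g in itertools.groupby(ops)]
    consumes = {"U": "DL", "L": "DU"}  # ops that consume the gapped sequence
    gap_cost = 0.0
    for idx, (op, g) in enumerate(runs):
        if op == "D":
            continue
        before = any(r[0] in consumes[op] for r in runs[:idx])
        after = any(r[0] in consumes[op] for r in runs[idx + 1 :])
        if end_gaps_free and (not before or not after):
            continue
        gap_cost += GO + g * GE
    return subs - gap_cost


def _enumerate_paths(na, nb):
    if na == 0 and nb == 0:
        yield []
        return
    if na > 0 and nb > 0:
        for rest in _enumerate_paths(na - 1, nb - 1):
            yield ["D"] + rest
    if na > 0:
        for rest in _enumerate_paths(na - 1, nb):
            yield ["U"] + rest
    if nb > 0:
        for rest in _enumerate_paths(na, nb - 1):
            yield ["L"] + rest


def brute_global(a, b, end_gaps_free=True):
    return max(
        _score_ops(a, b, ops, end_gaps_free)
        for ops in _enumerate_paths(len(a), len(b))
    )


def brute_local(a, b):
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, brute_global(a[i1:i2], b[j1:j2], False))
    return best


class TestAgainstOracle:
    def test_exhaustive_short_pairs(self):
        words = ["".join(w) for n in (1, 2) for w in itertools.product("AC", repeat=n)]
        for a in words:
            for b in words:
                for free in (True, False):
                    scheme = ScoringScheme(gap_open=GO, gap_extend=GE, end_gaps_free=free)
                    assert align_score(a, b, scheme) == pytest.approx(
                        brute_global(a, b, free)
                    ), (a, b, free)

    def test_random_pairs_global(self, rng):
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
            for free in (True, False):
                scheme = ScoringScheme(end_gaps_free=free)
                assert align_score(a, b, scheme) == pytest.approx(
                    brute_global(a, b, free)
                ), (a, b, free)

    def test_random_pairs_local(self, rng):
        scheme = ScoringScheme(mode="local")
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 6)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 6)))
            assert align_score(a, b, scheme) == pytest.approx(brute_local(a, b)), (a, b)


class TestAlignPair:
    def test_perfect_match(self):
        score, _ = align_pair("ACGT", "ACGT")
        assert score == 20.0

    def test_free_end_gaps(self):
        assert align_score("AAAA", "TTAAAATT") == 20.0

    def test_symmetry(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 30))
            b = "".join(rng.choice(list("ACGT"), 30))
            assert align_score(a, b) == align_score(b, a)

    def test_mismatch_never_raises_score(self, rng):
        a = "".join(rng.choice(list("ACGT"), 40))
        base = align_score(a, a)
        chars = list(a)
        chars[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[20]]
        assert align_score(a, "".join(chars)) <= base

    def test_local_nonnegative(self, rng):
        scheme = ScoringScheme(mode="local")
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 20))
            b = "".join(rng.choice(list("ACGT"), 20))
            assert align_score(a, b, scheme) >= 0

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestSimilarityMatrix:
    def test_three_identical(self):
        recs = [PromoterRecord(id=f"r{i}", sequence="ACGTACGTAC") for i in range(3)]
        sim = similarity_matrix(recs)
        off = sim.S[~np.eye(3, dtype=bool)]
        assert np.all(off == 50.0)
        assert np.all(np.diag(sim.S) == 50.0)  # 5 per position self-score

    def test_two_records(self):
        recs = [
            PromoterRecord(id="a", sequence="ACGTACGT"),
            PromoterRecord(id="b", sequence="TTTTACGT"),
        ]
        sim = similarity_matrix(recs)
        assert sim.S.shape == (2, 2)
        assert sim.S[0, 1] == sim.S[1, 0]

    def test_permutation_equivariance(self, rng):
        recs = [
            PromoterRecord(id=f"r{i}", sequence="".join(rng.choice(list("ACGT"), 30)))
            for i in range(4)
        ]
        sim = similarity_matrix(recs)
        perm = [2, 0, 3, 1]
        sim_p = similarity_matrix([recs[i] for i in perm])
        assert np.allclose(sim_p.S, sim.S[np.ix_(perm, perm)])

    def test_requires_two(self):
        with pytest.raises(ValueError):
            similarity_matrix([PromoterRecord(id="a", sequence="ACGT")])

    def test_cache_resume(self, tmp_path, rng):
        recs = [
            PromoterRecord(id=f"r{i}", sequence="".join(rng.choice(list("ACGT"), 25)))
            for i in range(3)
        ]
        cache = tmp_path / "pairs.tsv"
        first = similarity_matrix(recs, cache=cache)
        resumed = similarity_matrix(recs, cache=cache)
        assert np.allclose(first.S, resumed.S)

    def test_tsv_roundtrip(self, tmp_path, rng):
        recs = [
            PromoterRecord(id=f"r{i}", sequence="".join(rng.choice(list("ACGT"), 20)))
            for i in range(3)
        ]
        sim = similarity_matrix(recs)
        path = tmp_path / "sim.tsv"
        sim.to_tsv(path)
        back = SimilarityMatrix.from_tsv(path)
        assert back.ids == sim.ids
        assert np.allclose(back.S, sim.S)


class TestReshuffleNull:
    def test_composition_preserved(self, rng):
        rec = PromoterRecord(id="r", sequence="".join(rng.choice(list("ACGT"), 100)))
        shuf = reshuffle(rec, 7)
        assert sorted(shuf.sequence) == sorted(rec.sequence)
        assert shuf.L == rec.L

    def test_deterministic(self):
        rec = PromoterRecord(id="r", sequence="ACGTACGTACGTACGTACGT")
        assert reshuffle(rec, 3).sequence == reshuffle(rec, 3).sequence

    def test_homopolymer_degenerate_theta(self):
        recs = [PromoterRecord(id=f"r{i}", sequence="AAAAA") for i in range(3)]
        # reshuffling a homopolymer is the identity
        assert null_threshold(recs, seed=0) == 25.0

    def test_theta_stabilizes(self):
        rng = np.random.default_rng(5)
        recs = [
            PromoterRecord(id=f"r{i}", sequence="".join(rng.choice(list("ACGT"), 200)))
            for i in range(12)
        ]
        thetas = [null_threshold(recs, seed=s) for s in range(3)]
        assert np.std(thetas) < 0.05 * np.mean(thetas)
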