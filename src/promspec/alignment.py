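"""Pairwise affine-gap alignment and all-vs-all similarity matrices.

Scoring follows the EMBOSS conventions: the EDNAFULL nucleotide
substitution matrix (match +5, mismatch -4, IUPAC-extended), an affine gap
cost of ``gap_open + g * gap_extend`` for a run of ``g`` gaps, and — in
global mode — no penalty for gaps at either end of a sequence.  Under
these settings global (Needleman-Wunsch) and local (Smith-Waterman) scores
of similar sequences essentially coincide.

The dynamic programming is delegated to :class:`Bio.Align.PairwiseAligner`
(C implementation), wrapped so that scores are bit-reproducible for a
given :class:`ScoringScheme`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import PromoterRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """EMBOSS-dialect alignment parameters.

    ``gap_open``/``gap_extend`` are costs (non-negative); the cost of a run
    of ``g >= 1`` gaps is ``gap_open + g * gap_extend``.  With
    ``end_gaps_free`` (global mode only) terminal gaps cost nothing.
    """

    gap_open: float = 20.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True
    mode: str = "global"
    matrix_name: str = "EDNAFULL"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")

    def substitution_matrix(self):
        # NUC.4.4 is the EDNAFULL matrix (match +5 / mismatch -4, IUPAC)
        return substitution_matrices.load("NUC.4.4")


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.substitution_matrix()
    aligner.mode = scheme.mode
    # Biopython charges open for the first gap of a run and extend for the
    # rest; EMBOSS charges open + extend for the first.  Shift accordingly.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    if scheme.mode == "global" and scheme.end_gaps_free:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


def align_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Best alignment score of two DNA strings under the scheme."""
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return float(_make_aligner(scheme).score(a.upper(), b.upper()))


def align_pair(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[float, str]:
    """Best score plus one optimal alignment (pretty-printed).

    Traceback ties are resolved deterministically by the engine; only the
    score feeds the downstream pipeline.
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(scheme)
    alignments = aligner.align(a.upper(), b.upper())
    best = alignments[0]
    return float(best.score), str(best)


@dataclass
class SimilarityMatrix:
    """Symmetric all-vs-all best-alignment scores."""

    ids: list[str]
    S: np.ndarray
    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError("score matrix shape does not match ids")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("score matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids: list[str]) -> "SimilarityMatrix":
        pos = {pid: i for i, pid in enumerate(self.ids)}
        order = [pos[pid] for pid in ids]
        return SimilarityMatrix(list(ids), self.S[np.ix_(order, order)], self.scheme)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("id_i\tid_j\tscore\n")
            for i in range(self.n):
                for j in range(i, self.n):
                    fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{self.S[i, j]:g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, scheme: ScoringScheme | None = None) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t")
        ids: list[str] = []
        seen = set()
        for pid in pd.concat([df["id_i"], df["id_j"]]).astype(str):
            if pid not in seen:
                seen.add(pid)
                ids.append(pid)
        pos = {pid: i for i, pid in enumerate(ids)}
        S = np.zeros((len(ids), len(ids)))
        for _, row in df.iterrows():
            i, j = pos[str(row["id_i"])], pos[str(row["id_j"])]
            S[i, j] = S[j, i] = float(row["score"])
        return cls(ids, S, scheme or ScoringScheme())


def similarity_matrix(
    records: list[PromoterRecord],
    scheme: ScoringScheme | None = None,
    cache: str | Path | None = None,
    log_every: int = 500,
) -> SimilarityMatrix:
    """All N(N-1)/2 pairwise scores (plus self-scores on the diagonal).

    ``cache`` names an optional TSV to which finished pairs are appended
    and from which a previous partial run is resumed.
    """
    scheme = scheme or ScoringScheme()
    n = len(records)
    if n < 2:
        raise ValueError("need at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != n:
        raise ValueError("duplicate record ids")
    pos = {pid: i for i, pid in enumerate(ids)}
    S = np.full((n, n), np.nan)

    done: set[tuple[int, int]] = set()
    cache_fh = None
    if cache is not None:
        cache = Path(cache)
        if cache.exists():
            cached = pd.read_csv(cache, sep="\t")
            for _, row in cached.iterrows():
                i, j = pos.get(str(row["id_i"])), pos.get(str(row["id_j"]))
                if i is not None and j is not None:
                    S[i, j] = S[j, i] = float(row["score"])
                    done.add((min(i, j), max(i, j)))
            logger.info("resumed %d cached pairs from %s", len(done), cache)
        else:
            cache.write_text("id_i\tid_j\tscore\n")
        cache_fh = cache.open("a")

    aligner = _make_aligner(scheme)
    seqs = [r.sequence for r in records]
    k = 0
    try:
        for i in range(n):
            for j in range(i, n):
                if (i, j) in done:
                    continue
                score = float(aligner.score(seqs[i], seqs[j]))
                S[i, j] = S[j, i] = score
                if cache_fh is not None:
                    cache_fh.write(f"{ids[i]}\t{ids[j]}\t{score:g}\n")
                k += 1
                if log_every and k % log_every == 0:
                    logger.info("aligned %d pairs", k)
    finally:
        if cache_fh is not None:
            cache_fh.close()
    return SimilarityMatrix(ids, S, scheme)


def reshuffle(record: PromoterRecord, seed: int | np.random.Generator) -> PromoterRecord:
    """Uniform random permutation of the record's characters.

    Composition is preserved exactly; deterministic under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chars = np.array(list(record.sequence))
    rng.shuffle(chars)
    return PromoterRecord(id=record.id, sequence="".join(chars))


def null_threshold(
    records: list[PromoterRecord],
    scheme: ScoringScheme | None = None,
    seed: int = 0,
    replicates: int = 1,
) -> float:
    """Adjacency threshold from the reshuffled-sequence null model.

    Each promoter is reshuffled (``replicates`` independent times); theta
    is the arithmetic mean of all pairwise alignment scores among the
    reshuffled set, averaged over replicates.
    """
    scheme = scheme or ScoringScheme()
    if len(records) < 2:
        raise ValueError("need at least two records")
    rng = np.random.default_rng(seed)
    aligner = _make_aligner(scheme)
    means = []
    for _ in range(max(1, replicates)):
        shuffled = [reshuffle(r, rng).sequence for r in records]
        total = 0.0
        count = 0
        for i in range(len(shuffled)):
            for j in range(i + 1, len(shuffled)):
                total += float(aligner.score(shuffled[i], shuffled[j]))
                count += 1
        means.append(total / count)
    return float(np.mean(means))
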