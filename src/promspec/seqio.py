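"""Promoter sequence I/O and the coordinate / binary-code conventions.

Coordinate conventions used throughout the package:

* The chain index ``n`` runs 1..L in the 5'->3' direction.
* The promoter-relative coordinate of site ``n`` is ``x = n - L - 1``, so
  the last nucleotide (immediately upstream of the TSS) sits at ``x = -1``
  and the first at ``x = -L``.
* BED interchange converts to 0-based half-open coordinates.

Sequences are stored uppercased over the alphabet {A, C, G, T, N}.  The
weak/strong binary code maps A,T -> W and C,G -> S; reverse-complementing a
quaternary sequence therefore simply reverses its binary code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")

_WS_TABLE = str.maketrans("ATCG", "WWSS")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a FASTA record violates the expected format/alphabet."""


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence, 5'->3' on the annotated gene strand.

    ``tss_offset`` is the chain index of the nucleotide immediately
    upstream of the TSS; by convention this is the last character.
    """

    id: str
    sequence: str
    tss_offset: int = field(default=-1)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - DNA_ALPHABET_N
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )
        if self.tss_offset == -1:
            object.__setattr__(self, "tss_offset", len(seq))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def L(self) -> int:
        return len(self.sequence)

    def position_of(self, n: int) -> int:
        """Promoter-relative coordinate x of chain site n (1-based)."""
        if not 1 <= n <= self.L:
            raise IndexError(f"site {n} outside chain 1..{self.L}")
        return n - self.L - 1

    def site_of(self, x: int) -> int:
        """Chain site n (1-based) of promoter-relative coordinate x."""
        n = x + self.L + 1
        if not 1 <= n <= self.L:
            raise IndexError(f"coordinate {x} outside -{self.L}..-1")
        return n

    def has_ambiguity(self) -> bool:
        return "N" in self.sequence


@dataclass(frozen=True)
class BinarySequence:
    """Weak/strong binary code of a DNA sequence (W = A/T, S = C/G)."""

    code: str

    def __post_init__(self) -> None:
        bad = set(self.code) - {"W", "S"}
        if bad:
            raise ValueError(f"invalid binary characters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.code)

    def __getitem__(self, item):
        return self.code[item]

    def as_array(self) -> np.ndarray:
        """Boolean array, True where the site is strong (S)."""
        return np.frombuffer(self.code.encode(), dtype="S1") == b"S"


def encode_ws(seq: str) -> BinarySequence:
    """Map a DNA string over {A,C,G,T} to the W/S binary code.

    Ambiguity codes are rejected; callers must mask or drop such records
    first (see :func:`drop_ambiguous`).
    """
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"cannot binary-encode sequence with characters {sorted(bad)!r}; "
            "mask or exclude ambiguous records first"
        )
    return BinarySequence(seq.translate(_WS_TABLE))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET_N
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)!r}")
    return seq.translate(_RC_TABLE)[::-1]


def read_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read promoter records from a FASTA file.

    Sequences are uppercased; input order is preserved.  A record with a
    character outside {A,C,G,T,N} raises :class:`FastaParseError` naming
    the record.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[PromoterRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(PromoterRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.L, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_manifest(records: Iterable[PromoterRecord], path: str | Path, source: str = "-") -> None:
    """Write a TSV bookkeeping manifest (id, length, source)."""
    with Path(path).open("w") as fh:
        fh.write("id\tlength\tsource\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.L}\t{source}\n")


def drop_ambiguous(
    records: Iterable[PromoterRecord],
    policy: str = "drop",
    seed: int | None = None,
) -> list[PromoterRecord]:
    """Handle records containing N.

    ``policy='drop'`` excludes them with a logged warning; ``policy='mask'``
    replaces each N with a uniformly random base under ``seed``.
    """
    if policy not in ("drop", "mask"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    rng = np.random.default_rng(seed)
    out: list[PromoterRecord] = []
    for rec in records:
        if not rec.has_ambiguity():
            out.append(rec)
        elif policy == "drop":
            logger.warning("dropping record %s: contains ambiguous bases", rec.id)
        else:
            bases = np.array(list("ACGT"))
            chars = list(rec.sequence)
            for i, c in enumerate(chars):
                if c == "N":
                    chars[i] = str(rng.choice(bases))
            out.append(PromoterRecord(id=rec.id, sequence="".join(chars)))
    return out
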