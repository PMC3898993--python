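"""Base-composition analysis, dinucleotide profiles and the TATA-box scan.

The TATA-box is matched by the degenerate consensus ``HWHWWWWR`` (IUPAC
codes), which expands to 576 quaternary 8-mers; a user-supplied exclusion
list of 44 strings reduces the search catalogue to 532.  Promoters are
labelled TATA if at least one catalogue member occurs exactly, with its
start inside a promoter-relative window (default [-40, -19]), on the given
strand only.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import PromoterRecord

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

TATA_CONSENSUS = "HWHWWWWR"
DEFAULT_TATA_WINDOW = (-40, -19)


def expand_degenerate(consensus: str) -> set[str]:
    """All quaternary strings matching an IUPAC degenerate string."""
    consensus = consensus.upper()
    try:
        pools = [IUPAC_CODES[c] for c in consensus]
    except KeyError as exc:
        raise ValueError(f"unknown IUPAC code {exc.args[0]!r} in {consensus!r}") from exc
    return {"".join(p) for p in itertools.product(*pools)}


def default_exclusion_list(consensus: str = TATA_CONSENSUS, size: int = 44) -> set[str]:
    """Deterministic placeholder exclusion list (first ``size`` members in
    lexicographic order).

    The biologically curated list is not distributed with the package; this
    placeholder reproduces catalogue *counts* only.  Supply a curated list
    for real analyses.
    """
    expanded = sorted(expand_degenerate(consensus))
    if size > len(expanded):
        raise ValueError("exclusion list larger than the expansion")
    return set(expanded[:size])


@dataclass(frozen=True)
class TataCatalog:
    """Search catalogue for the TATA-box scan."""

    consensus: str = TATA_CONSENSUS
    excluded: frozenset[str] = frozenset()
    window: tuple[int, int] = DEFAULT_TATA_WINDOW
    expanded: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        expanded = frozenset(expand_degenerate(self.consensus))
        stray = set(self.excluded) - expanded
        if stray:
            raise ValueError(f"excluded strings not in the expansion: {sorted(stray)[:5]!r}")
        object.__setattr__(self, "expanded", expanded)
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        if self.window[0] > self.window[1]:
            raise ValueError("window start must be <= window end")

    @property
    def members(self) -> frozenset[str]:
        return self.expanded - self.excluded

    @property
    def word_length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class TataScanResult:
    promoter_id: str
    is_tata: bool
    match_positions: tuple[int, ...]  # promoter-relative start coordinates

    @property
    def label(self) -> str:
        return "TATA" if self.is_tata else "TATA-less"


def scan_tata(record: PromoterRecord, catalog: TataCatalog) -> TataScanResult:
    """Exact-match scan of the catalogue inside the search window.

    A match counts when a non-excluded 8-mer starts at a promoter-relative
    coordinate within ``catalog.window``; only the given (top) strand is
    searched.
    """
    w0, w1 = catalog.window
    k = catalog.word_length
    L = record.L
    if w0 < -L or w1 > -1 or w1 + k - 1 > -1:
        raise ValueError(
            f"search window [{w0},{w1}] (+{k}-mer) outside promoter of length {L}"
        )
    members = catalog.members
    hits = []
    for x in range(w0, w1 + 1):
        i = x + L  # 0-based index of the match start
        if record.sequence[i : i + k] in members:
            hits.append(x)
    return TataScanResult(record.id, bool(hits), tuple(hits))


@dataclass(frozen=True)
class BCAProfile:
    """Per-position nucleotide frequencies aligned at the TSS (x = -1)."""

    positions: np.ndarray  # promoter-relative, -m..-1
    freq: pd.DataFrame     # index positions, columns A,T,C,G

    def to_frame(self) -> pd.DataFrame:
        return self.freq.copy()


def bca(records: list[PromoterRecord]) -> BCAProfile:
    """Base-composition analysis over a promoter set.

    Profiles are aligned at the TSS (last nucleotide at x = -1) and
    computed over the common suffix when lengths differ.
    """
    if not records:
        raise ValueError("bca requires a non-empty promoter set")
    m = min(r.L for r in records)
    counts = np.zeros((m, 4), dtype=np.int64)
    order = "ATCG"
    idx = {b: j for j, b in enumerate(order)}
    for rec in records:
        suffix = rec.sequence[-m:]
        for i, c in enumerate(suffix):
            if c in idx:
                counts[i, idx[c]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freq = counts / np.where(totals == 0, 1, totals)
    positions = np.arange(-m, 0)
    df = pd.DataFrame(freq, index=positions, columns=list(order))
    df.index.name = "position"
    return BCAProfile(positions=positions, freq=df)


def dinucleotide_profile(
    records: list[PromoterRecord],
    pairs: list[str],
    window_width: int = 1,
) -> pd.DataFrame:
    """Sliding-window dinucleotide density per promoter-relative position.

    The density at position x is the number of (overlapping) occurrences of
    the pair whose start lies in a window of ``window_width`` start
    positions centred at x, divided by the number of valid start positions
    in the window, averaged over promoters.  Returns a DataFrame indexed by
    position with one column per pair.
    """
    if not records:
        raise ValueError("dinucleotide_profile requires a non-empty set")
    if window_width < 1:
        raise ValueError("window_width must be >= 1")
    for p in pairs:
        if len(p) != 2:
            raise ValueError(f"dinucleotide {p!r} must have length 2")
    m = min(r.L for r in records)
    n_starts = m - 1  # 2-mer start positions in the common suffix
    out = {}
    for pair in pairs:
        acc = np.zeros(n_starts)
        for rec in records:
            suffix = rec.sequence[-m:]
            occ = np.fromiter(
                (suffix[i : i + 2] == pair for i in range(n_starts)),
                dtype=float,
                count=n_starts,
            )
            # centred moving average; edges divide by the valid window size
            kernel = np.ones(window_width)
            num = np.convolve(occ, kernel, mode="same")
            den = np.convolve(np.ones(n_starts), kernel, mode="same")
            acc += num / den
        out[pair] = acc / len(records)
    df = pd.DataFrame(out, index=np.arange(-m, -1))
    df.index.name = "position"
    return df


def composition_counts(seq: str) -> Counter:
    """Multiset of characters; convenience for reshuffle checks."""
    return Counter(seq)
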