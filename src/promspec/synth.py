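"""Synthetic promoter sets with known ground truth.

Two generators are provided:

* :func:`generate` draws a mixture of compositional classes (CG-rich,
  AT-rich, uniform) and optionally plants a long shared element on the
  forward or reverse strand of designated classes — a transposon
  surrogate for exercising the clustering pipeline.

* :func:`plant_regular` embeds literal tracts into a *regularity-free*
  background: the W/S binary code of the background contains no
  homogeneous run of 5+, no 2- or 3-periodic tract of 6+, and no
  mirror-symmetric (palindromic) tract of 7+ — the exact left/right
  degeneracy of a mirror tract hybridizes chain eigenmodes across both
  halves and would light up the region detector.  The background is built
  site by site with backtracking, so planted regularity never bleeds
  across tract junctions.

Truth tables accompany every generated set so tests are self-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .seqio import PromoterRecord, encode_ws, reverse_complement

_BASES = np.array(list("ACGT"))
_W_BASES = np.array(list("AT"))
_S_BASES = np.array(list("CG"))


@dataclass(frozen=True)
class ClassSpec:
    """One mixture class: composition plus an optional planted element."""

    label: str
    proportion: float
    base_probs: Mapping[str, float]
    element: str | None = None  # None, "forward" or "reverse"

    def __post_init__(self) -> None:
        probs = dict(self.base_probs)
        if set(probs) != set("ACGT"):
            raise ValueError("base_probs must cover exactly A,C,G,T")
        if not np.isclose(sum(probs.values()), 1.0):
            raise ValueError(f"class {self.label}: base probabilities must sum to 1")
        if self.element not in (None, "forward", "reverse"):
            raise ValueError(f"class {self.label}: bad element strand {self.element!r}")
        object.__setattr__(self, "base_probs", MappingProxyType(probs))


@dataclass(frozen=True)
class MixturePreset:
    name: str
    classes: tuple[ClassSpec, ...]
    element_fraction: float = 0.6  # planted-element length as a fraction of L

    def __post_init__(self) -> None:
        if not np.isclose(sum(c.proportion for c in self.classes), 1.0):
            raise ValueError("class proportions must sum to 1")
        if not 0 < self.element_fraction < 1:
            raise ValueError("element_fraction must be in (0, 1)")


_UNIFORM = {b: 0.25 for b in "ACGT"}

PRESETS: dict[str, MixturePreset] = {
    "human4": MixturePreset(
        name="human4",
        classes=(
            ClassSpec("A", 0.25, {"A": 0.15, "T": 0.15, "C": 0.35, "G": 0.35}),
            ClassSpec("B", 0.25, {"A": 0.35, "T": 0.35, "C": 0.15, "G": 0.15}),
            ClassSpec("C", 0.25, _UNIFORM, element="forward"),
            ClassSpec("D", 0.25, _UNIFORM, element="reverse"),
        ),
    ),
}


@dataclass
class SynthResult:
    records: list[PromoterRecord]
    truth: pd.DataFrame  # id, label, element_start, element_end, element_strand


def _class_counts(classes: tuple[ClassSpec, ...], n: int) -> list[int]:
    raw = [c.proportion * n for c in classes]
    counts = [int(np.floor(x)) for x in raw]
    remainders = np.argsort([f - c for f, c in zip(raw, counts)])[::-1]
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def generate(
    preset: MixturePreset | str,
    n: int,
    length: int,
    seed: int = 0,
    element: str | None = None,
) -> SynthResult:
    """Draw a labelled synthetic promoter set from a mixture preset.

    Classes with a planted element share one fixed pseudo-random string of
    length ``element_fraction * length`` (override it with ``element``,
    e.g. a real Alu consensus), inserted by overwriting a random window —
    verbatim on forward classes, reverse-complemented on reverse classes.
    Deterministic under ``seed``.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(seed)
    elen = int(round(preset.element_fraction * length))
    if element is None:
        element = "".join(rng.choice(_BASES, size=elen))
    if len(element) > length:
        raise ValueError("planted element longer than the promoter")

    records: list[PromoterRecord] = []
    rows = []
    counts = _class_counts(preset.classes, n)
    idx = 0
    for spec, n_k in zip(preset.classes, counts):
        probs = np.array([spec.base_probs[b] for b in "ACGT"])
        for _ in range(n_k):
            seq = rng.choice(_BASES, size=length, p=probs)
            start = end = -1
            strand = ""
            if spec.element is not None:
                insert = element if spec.element == "forward" else reverse_complement(element)
                pos = int(rng.integers(0, length - len(insert) + 1))
                seq[pos : pos + len(insert)] = list(insert)
                start, end = pos + 1, pos + len(insert)
                strand = "+" if spec.element == "forward" else "-"
            pid = f"{preset.name}_{spec.label}_{idx:04d}"
            idx += 1
            records.append(PromoterRecord(id=pid, sequence="".join(seq)))
            rows.append(
                {
                    "id": pid,
                    "label": spec.label,
                    "element_start": start,
                    "element_end": end,
                    "element_strand": strand,
                }
            )
    truth = pd.DataFrame(rows)
    return SynthResult(records=records, truth=truth)


# ---------------------------------------------------------------------------
# regularity-free backgrounds


def _violation_at(b: np.ndarray, i: int) -> list[tuple[int, int, str]]:
    """Forbidden W/S patterns ending at site i: (lo, hi, kind), 0-based.

    Patterns: homogeneous run of 5 ("run"), 2-/3-periodic tracts of 6
    ("periodic"), and mirror-symmetric windows of length 7 and 8 ("pal";
    every longer palindrome contains one of these at its center).
    """
    spans = []
    if i >= 4 and np.all(b[i - 4 : i + 1] == b[i]):
        spans.append((i - 4, i, "run"))
    # lag-p agreement stretches: M consecutive sites repeating the sites p
    # before them.  (2,4)/(3,3) are the classic 2-/3-periodic tracts of 6;
    # p up to 8 suppresses tandem blocks whose repeated runs act as
    # exactly degenerate resonators for the chain eigenmodes
    for p, M in (
        (2, 4), (3, 3), (4, 4), (5, 4), (6, 4), (7, 4), (8, 4),
        (9, 6), (10, 6), (11, 6), (12, 6),
    ):
        lo = i - p - M + 1
        if lo >= 0 and np.all(b[i - M + 1 : i + 1] == b[i - M + 1 - p : i + 1 - p]):
            spans.append((lo, i, "periodic"))
    # mirror arrangements X^3 Y X^3 / X^3 YY X^3: the two equal runs are
    # degenerate and hybridize into delocalized mode pairs
    for gap in (1, 2):
        span = 6 + gap
        lo = i - span + 1
        if lo >= 0:
            w = b[lo : i + 1]
            c = w[0]
            if (
                np.all(w[:3] == c)
                and np.all(w[-3:] == c)
                and np.all(w[3 : 3 + gap] != c)
            ):
                spans.append((lo, i, "pal"))
    return spans


def find_regular_tracts(binary_code: str) -> list[tuple[int, int]]:
    """Scan a W/S string for the forbidden regular patterns.

    Returns 1-based inclusive spans of every violation; the empty list
    certifies a regularity-free background.  Independent oracle for
    :func:`plant_regular`.
    """
    b = np.frombuffer(binary_code.encode(), dtype="S1") == b"S"
    out = []
    for i in range(len(b)):
        out.extend((lo + 1, hi + 1, kind) for lo, hi, kind in _violation_at(b, i))
    return out


def _exempt(
    violation: tuple[int, int, str], tracts0: list[tuple[int, int]]
) -> bool:
    """Whether a violation is attributable to a planted tract.

    Homogeneous runs must lie fully inside a tract (a run bleeding across
    a junction would change the planted run's effective length).
    Palindromic and periodic patterns are exempt already on overlap: a
    planted run unavoidably mirrors itself across its junctions (e.g.
    W SSSSS W around a 5-tract), and the pinned junction buffers echo
    each other at short lags around short tracts.
    """
    lo, hi, kind = violation
    if kind in ("pal", "periodic"):
        return any(lo <= e and s <= hi for s, e in tracts0)
    return any(s <= lo and hi <= e for s, e in tracts0)


_VIABLE_CACHE: dict[int, frozenset] = {}


_STATE_WIDTH = 11  # longest forbidden pattern spans 12 sites


def _viable_states() -> frozenset:
    """Windows from which an infinite regularity-free tail exists.

    Built once: all violation-free 11-windows, transitions checked on the
    12-window, then co-viability trimmed (states without outgoing edges
    removed iteratively).  Used to prune dead-end choices during
    background generation.
    """
    if 0 in _VIABLE_CACHE:
        return _VIABLE_CACHE[0]
    import itertools

    def clean(w: tuple) -> bool:
        b = np.array(w, dtype=np.int8)
        return all(not _violation_at(b, i) for i in range(len(b)))

    states = {
        w for w in itertools.product((0, 1), repeat=_STATE_WIDTH) if clean(w)
    }
    while True:
        keep = {
            s
            for s in states
            if any(clean(s + (c,)) and (s + (c,))[1:] in states for c in (0, 1))
        }
        if keep == states:
            break
        states = keep
    _VIABLE_CACHE[0] = frozenset(states)
    return _VIABLE_CACHE[0]


def plant_regular(
    length: int,
    tracts: list[tuple[str, int]],
    seed: int = 0,
    record_id: str = "synthetic",
    max_steps_per_site: int = 400,
    junction_buffer: int = 3,
) -> tuple[PromoterRecord, list[tuple[int, int, str]]]:
    """Embed literal tracts in a regularity-free background.

    ``tracts`` is a list of ``(sequence, start)`` with 1-based,
    non-overlapping start positions.  Background sites are chosen W/S by
    depth-first backtracking so that no forbidden regular pattern occurs
    outside the planted coordinates (junction effects included), then
    dressed with uniform A/T or C/G.  The ``junction_buffer`` background
    sites flanking each tract are pinned to the opposite letter of the
    tract's terminal site, so chance same-letter background runs cannot
    resonate with the planted tract and smear its boundary.  Returns the
    record and the truth list ``(start, end, sequence)``.  Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    fixed = np.full(length, -1, dtype=np.int8)
    truth: list[tuple[int, int, str]] = []
    tracts0: list[tuple[int, int]] = []
    quaternary = np.full(length, "", dtype="U1")
    for seq, start in sorted(tracts, key=lambda t: t[1]):
        seq = seq.upper()
        s0, e0 = start - 1, start - 1 + len(seq) - 1
        if s0 < 0 or e0 >= length:
            raise ValueError(f"tract at {start} of length {len(seq)} does not fit")
        if any(s0 <= e and s <= e0 for s, e in tracts0):
            raise ValueError("planted tracts overlap")
        code = encode_ws(seq).code
        fixed[s0 : e0 + 1] = [1 if c == "S" else 0 for c in code]
        quaternary[s0 : e0 + 1] = list(seq)
        tracts0.append((s0, e0))
        truth.append((start, e0 + 1, seq))
    for (s0, e0), (_, _, seq) in zip(tracts0, truth):
        left = 1 - (1 if encode_ws(seq).code[0] == "S" else 0)
        right = 1 - (1 if encode_ws(seq).code[-1] == "S" else 0)
        for d in range(1, junction_buffer + 1):
            if s0 - d >= 0 and fixed[s0 - d] < 0:
                fixed[s0 - d] = left
            if e0 + d < length and fixed[e0 + d] < 0:
                fixed[e0 + d] = right

    b = np.full(length, -1, dtype=np.int8)
    viable = _viable_states()
    free = fixed < 0
    # state pruning applies where the trailing state window and the next
    # sites are all background (tract junctions fall back to plain DFS)
    w = _STATE_WIDTH
    prunable = np.zeros(length, dtype=bool)
    for i in range(w - 1, length):
        if free[i - w + 1 : i + 1].all() and free[i + 1 : i + w + 2].all():
            prunable[i] = True

    def admissible(i: int) -> bool:
        if any(not _exempt(v, tracts0) for v in _violation_at(b, i)):
            return False
        if prunable[i] and tuple(b[i - w + 1 : i + 1]) not in viable:
            return False
        return True

    # per-free-site stack of untried choices (shuffled for uniformity)
    choices: list[list[int]] = [[] for _ in range(length)]
    i = 0
    steps = 0
    budget = max_steps_per_site * length
    while i < length:
        steps += 1
        if steps > budget:
            raise RuntimeError(
                "could not build a regularity-free background within the "
                "step budget; relax the constraints or change the seed"
            )
        if fixed[i] >= 0:
            b[i] = fixed[i]
            if admissible(i):
                i += 1
                continue
        else:
            if not choices[i] and b[i] == -1:
                opts = [0, 1]
                rng.shuffle(opts)
                choices[i] = opts
            placed = False
            while choices[i]:
                b[i] = choices[i].pop()
                if admissible(i):
                    placed = True
                    break
            if placed:
                i += 1
                continue
        # dead end: rewind to the previous free site with options left
        b[i] = -1
        if fixed[i] < 0:
            choices[i] = []
        j = i - 1
        while j >= 0 and (fixed[j] >= 0 or not choices[j]):
            b[j] = -1
            if fixed[j] < 0:
                choices[j] = []
            j -= 1
        if j < 0:
            raise RuntimeError("infeasible tract layout: backtracked past the origin")
        b[j] = -1
        i = j

    undressed = quaternary == ""
    w_free = undressed & (b == 0)
    s_free = undressed & (b == 1)
    quaternary[w_free] = rng.choice(_W_BASES, size=int(w_free.sum()))
    quaternary[s_free] = rng.choice(_S_BASES, size=int(s_free.sum()))
    record = PromoterRecord(id=record_id, sequence="".join(quaternary))
    return record, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
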