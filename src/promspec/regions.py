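"""Regular-region detection from delocalized eigenvectors, and cataloguing.

A tract of a promoter is *regular* (homogeneous, periodic or palindromic
in the W/S code) when the chain eigenvectors overlying it are delocalized.
Detection proceeds in two steps:

I/II.  every eigenvector with participation number P >= P_thr is declared
       delocalized and assigned an effective interval [s, e] from its
       cumulative-mass tails;
III.   overlap-connected intervals form mode groups; within each group the
       best-fitting candidate region is the one whose contained-mode count
       n matches its length m within a 30% tolerance (an isolated regular
       region of m sites carries exactly m modes).

Accepted candidates are refined at the boundaries — extended along their
own W/S periodicity and closed over overlapping localized modes, since the
terminal sites of a regular tract carry only strongly localized modes —
and regions shorter than ``min_len`` (default 7 nt, the method's stated
minimum) are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pb import HessianSpectrum, spectrum_indicators
from .seqio import PromoterRecord, encode_ws

DEFAULT_P_THR = 4.0
DEFAULT_TOL = 0.3
DEFAULT_MIN_LEN = 7


@dataclass(frozen=True)
class RegularRegion:
    """An accepted regular tract, 1-based inclusive chain coordinates."""

    promoter_id: str
    s: int
    e: int
    quaternary: str
    binary: str
    n_support: int

    @property
    def length(self) -> int:
        return self.e - self.s + 1


def _components(intervals: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group intervals into overlap-connected components."""
    comps: list[list[tuple[int, int]]] = []
    hi = None
    for iv in sorted(intervals):
        if hi is not None and iv[0] <= hi:
            comps[-1].append(iv)
            hi = max(hi, iv[1])
        else:
            comps.append([iv])
            hi = iv[1]
    return comps


def _accept_component(
    comp: list[tuple[int, int]], tol: float
) -> tuple[int, int, int] | None:
    """Best-fitting sub-interval of a mode group under the count criterion.

    Candidate regions take their boundaries from the start/end values of
    the group's intervals (so a single mode with a wide tail-determined
    interval cannot distort an otherwise consistent region).  Among all
    candidates whose contained-mode count n matches their length m within
    ``tol`` (|n - m| <= tol * m), the tightest fit wins: smallest
    |n - m| / m, then largest m, then leftmost.  Returns (s, e,
    n_support) or None when no candidate passes.
    """
    starts = np.array(sorted({iv[0] for iv in comp}))
    ends = np.array(sorted({iv[1] for iv in comp}))
    s_idx = {v: i for i, v in enumerate(starts)}
    e_idx = {v: i for i, v in enumerate(ends)}
    H = np.zeros((len(starts), len(ends)))
    for s, e in comp:
        H[s_idx[s], e_idx[e]] += 1
    # count[i, j] = #modes with start >= starts[i] and end <= ends[j]
    count = np.cumsum(np.cumsum(H[::-1], axis=0)[::-1], axis=1)
    m = ends[None, :] - starts[:, None] + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(count - m) / m
    passing = (m >= 1) & (np.abs(count - m) <= tol * m)
    if not passing.any():
        return None
    # lexsort on the flattened passing set: ratio, then -m, then start
    flat = np.flatnonzero(passing.ravel())
    order = np.lexsort(
        (
            np.repeat(starts, len(ends))[flat],
            -m.ravel()[flat],
            ratio.ravel()[flat],
        )
    )
    best = flat[order[0]]
    bi, bj = divmod(best, len(ends))
    return int(starts[bi]), int(ends[bj]), int(count[bi, bj])


def _extend_periodic(
    s: int, e: int, code: str, max_period: int = 9
) -> tuple[int, int]:
    """Extend an accepted region along its own W/S periodicity.

    If the region is consistent with some period p (homopolymers satisfy
    p = 1, tandem structures their block length), its true boundary is
    where the periodicity breaks, which may lie a few sites beyond the
    delocalized-mode intervals (terminal sites of a regular tract carry
    only localized modes).  Extension is symmetric in the two directions,
    so detection commutes with sequence reversal.  ``code`` is the full
    W/S string; s, e are 1-based.
    """
    best = (s, e)
    m0 = e - s + 1
    for p in range(1, min(max_period, m0 - 1) + 1):
        if any(code[j] != code[j + p] for j in range(s - 1, e - p)):
            continue
        s2, e2 = s, e
        while s2 > 1 and code[s2 - 2] == code[s2 - 2 + p]:
            s2 -= 1
        while e2 < len(code) and code[e2] == code[e2 - p]:
            e2 += 1
        if e2 - s2 > best[1] - best[0]:
            best = (s2, e2)
    return best


def _complete_boundaries(
    s: int, e: int, all_intervals: list[tuple[int, int]], tol: float
) -> tuple[int, int]:
    """Absorb overlapping sub-threshold modes into the accepted region.

    An isolated regular tract of m sites owns all m of its eigenmodes,
    but its terminal sites often carry only strongly localized ones
    (below any participation threshold), so the merged delocalized
    intervals stop a site or two short.  Take the closure of the region
    under union with every mode interval overlapping it; if the closure
    would grow the region by more than ``tol``-fraction (a background
    mode chain, not a boundary effect), keep the original bounds.
    """
    m0 = e - s + 1
    s2, e2 = s, e
    while True:
        blockers = [
            iv
            for iv in all_intervals
            if iv[0] <= e2 and iv[1] >= s2 and (iv[0] < s2 or iv[1] > e2)
        ]
        if not blockers:
            break
        s2 = min([s2] + [iv[0] for iv in blockers])
        e2 = max([e2] + [iv[1] for iv in blockers])
        if (e2 - s2 + 1) - m0 > tol * m0:
            return s, e
    return s2, e2


def detect_regions(
    spectrum: HessianSpectrum,
    record: PromoterRecord | None = None,
    P_thr: float = DEFAULT_P_THR,
    eps: float = 0.01,
    delta: float = 1e-4,
    tol: float = DEFAULT_TOL,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[RegularRegion]:
    """Regular regions of one promoter from its Hessian spectrum.

    When ``record`` is given, its sequence fills the quaternary/binary
    fields (it must match the spectrum length); otherwise those fields are
    empty strings.  Output is deterministic and sorted by start site.
    """
    ind = spectrum_indicators(spectrum, eps=eps, delta=delta)
    all_intervals = [(i.s, i.e) for i in ind]
    selected = [(i.s, i.e) for i in ind if i.P >= P_thr]
    regions: list[RegularRegion] = []
    if record is not None and record.L != spectrum.L:
        raise ValueError("record length does not match spectrum length")
    seq = record.sequence if record is not None else ""
    binary = encode_ws(seq).code if seq else ""
    pid = record.id if record is not None else ""
    pending = _components(selected)
    accepted: list[tuple[int, int, int]] = []
    while pending:
        comp = pending.pop()
        hit = _accept_component(comp, tol)
        if hit is None:
            continue
        s, e, n_support = hit
        # modes whose intervals fell outside the accepted region may still
        # support a separate region; requeue the non-overlapping ones
        leftovers = [iv for iv in comp if iv[1] < s or iv[0] > e]
        if leftovers:
            pending.extend(_components(leftovers))
        if binary:
            s, e = _extend_periodic(s, e, binary)
        s2, e2 = _complete_boundaries(s, e, all_intervals, tol)
        n2 = sum(1 for iv in selected if s2 <= iv[0] and iv[1] <= e2)
        # keep the completed bounds only while the count criterion holds
        if abs(n2 - (e2 - s2 + 1)) <= tol * (e2 - s2 + 1):
            s, e = s2, e2
        n_support = sum(1 for iv in selected if s <= iv[0] and iv[1] <= e)
        if e - s + 1 < min_len:
            continue
        accepted.append((s, e, n_support))
    # completion may make neighbouring regions touch; clip overlaps
    accepted.sort()
    pruned: list[tuple[int, int, int]] = []
    for s, e, n in accepted:
        if pruned and s <= pruned[-1][1]:
            s = pruned[-1][1] + 1
            if e - s + 1 < min_len:
                continue
        pruned.append((s, e, n))
    for s, e, n_support in pruned:
        regions.append(
            RegularRegion(
                promoter_id=pid,
                s=s,
                e=e,
                quaternary=seq[s - 1 : e] if seq else "",
                binary=binary[s - 1 : e] if binary else "",
                n_support=n_support,
            )
        )
    return sorted(regions, key=lambda r: r.s)


def coverage_fraction(regions: list[RegularRegion], L: int) -> float:
    """Fraction of the promoter covered by (non-overlapping) regions."""
    spans = sorted((r.s, r.e) for r in regions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("regions overlap; merge before computing coverage")
    return sum(e - s + 1 for s, e in spans) / L


def mean_coverage_fraction(
    regions_by_promoter: dict[str, list[RegularRegion]],
    lengths: dict[str, int],
) -> float:
    """Average coverage fraction over a promoter set."""
    if not regions_by_promoter:
        raise ValueError("empty promoter set")
    fracs = [
        coverage_fraction(regs, lengths[pid])
        for pid, regs in regions_by_promoter.items()
    ]
    return sum(fracs) / len(fracs)


def length_histogram(regions: list[RegularRegion]) -> dict[int, int]:
    """Counts of region lengths; the counts sum to the number of regions."""
    return dict(sorted(Counter(r.length for r in regions).items()))


def count_occurrences(motif: str, sequence: str) -> list[int]:
    """1-based start positions of (overlapping) exact occurrences."""
    hits = []
    start = sequence.find(motif)
    while start != -1:
        hits.append(start + 1)
        start = sequence.find(motif, start + 1)
    return hits


@dataclass(frozen=True)
class MotifCatalogEntry:
    """One regular-sequence string with per-cluster statistics."""

    sequence: str
    n_promoters: int
    promoter_pct: float
    n_occurrences: int
    mean_copies: float
    pct_in_transposon: float | None  # None when no annotation supplied


def catalog(
    regions_by_promoter: dict[str, list[RegularRegion]],
    cluster_records: list[PromoterRecord],
    repeat_intervals=None,
    top_k: int = 15,
    overlap_rule: str = "contained",
) -> list[MotifCatalogEntry]:
    """Top regular-sequence strings of a cluster, ranked by spread.

    Distinct quaternary strings of the detected regions are re-counted by
    exact (overlapping) substring search over every cluster promoter on
    the given strand.  Ranking: promoters containing the motif, then total
    occurrences, then lexicographic.  When ``repeat_intervals`` (an
    iterable of :class:`promspec.repeats.RepeatInterval`) is supplied, the
    fraction of occurrences falling inside a repeat is reported; otherwise
    the column is None.
    """
    from .repeats import occurrence_in_repeat

    motifs = {
        r.quaternary
        for regs in regions_by_promoter.values()
        for r in regs
        if r.quaternary
    }
    n_cluster = len(cluster_records)
    entries: list[MotifCatalogEntry] = []
    for motif in motifs:
        occs: list[tuple[str, int, int]] = []  # (promoter_id, start, end)
        n_prom = 0
        for rec in cluster_records:
            starts = count_occurrences(motif, rec.sequence)
            if starts:
                n_prom += 1
                occs.extend((rec.id, st, st + len(motif) - 1) for st in starts)
        if n_prom == 0:
            continue
        pct_tp = None
        if repeat_intervals is not None:
            pct_tp = occurrence_in_repeat(occs, repeat_intervals, rule=overlap_rule)
        entries.append(
            MotifCatalogEntry(
                sequence=motif,
                n_promoters=n_prom,
                promoter_pct=n_prom / n_cluster,
                n_occurrences=len(occs),
                mean_copies=len(occs) / n_prom,
                pct_in_transposon=pct_tp,
            )
        )
    entries.sort(key=lambda e: (-e.n_promoters, -e.n_occurrences, e.sequence))
    return entries[:top_k]


def regions_to_bed(regions: list[RegularRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open; name = quaternary string)."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.promoter_id}\t{r.s - 1}\t{r.e}\t{r.quaternary}\n")
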