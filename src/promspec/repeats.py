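"""Repeat-annotation parsing and transposon-overlap statistics.

Annotations arrive either as RepeatMasker ``.out`` tables (whitespace
columns after a 3-line header) or as BED intervals, both in promoter-local
coordinates.  Internally intervals are 1-based inclusive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from .seqio import PromoterRecord


@dataclass(frozen=True)
class RepeatInterval:
    """One annotated repeat, promoter-local 1-based inclusive."""

    promoter_id: str
    start: int
    end: int
    family: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")


def _parse_bed_line(line: str, lineno: int) -> RepeatInterval:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: not a BED interval: {line!r}")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else "repeat"
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
    return RepeatInterval(chrom, start + 1, end, name, strand)


def _parse_rm_line(line: str, lineno: int) -> RepeatInterval:
    # columns: SW pct_div pct_del pct_ins query q_begin q_end q_left strand
    #          repeat class/family r_begin r_end r_left id
    fields = line.split()
    if len(fields) < 11:
        raise ValueError(f"line {lineno}: not a RepeatMasker row: {line!r}")
    query = fields[4]
    start, end = int(fields[5]), int(fields[6])
    strand = "-" if fields[8] in ("C", "-") else "+"
    family = fields[10]
    return RepeatInterval(query, start, end, family, strand)


def parse_repeatmasker(path: str | Path) -> list[RepeatInterval]:
    """Read repeat intervals from a RepeatMasker ``.out`` file or BED.

    The RepeatMasker dialect is detected by its banner header (or by rows
    whose 2nd/3rd fields are not integers); the parser is tolerant to
    column spacing.  An empty file yields an empty list.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    intervals: list[RepeatInterval] = []
    is_rm = any(
        ln.lstrip().lower().startswith(("sw", "score")) for ln in lines[:3]
    )
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if is_rm and (
            line.lower().startswith(("sw", "score", "there were no"))
            or not line[0].isdigit()
        ):
            continue  # header/banner lines
        try:
            if is_rm:
                intervals.append(_parse_rm_line(line, lineno))
            else:
                intervals.append(_parse_bed_line(line, lineno))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: cannot parse line {lineno}: {raw!r}") from exc
    return intervals


def _merge(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def cluster_coverage(
    intervals: list[RepeatInterval],
    cluster_records: list[PromoterRecord],
) -> tuple[float, dict[str, float]]:
    """Percent of cluster nucleotides covered by repeats, total and per family.

    Total coverage merges overlapping intervals per promoter (union
    semantics); per-family percentages are computed family by family
    without merging across families.  Returns (total_pct, {family: pct}),
    both on a 0-100 scale.
    """
    lengths = {r.id: r.L for r in cluster_records}
    total_nt = sum(lengths.values())
    if total_nt == 0:
        raise ValueError("empty cluster")
    by_prom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    by_fam: dict[str, dict[str, list[tuple[int, int]]]] = defaultdict(lambda: defaultdict(list))
    for iv in intervals:
        if iv.promoter_id not in lengths:
            continue
        if iv.end > lengths[iv.promoter_id]:
            raise ValueError(
                f"interval [{iv.start},{iv.end}] exceeds promoter "
                f"{iv.promoter_id} of length {lengths[iv.promoter_id]}"
            )
        by_prom[iv.promoter_id].append((iv.start, iv.end))
        by_fam[iv.family][iv.promoter_id].append((iv.start, iv.end))
    covered = sum(
        e - s + 1 for spans in by_prom.values() for s, e in _merge(spans)
    )
    per_family = {
        fam: 100.0
        * sum(e - s + 1 for spans in proms.values() for s, e in _merge(spans))
        / total_nt
        for fam, proms in by_fam.items()
    }
    return 100.0 * covered / total_nt, per_family


def occurrence_in_repeat(
    occurrences: list[tuple[str, int, int]],
    intervals: list[RepeatInterval],
    rule: str = "contained",
) -> float | None:
    """Fraction of motif occurrences that fall inside an annotated repeat.

    An occurrence ``(promoter_id, start, end)`` (1-based inclusive) counts
    as inside when its full span lies within a single repeat interval
    (``rule='contained'``, the default) or when it overlaps one at all
    (``rule='any_overlap'``).  Returns None for an empty occurrence list.
    """
    if rule not in ("contained", "any_overlap"):
        raise ValueError(f"unknown overlap rule {rule!r}")
    if not occurrences:
        return None
    by_prom: dict[str, list[RepeatInterval]] = defaultdict(list)
    for iv in intervals:
        by_prom[iv.promoter_id].append(iv)
    inside = 0
    for pid, start, end in occurrences:
        for iv in by_prom.get(pid, ()):
            if rule == "contained" and iv.start <= start and end <= iv.end:
                inside += 1
                break
            if rule == "any_overlap" and start <= iv.end and iv.start <= end:
                inside += 1
                break
    return inside / len(occurrences)


def write_bed(intervals: list[RepeatInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open)."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.promoter_id}\t{iv.start - 1}\t{iv.end}\t{iv.family}\t0\t{iv.strand}\n"
            )
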