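"""Genomic coordinate primitives.

All coordinates are 0-based, half-open (BED convention): an interval
[start, end) covers bases start .. end-1.  Two intervals overlap iff they
share at least one base; abutting intervals ([0,100) and [100,200)) do not
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span on a named sequence.

    ``strand`` is '+', '-' or '.' (unstranded).  Intervals sort by
    (chrom, start, end), which is the order every sweep in this package
    relies on.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 base (same chrom, half-open logic)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(xs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping intervals into their union spans.

    Returns a sorted list of pairwise non-overlapping intervals covering
    exactly the same bases as the input.  Abutting intervals are *not*
    merged (no shared base).  Idempotent.  Strand is dropped ('.'), since
    a union of mixed-strand spans has no strand.
    """
    xs = sorted(xs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in xs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def group_by_chrom(xs: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    by: dict[str, list[GenomicInterval]] = {}
    for iv in xs:
        by.setdefault(iv.chrom, []).append(iv)
    for vs in by.values():
        vs.sort(key=lambda iv: (iv.start, iv.end))
    return by


def any_overlap_flags(
    queries: Sequence[GenomicInterval], references: Sequence[GenomicInterval]
) -> list[bool]:
    """For each query, whether it overlaps >= 1 reference interval.

    Binary search over merged, sorted references per chromosome.
    """
    import bisect

    merged = group_by_chrom(merge_intervals(references))
    starts = {c: [iv.start for iv in ivs] for c, ivs in merged.items()}
    flags: list[bool] = []
    for q in queries:
        ivs = merged.get(q.chrom)
        if not ivs:
            flags.append(False)
            continue
        # rightmost reference starting before q.end; merged refs are disjoint,
        # so only that one can reach back into q.
        i = bisect.bisect_left(starts[q.chrom], q.end) - 1
        flags.append(i >= 0 and ivs[i].end > q.start)
    return flags


def covered_bases(xs: Iterable[GenomicInterval]) -> int:
    """Total number of distinct bases covered by the input intervals."""
    return sum(iv.length for iv in merge_intervals(xs))
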