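"""Replicate q-value filtering and >=k-of-n consensus peak calling.

A locus is a consensus peak for a condition when peaks from at least
``min_support`` distinct biological replicates mutually overlap
(transitively, through shared bases).  The consensus interval is the
union of every replicate peak in that overlap component, so every
supported base is retained and the result is invariant to replicate
order.  Replicate peaks are filtered beforehand on the upstream caller's
q-value: strictly greater than the -log10 threshold (default 6, i.e.
q < 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import GenomicInterval, merge_intervals


@dataclass(frozen=True)
class ReplicatePeak:
    interval: GenomicInterval
    neglog10_q: float
    signal: float = 0.0
    replicate_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.neglog10_q < 0:
            raise ValueError("neglog10_q must be >= 0")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")


@dataclass(frozen=True)
class ConsensusPeak:
    interval: GenomicInterval
    support_count: int
    replicate_ids: tuple[str, ...]


@dataclass
class ConsensusPeakSet:
    condition: str
    peaks: list[ConsensusPeak] = field(default_factory=list)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


def filter_by_qvalue(
    peaks: Iterable[ReplicatePeak], min_neglog10_q: float = 6.0
) -> list[ReplicatePeak]:
    """Retain peaks with -log10(q) strictly greater than the threshold."""
    if min_neglog10_q < 0:
        raise ValueError("threshold must be >= 0")
    return [p for p in peaks if p.neglog10_q > min_neglog10_q]


def call_consensus(
    replicate_sets: Sequence[Sequence[ReplicatePeak]],
    min_support: int = 2,
    condition: str = "",
) -> ConsensusPeakSet:
    """Overlap-component voting across replicates.

    Peaks from all replicates are pooled and swept in coordinate order;
    a maximal run of transitively overlapping peaks forms one component.
    Components whose peaks come from >= ``min_support`` distinct
    replicates yield one consensus peak spanning the union of the
    component.  A single replicate contributing several peaks counts as
    support 1.
    """
    n_reps = len(replicate_sets)
    if not (1 <= min_support <= n_reps):
        raise ValueError(
            f"min_support={min_support} unsatisfiable with {n_reps} replicate sets"
        )
    tagged: list[tuple[GenomicInterval, str]] = []
    for i, reps in enumerate(replicate_sets):
        for p in reps:
            rep_id = p.replicate_id or f"rep{i + 1}"
            tagged.append((p.interval, rep_id))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    out: list[ConsensusPeak] = []
    comp: list[tuple[GenomicInterval, str]] = []

    def flush() -> None:
        if not comp:
            return
        reps = sorted({r for _, r in comp})
        if len(reps) >= min_support:
            start = min(iv.start for iv, _ in comp)
            end = max(iv.end for iv, _ in comp)
            out.append(
                ConsensusPeak(
                    GenomicInterval(comp[0][0].chrom, start, end),
                    len(reps),
                    tuple(reps),
                )
            )

    cur_chrom, cur_end = None, -1
    for iv, rep in tagged:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            comp.append((iv, rep))
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            comp = [(iv, rep)]
            cur_chrom, cur_end = iv.chrom, iv.end
    flush()
    return ConsensusPeakSet(condition=condition, peaks=out)


@dataclass(frozen=True)
class MergedPeak:
    """Cross-condition quantitation locus, tagged with contributing conditions."""

    interval: GenomicInterval
    conditions: tuple[str, ...]

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


def merge_conditions(sets: Sequence[ConsensusPeakSet]) -> list[MergedPeak]:
    """Union of all conditions' consensus intervals, merged.

    Each merged interval records which conditions contributed >= 1
    consensus peak overlapping it.
    """
    if not sets:
        raise ValueError("need >= 1 consensus peak set")
    merged = merge_intervals(iv for s in sets for iv in s.intervals)
    out: list[MergedPeak] = []
    for iv in merged:
        conds = tuple(
            s.condition
            for s in sets
            if any(
                p.chrom == iv.chrom and p.start < iv.end and iv.start < p.end
                for p in s.intervals
            )
        )
        out.append(MergedPeak(iv, conds))
    return out
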