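"""Gene models and TSS-window feature annotation.

A peak is classified into exactly one of four feature classes relative to
the gene models: promoter (oriented TSS window [-1000, +500)), enhancer
([-10000, -1000)), gene body, or distal.  Distances are signed in the
gene's orientation: negative = upstream of the TSS.

The TSS of a '+' gene is tx_start; of a '-' gene, tx_end (the half-open
end coordinate), so the oriented distance of a position m is
``m - tss`` on '+' and ``tss - m`` on '-'.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .intervals import GenomicInterval

PROMOTER_WINDOW = (-1000, 500)
ENHANCER_WINDOW = (-10000, -1000)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    symbol: Optional[str] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError("require tx_start < tx_end")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    def oriented_distance(self, position: int) -> int:
        """Signed TSS distance of a genomic position (upstream negative)."""
        return position - self.tss if self.strand == "+" else self.tss - position

    def window_interval(self, lo: int, hi: int) -> GenomicInterval:
        """Genomic interval of the oriented TSS window [lo, hi)."""
        if self.strand == "+":
            start, end = self.tss + lo, self.tss + hi
        else:
            start, end = self.tss - hi, self.tss - lo
        return GenomicInterval(self.chrom, max(0, start), max(1, end), self.strand)

    def promoter(self, window: tuple[int, int] = PROMOTER_WINDOW) -> GenomicInterval:
        return self.window_interval(*window)


class FeatureClass(str, enum.Enum):
    PROMOTER = "promoter"
    ENHANCER = "enhancer"
    GENE_BODY = "gene_body"
    DISTAL = "distal"


_PRECEDENCE = {
    FeatureClass.PROMOTER: 0,
    FeatureClass.ENHANCER: 1,
    FeatureClass.GENE_BODY: 2,
    FeatureClass.DISTAL: 3,
}


@dataclass(frozen=True)
class FeatureAssignment:
    peak: GenomicInterval
    feature_class: FeatureClass
    gene_id: Optional[str]
    tss_distance: Optional[int]


def tss_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    """Signed distance from the gene TSS to the peak midpoint.

    Measured in the gene's orientation (upstream negative); the midpoint
    is floor((start + end) / 2).
    """
    return gene.oriented_distance(peak.midpoint)


def _classify_for_gene(
    d: int,
    peak: GenomicInterval,
    gene: GeneModel,
    promoter_window: tuple[int, int],
    enhancer_window: tuple[int, int],
    mode: str,
) -> Optional[FeatureClass]:
    if mode == "midpoint":
        if promoter_window[0] <= d < promoter_window[1]:
            return FeatureClass.PROMOTER
        if enhancer_window[0] <= d < enhancer_window[1]:
            return FeatureClass.ENHANCER
        if 0 <= d < gene.length:
            return FeatureClass.GENE_BODY
        return None
    # full-interval overlap mode: any shared base with the genomic window
    from .intervals import overlaps

    for cls, win in (
        (FeatureClass.PROMOTER, promoter_window),
        (FeatureClass.ENHANCER, enhancer_window),
    ):
        if overlaps(peak, gene.window_interval(*win)):
            return cls
    body = GenomicInterval(gene.chrom, gene.tx_start, gene.tx_end)
    if overlaps(peak, body):
        return FeatureClass.GENE_BODY
    return None


def assign_feature(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    enhancer_window: tuple[int, int] = ENHANCER_WINDOW,
    mode: str = "midpoint",
) -> FeatureAssignment:
    """Assign exactly one feature class to a peak.

    Precedence across genes: promoter > enhancer > gene_body > distal.
    Ties within a class are broken by smallest ``|tss_distance|`` of the
    peak midpoint, then by gene_id for determinism.  ``mode='midpoint'``
    (default) decides membership by the peak midpoint, so classes are
    mutually exclusive by construction; ``mode='overlap'`` uses >=1 bp
    full-interval overlap with the genomic window.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError("mode must be 'midpoint' or 'overlap'")
    best: Optional[tuple[int, int, str, FeatureClass, GeneModel, int]] = None
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        d = tss_distance(peak, gene)
        cls = _classify_for_gene(d, peak, gene, promoter_window, enhancer_window, mode)
        if cls is None:
            continue
        key = (_PRECEDENCE[cls], abs(d), gene.gene_id, cls, gene, d)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        return FeatureAssignment(peak, FeatureClass.DISTAL, None, None)
    _, _, _, cls, gene, d = best
    return FeatureAssignment(peak, cls, gene.gene_id, d)


def assign_features(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    enhancer_window: tuple[int, int] = ENHANCER_WINDOW,
    mode: str = "midpoint",
) -> list[FeatureAssignment]:
    """Annotate every peak (totality: one assignment per peak).

    Gene lookup is pre-bucketed by chromosome so annotation stays linear
    in practice for the locally dense gene sets this package handles.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return [
        assign_feature(
            p, by_chrom.get(p.chrom, ()), promoter_window, enhancer_window, mode
        )
        for p in peaks
    ]


def class_counts(assignments: Sequence[FeatureAssignment]) -> dict[str, int]:
    out = {c.value: 0 for c in FeatureClass}
    for a in assignments:
        out[a.feature_class.value] += 1
    return out
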