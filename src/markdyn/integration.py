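"""Chromatin-to-transcription integration.

* Pearson partitioning of promoter binding against expression
  trajectories at strict +/-0.8 thresholds;
* a boolean gene x timepoint x mark promoter-occupancy ledger with
  combination fractions and transition flows between consecutive ages;
* peak-set colocalization percentages per feature class;
* hypergeometric gene-set over-representation with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffbind import bh_adjust
from .genes import FeatureAssignment, GeneModel, PROMOTER_WINDOW
from .intervals import GenomicInterval, any_overlap_flags

POS_THRESHOLD = 0.8
NEG_THRESHOLD = -0.8


# ------------------------------------------------------ correlation partition


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r; NaN when either vector is constant."""
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CorrelationPartition:
    pairs: pd.DataFrame  # peak_id, gene_id, pearson_r, corr_class, flagged
    genes: pd.DataFrame  # gene_id -> representative peak, r, class


def correlate_binding_expression(
    binding: pd.DataFrame,
    expression: pd.DataFrame,
    peak_gene_map: pd.DataFrame,
    pos_threshold: float = POS_THRESHOLD,
    neg_threshold: float = NEG_THRESHOLD,
) -> CorrelationPartition:
    """Per peak-gene Pearson r across shared timepoints, classified strictly.

    ``binding``: peaks x timepoints normalized abundance (replicate-
    averaged); ``expression``: genes x timepoints; ``peak_gene_map``:
    columns peak_id, gene_id and optionally ``start`` (genomic
    coordinate, used to break max-|r| ties toward the lower coordinate
    when choosing a gene's representative peak).  A pair with a constant
    binding or expression vector has undefined r: it is classified
    neutral and flagged.
    """
    shared = [t for t in binding.columns if t in expression.columns]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared timepoints between binding and expression, got {shared}"
        )
    rows = []
    for rec in peak_gene_map.itertuples():
        peak_id, gene_id = rec.peak_id, rec.gene_id
        if peak_id not in binding.index or gene_id not in expression.index:
            continue
        r = _pearson(
            binding.loc[peak_id, shared].values.astype(float),
            expression.loc[gene_id, shared].values.astype(float),
        )
        if np.isnan(r):
            cls, flagged = "neutral", True
        elif r > pos_threshold:
            cls, flagged = "positive", False
        elif r < neg_threshold:
            cls, flagged = "negative", False
        else:
            cls, flagged = "neutral", False
        rows.append(
            {
                "peak_id": peak_id,
                "gene_id": gene_id,
                "pearson_r": r,
                "corr_class": cls,
                "flagged": flagged,
                "start": getattr(rec, "start", 0),
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=["peak_id", "gene_id", "pearson_r", "corr_class", "flagged", "start"],
    )
    gene_rows = []
    for gene_id, sub in pairs.groupby("gene_id", sort=True):
        sub = sub.assign(abs_r=sub.pearson_r.abs().fillna(-1.0))
        best = sub.sort_values(
            ["abs_r", "start", "peak_id"], ascending=[False, True, True]
        ).iloc[0]
        gene_rows.append(
            {
                "gene_id": gene_id,
                "peak_id": best.peak_id,
                "pearson_r": best.pearson_r,
                "corr_class": best.corr_class,
            }
        )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "peak_id", "pearson_r", "corr_class"]
    )
    return CorrelationPartition(pairs.drop(columns=["start"]), genes)


# ----------------------------------------------------------- occupancy ledger


class OccupancyLedger:
    """Boolean gene x timepoint x mark presence tensor.

    Timepoints are kept in the given (developmental) order; marks and
    genes are kept sorted for determinism.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        timepoints: Sequence[str],
        marks: Sequence[str],
    ):
        values = np.asarray(values, dtype=bool)
        if values.shape != (len(gene_ids), len(timepoints), len(marks)):
            raise ValueError("ledger shape mismatch")
        self.values = values
        self.gene_ids = list(gene_ids)
        self.timepoints = list(timepoints)
        self.marks = list(marks)

    def slice(self, mark: str) -> pd.DataFrame:
        m = self.marks.index(mark)
        return pd.DataFrame(
            self.values[:, :, m], index=self.gene_ids, columns=self.timepoints
        )

    def to_long(self) -> pd.DataFrame:
        recs = []
        for gi, g in enumerate(self.gene_ids):
            for ti, t in enumerate(self.timepoints):
                for mi, m in enumerate(self.marks):
                    recs.append(
                        {
                            "gene_id": g,
                            "timepoint": t,
                            "mark": m,
                            "present": bool(self.values[gi, ti, mi]),
                        }
                    )
        return pd.DataFrame(recs)


def build_occupancy_ledger(
    peak_sets: Mapping[tuple[str, str], Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    marks: Sequence[str] | None = None,
    timepoints: Sequence[str] | None = None,
    biotype: str | None = "protein_coding",
) -> OccupancyLedger:
    """Promoter presence per (gene, timepoint, mark): any >= 1 bp overlap
    between a peak of that mark/timepoint and the gene's promoter window.

    ``peak_sets`` keys are (mark, timepoint).  The mark x timepoint grid
    must be complete; missing cells raise with the full list.
    """
    marks = sorted({m for m, _ in peak_sets}) if marks is None else list(marks)
    if timepoints is None:
        timepoints = sorted({t for _, t in peak_sets})
    missing = [
        (m, t) for m in marks for t in timepoints if (m, t) not in peak_sets
    ]
    if missing:
        raise ValueError(f"incomplete mark x timepoint grid; missing cells: {missing}")
    if biotype is not None:
        genes = [g for g in genes if g.biotype == biotype]
    genes = sorted(genes, key=lambda g: g.gene_id)
    promoters = [g.promoter(promoter_window) for g in genes]
    values = np.zeros((len(genes), len(timepoints), len(marks)), dtype=bool)
    for mi, m in enumerate(marks):
        for ti, t in enumerate(timepoints):
            flags = any_overlap_flags(promoters, list(peak_sets[(m, t)]))
            values[:, ti, mi] = flags
    return OccupancyLedger(values, [g.gene_id for g in genes], timepoints, marks)


def combination_label(marks: Sequence[str], pattern: Sequence[bool]) -> str:
    present = [m for m, p in zip(marks, pattern) if p]
    return "+".join(present) if present else "none"


def cooccupancy_fractions(ledger: OccupancyLedger, anchor_mark: str) -> pd.DataFrame:
    """Among genes carrying the anchor mark at each timepoint, the
    fraction holding each boolean combination of the other marks.

    Fractions per timepoint sum to 1; a timepoint with no anchor-positive
    genes reports NaN fractions for every combination.
    """
    if anchor_mark not in ledger.marks:
        raise ValueError(f"anchor mark {anchor_mark!r} not in ledger")
    ai = ledger.marks.index(anchor_mark)
    others = [m for m in ledger.marks if m != anchor_mark]
    oi = [ledger.marks.index(m) for m in others]
    patterns = [
        tuple(bool((k >> j) & 1) for j in range(len(others)))
        for k in range(2 ** len(others))
    ]
    rows = []
    for ti, t in enumerate(ledger.timepoints):
        anchored = ledger.values[:, ti, ai]
        n_anchor = int(anchored.sum())
        sub = ledger.values[anchored][:, ti, :][:, oi] if n_anchor else None
        for pat in patterns:
            if n_anchor == 0:
                frac, count = float("nan"), 0
            else:
                match = np.all(sub == np.array(pat, dtype=bool), axis=1)
                count = int(match.sum())
                frac = count / n_anchor
            rows.append(
                {
                    "timepoint": t,
                    "combination": combination_label(others, pat),
                    "fraction": frac,
                    "count": count,
                    "n_anchor_genes": n_anchor,
                }
            )
    return pd.DataFrame(rows)


def transition_flows(ledger: OccupancyLedger) -> pd.DataFrame:
    """Gene counts flowing between mark-combination states at consecutive
    timepoints.  Row sums per source state reproduce that state's gene
    count at the earlier timepoint (conservation).
    """
    if len(ledger.timepoints) < 2:
        raise ValueError("transition flows need >= 2 ordered timepoints")
    state_of = lambda gi, ti: combination_label(
        ledger.marks, ledger.values[gi, ti, :]
    )
    rows: dict[tuple[str, str, str], int] = {}
    for ti in range(len(ledger.timepoints) - 1):
        t_from, t_to = ledger.timepoints[ti], ledger.timepoints[ti + 1]
        for gi in range(len(ledger.gene_ids)):
            key = (f"{t_from}->{t_to}", state_of(gi, ti), state_of(gi, ti + 1))
            rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [
            {"transition": k[0], "state_from": k[1], "state_to": k[2], "gene_count": v}
            for k, v in sorted(rows.items())
        ]
    )


# -------------------------------------------------------------- colocalization


def colocalization_fraction(
    query_peaks: Sequence[GenomicInterval],
    reference_peaks: Sequence[GenomicInterval],
    annotations: Sequence[FeatureAssignment],
) -> dict:
    """Fraction of query peaks overlapping >= 1 reference peak, overall
    and per feature class of the query annotation."""
    if len(query_peaks) == 0:
        raise ValueError("empty query peak set")
    if len(annotations) != len(query_peaks):
        raise ValueError("annotations must align with query peaks")
    if len(reference_peaks) == 0:
        flags = [False] * len(query_peaks)
    else:
        flags = any_overlap_flags(query_peaks, reference_peaks)
    report: dict = {
        "overall": {
            "n_query": len(query_peaks),
            "n_overlapping": int(sum(flags)),
            "fraction": sum(flags) / len(query_peaks),
        },
        "by_class": {},
    }
    by_cls: dict[str, list[bool]] = {}
    for a, f in zip(annotations, flags):
        by_cls.setdefault(a.feature_class.value, []).append(f)
    for cls, fs in sorted(by_cls.items()):
        report["by_class"][cls] = {
            "n_query": len(fs),
            "n_overlapping": int(sum(fs)),
            "fraction": sum(fs) / len(fs),
        }
    return report


# --------------------------------------------------------- gene-set enrichment


def geneset_enrichment(
    query_genes: Sequence[str],
    universe_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    Sets are intersected with the universe; p = P(X >= overlap) for X ~
    Hypergeom(universe, set, query); BH across the collection; sorted by
    p then set_id.
    """
    universe = set(universe_genes)
    query = set(query_genes)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for set_id, members in gene_sets.items():
        s = set(members) & universe
        k = len(query & s)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(s), len(query)))
        rows.append(
            {
                "set_id": set_id,
                "overlap": k,
                "query_size": len(query),
                "set_size": len(s),
                "universe_size": len(universe),
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["bh_q"] = bh_adjust(df["p_value"].values)
        df = df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(
            drop=True
        )
    return df
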