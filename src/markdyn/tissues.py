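"""Cross-tissue promoter-occupancy comparison.

From a boolean gene x tissue promoter-occupancy matrix: pairwise phi
coefficients (Pearson correlation of binary variables from the 2x2 gene
tally), Ward minimum-variance clustering of the Euclidean distances
between tissue rows of the phi matrix, and UpSet-style exclusive
intersection counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .genes import GeneModel, PROMOTER_WINDOW
from .intervals import GenomicInterval
from .integration import build_occupancy_ledger


def promoter_occupancy_matrix(
    peak_sets_per_tissue: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    biotype: str | None = "protein_coding",
) -> pd.DataFrame:
    """Boolean genes x tissues matrix of promoter any-overlap presence."""
    tissues = sorted(peak_sets_per_tissue)
    for t in tissues:
        if len(peak_sets_per_tissue[t]) == 0:
            warnings.warn(f"tissue {t!r} has no peaks; its column is all False")
    ledger = build_occupancy_ledger(
        {(t, "t0"): list(peak_sets_per_tissue[t]) or [] for t in tissues},
        genes,
        promoter_window,
        marks=tissues,
        timepoints=["t0"],
        biotype=biotype,
    )
    return pd.DataFrame(
        ledger.values[:, 0, :], index=ledger.gene_ids, columns=ledger.marks
    )


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0).

    NaN when either margin is degenerate (constant column).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def phi_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Symmetric tissue x tissue phi coefficients with unit diagonal.

    Constant occupancy columns yield NaN off-diagonal entries (phi
    undefined) and a warning naming the tissues.
    """
    tissues = list(m.columns)
    constant = [t for t in tissues if m[t].nunique() < 2]
    if constant:
        warnings.warn(
            f"phi undefined for constant occupancy columns: {constant}"
        )
    vals = np.eye(len(tissues))
    for i in range(len(tissues)):
        for j in range(i + 1, len(tissues)):
            phi = phi_coefficient(m[tissues[i]].values, m[tissues[j]].values)
            vals[i, j] = vals[j, i] = phi
    return pd.DataFrame(vals, index=tissues, columns=tissues)


@dataclass
class SimilarityResult:
    phi: pd.DataFrame
    distance: pd.DataFrame  # Euclidean between phi rows
    linkage: np.ndarray  # scipy linkage matrix (Ward)
    tissues: list[str]


def similarity(
    occupancy: pd.DataFrame, distance_on: str = "phi_rows"
) -> SimilarityResult:
    """Phi matrix + distances + Ward linkage.

    ``distance_on='phi_rows'`` (default) is the literal composition of
    the recipe: Euclidean distance between tissue rows of the phi
    matrix.  ``'one_minus_phi'`` is the plausible alternative where the
    dissimilarity is 1 - phi directly.
    """
    # lexicographic tissue order makes merges deterministic under ties
    occupancy = occupancy[sorted(occupancy.columns)]
    phi = phi_matrix(occupancy)
    if phi.isna().any().any():
        raise ValueError(
            "phi matrix contains undefined entries; remove constant tissues "
            "before clustering"
        )
    if distance_on == "phi_rows":
        d = squareform(pdist(phi.values, metric="euclidean"))
    elif distance_on == "one_minus_phi":
        d = 1.0 - phi.values
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError("distance_on must be 'phi_rows' or 'one_minus_phi'")
    dist = pd.DataFrame(d, index=phi.index, columns=phi.columns)
    Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return SimilarityResult(phi, dist, Z, list(phi.index))


def ward_cluster(sim: SimilarityResult, k: int) -> pd.Series:
    """Cluster labels (1..k) at a k-cluster cut of the Ward tree."""
    labels = hierarchy.fcluster(sim.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=sim.tissues, name="cluster")


def linkage_newick(sim: SimilarityResult) -> str:
    """Newick text of the Ward tree (branch lengths from merge heights)."""
    tree = hierarchy.to_tree(sim.linkage)
    names = sim.tissues

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def upset_counts(m: pd.DataFrame) -> pd.DataFrame:
    """Exclusive intersection counts per observed tissue combination.

    Each gene contributes to exactly the combination of tissues where it
    is occupied; genes with no occupancy are dropped, so the counts sum
    to the number of genes with >= 1 occupancy.
    """
    tissues = list(m.columns)
    rows: dict[tuple[bool, ...], int] = {}
    for pattern in m.values.astype(bool):
        if not pattern.any():
            continue
        key = tuple(pattern)
        rows[key] = rows.get(key, 0) + 1
    recs = [
        {
            "combination": "+".join(t for t, p in zip(tissues, key) if p),
            "degree": int(sum(key)),
            "count": n,
        }
        for key, n in rows.items()
    ]
    return (
        pd.DataFrame(recs, columns=["combination", "degree", "count"])
        .sort_values(["count", "combination"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
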