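"""Immunoglobulin constant-region profiling of plasmablast cells.

Plasmablasts carry very high immunoglobulin transcript content; their
dominant heavy-chain class (IGHG/IGHA/IGHM/IGHD/IGHE) and light-chain
class (IGK/IGL/IGLL5) are called from summed constant-region expression,
and cells are hierarchically clustered on the top IG genes to expose
isotype subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .panels import (IG_HEAVY_CLASSES, IG_HEAVY_ORDER, IG_LIGHT_CLASSES,
                     IG_LIGHT_ORDER)
from .simulate import ConfigurationError


@dataclass
class IgGeneSet:
    """Constant-region gene -> class maps for heavy and light chains."""

    heavy_classes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in IG_HEAVY_CLASSES.items()})
    light_classes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in IG_LIGHT_CLASSES.items()})
    heavy_order: list[str] = field(default_factory=lambda: list(IG_HEAVY_ORDER))
    light_order: list[str] = field(default_factory=lambda: list(IG_LIGHT_ORDER))

    def all_genes(self) -> list[str]:
        genes: list[str] = []
        for classes in (self.heavy_classes, self.light_classes):
            for gs in classes.values():
                genes.extend(gs)
        return genes


def ig_matrix(normalized: AnnData, plasma_cells: list[str] | np.ndarray,
              gene_set: IgGeneSet | None = None) -> pd.DataFrame:
    """Cells x IG-gene submatrix of the normalized expression of plasma
    cells. Cells with zero total IG expression are retained but flagged in
    ``attrs['zero_ig_cells']``; a data set with no IG genes at all raises."""
    gs = gene_set or IgGeneSet()
    genes = [g for g in gs.all_genes() if g in normalized.var_names]
    if not genes:
        raise ConfigurationError("no immunoglobulin gene present in the data")
    sub = normalized[list(plasma_cells), genes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    out = pd.DataFrame(X, index=sub.obs_names.copy(), columns=genes)
    out.attrs["zero_ig_cells"] = list(out.index[out.sum(axis=1) == 0])
    return out


def dominant_isotype(matrix: pd.DataFrame,
                     gene_set: IgGeneSet | None = None) -> pd.DataFrame:
    """Dominant heavy and light chain class per cell.

    Expression is summed within each class; the winner is the argmax, ties
    broken by the fixed class order and flagged. ``heavy_share`` /
    ``light_share`` give the winning class's fraction of that chain's
    total. All-zero cells get missing calls. Scale-invariant per row.
    """
    gs = gene_set or IgGeneSet()

    def class_sums(classes: dict[str, list[str]], order: list[str]
                   ) -> pd.DataFrame:
        cols = {}
        for cls in order:
            genes = [g for g in classes.get(cls, []) if g in matrix.columns]
            cols[cls] = matrix[genes].sum(axis=1) if genes else \
                pd.Series(0.0, index=matrix.index)
        return pd.DataFrame(cols)

    heavy = class_sums(gs.heavy_classes, gs.heavy_order)
    light = class_sums(gs.light_classes, gs.light_order)

    def call(sums: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series]:
        total = sums.sum(axis=1)
        # idxmax ties resolve to the first column, i.e. the fixed class order
        winner = sums.idxmax(axis=1).where(total > 0)
        share = pd.Series(
            np.where(total > 0,
                     sums.max(axis=1) / total.replace(0, np.nan), np.nan),
            index=sums.index)
        tie = (sums.eq(sums.max(axis=1), axis=0).sum(axis=1) > 1) & (total > 0)
        return winner, share, tie

    h_cls, h_share, h_tie = call(heavy)
    l_cls, l_share, l_tie = call(light)
    return pd.DataFrame({
        "heavy_class": h_cls, "heavy_share": h_share, "heavy_tie": h_tie,
        "light_class": l_cls, "light_share": l_share, "light_tie": l_tie,
    }, index=matrix.index.copy())


@dataclass
class IgClustering:
    linkage: np.ndarray
    leaf_order: list[str]
    labels: pd.Series
    genes: list[str]


def cluster_ig_cells(matrix: pd.DataFrame, top_n: int = 10,
                     n_clusters: int | None = None) -> IgClustering:
    """Hierarchical clustering of cells on the top IG genes.

    Restricts to the ``top_n`` genes by mean expression, then agglomerates
    with Euclidean distance and complete linkage. Leaf order is
    deterministic under input order; flat labels come from cutting at
    ``n_clusters`` (default: number of distinct dominant patterns, capped
    at 2 when unspecified).
    """
    if len(matrix) < 2:
        raise ValueError("hierarchical clustering needs >= 2 cells")
    top = matrix.mean(axis=0).sort_values(ascending=False, kind="stable")
    genes = list(top.index[:top_n])
    Z = linkage(matrix[genes].to_numpy(), method="complete",
                metric="euclidean")
    order = [matrix.index[i] for i in leaves_list(Z)]
    k = n_clusters if n_clusters is not None else 2
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                       index=matrix.index.copy(), name="ig_cluster")
    return IgClustering(linkage=Z, leaf_order=order, labels=labels, genes=genes)


def housekeeping_ratio(normalized: AnnData, plasma_cells: list[str],
                       housekeeping: tuple[str, ...] = ("ACTB", "GAPDH", "B2M"),
                       gene_set: IgGeneSet | None = None) -> pd.Series:
    """Diagnostic per-cell ratio of summed IG expression to a housekeeping
    panel (reported, not enforced)."""
    gs = gene_set or IgGeneSet()
    ig = ig_matrix(normalized, plasma_cells, gs).sum(axis=1)
    hk_genes = [g for g in housekeeping if g in normalized.var_names]
    if not hk_genes:
        return pd.Series(np.nan, index=ig.index, name="ig_housekeeping_ratio")
    sub = normalized[list(plasma_cells), hk_genes].X
    hk = np.asarray(sub.todense() if sp.issparse(sub) else sub).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hk > 0, ig.to_numpy() / hk, np.inf)
    return pd.Series(ratio, index=ig.index, name="ig_housekeeping_ratio")
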