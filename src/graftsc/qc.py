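"""Cell and gene quality control.

Two-round retention scheme: round 1 keeps cells by detected-gene bounds and
mitochondrial fraction and drops blacklisted genes; round 2 additionally
drops mitochondrially coded (MT-) genes before reclustering. Inequality
semantics follow the literal wording of the protocol (strict "more than
200 but less than 5000 genes", strict "> three cells", strict ">25%
mitochondrial content removed"); both conventions are switchable via
:class:`QCThresholds`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .panels import BLACKLIST_CLASS_PREFIXES, BLACKLIST_EXACT, BLACKLIST_PREFIXES
from .simulate import ConfigurationError


class EmptyFeatureError(ValueError):
    """Raised when gene filtering would remove every gene."""


@dataclass
class QCThresholds:
    """Retention bounds. With ``strict=True`` (default) the bounds are
    exclusive: a cell with exactly ``min_genes_per_cell`` detected genes is
    removed, a gene detected in exactly ``min_cells_per_gene`` cells is
    removed, and a cell at exactly ``max_mito_fraction`` is retained."""

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 5000
    max_mito_fraction: float = 0.25
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_genes_per_cell < self.max_genes_per_cell:
            raise ConfigurationError("gene-per-cell bounds must be ordered")
        if not 0.0 < self.max_mito_fraction <= 1.0:
            raise ConfigurationError("max_mito_fraction must be in (0,1]")


@dataclass
class GeneBlacklist:
    """Union of symbol rules identifying genes excluded from clustering."""

    prefix_rules: list[str] = field(default_factory=lambda: list(BLACKLIST_PREFIXES))
    exact_names: list[str] = field(default_factory=lambda: list(BLACKLIST_EXACT))
    class_rules: list[str] = field(
        default_factory=lambda: list(BLACKLIST_CLASS_PREFIXES))

    def matches(self, names: pd.Index) -> np.ndarray:
        hit = names.isin(self.exact_names)
        for p in list(self.prefix_rules) + list(self.class_rules):
            hit = hit | names.str.startswith(p)
        return np.asarray(hit)


def compute_cell_qc(counts: AnnData) -> pd.DataFrame:
    """Per-cell QC metrics: n_genes (count > 0), total_umi, mito_fraction.

    ``mito_fraction`` is the share of UMIs on MT-prefixed genes and is 0
    when the matrix carries no MT- genes.
    """
    X = counts.X if sp.issparse(counts.X) else sp.csr_matrix(counts.X)
    X = X.tocsr()
    n_genes = (X > 0).sum(axis=1).A1 if hasattr((X > 0).sum(axis=1), "A1") \
        else np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mt_mask = counts.var_names.str.startswith("MT-")
    if mt_mask.any():
        mt_umi = np.asarray(X[:, np.asarray(mt_mask)].sum(axis=1)).ravel()
    else:
        mt_umi = np.zeros(counts.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito = np.where(total > 0, mt_umi / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": np.asarray(n_genes, dtype=int), "total_umi": total.astype(int),
         "mito_fraction": mito},
        index=counts.obs_names.copy())


def filter_cells_round1(counts: AnnData, metrics: pd.DataFrame,
                        thresholds: QCThresholds | None = None) -> AnnData:
    """Round-1 cell retention: detected-gene bounds and mito fraction.

    Retains cells with ``min < n_genes < max`` (exclusive under strict
    semantics) and ``mito_fraction <= max_mito_fraction``; column order is
    preserved and retained counts are untouched.
    """
    thr = thresholds or QCThresholds()
    m = metrics.loc[counts.obs_names]
    if thr.strict:
        gene_ok = (m["n_genes"] > thr.min_genes_per_cell) & \
                  (m["n_genes"] < thr.max_genes_per_cell)
    else:
        gene_ok = (m["n_genes"] >= thr.min_genes_per_cell) & \
                  (m["n_genes"] <= thr.max_genes_per_cell)
    mito_ok = m["mito_fraction"] <= thr.max_mito_fraction
    return counts[np.asarray(gene_ok & mito_ok)].copy()


def filter_genes(counts: AnnData, thresholds: QCThresholds | None = None,
                 blacklist: GeneBlacklist | None = None,
                 round2: bool = False) -> AnnData:
    """Gene retention: detection breadth, blacklist, and (round 2) MT- drop.

    A gene is retained when it is detected (count > 0) in strictly more
    than ``min_cells_per_gene`` cells (>= under ``strict=False``), does not
    match the blacklist, and — when ``round2`` — does not start with MT-.
    """
    thr = thresholds or QCThresholds()
    bl = blacklist or GeneBlacklist()
    X = counts.X if sp.issparse(counts.X) else sp.csr_matrix(counts.X)
    cells_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    if thr.strict:
        keep = cells_detected > thr.min_cells_per_gene
    else:
        keep = cells_detected >= thr.min_cells_per_gene
    keep &= ~bl.matches(counts.var_names)
    if round2:
        keep &= ~np.asarray(counts.var_names.str.startswith("MT-"))
    if not keep.any():
        raise EmptyFeatureError("gene filtering removed every gene")
    return counts[:, keep].copy()


def flag_doublets_by_coexpression(normalized: AnnData,
                                  lineage_panels: dict[str, list[str]],
                                  tau: float = 1.0) -> pd.DataFrame:
    """Flag cells coexpressing markers of two distinct lineages.

    A cell is flagged iff at least two lineage panels each have mean
    normalized expression > ``tau`` in that cell. Returns a per-cell frame
    with ``is_doublet`` and the two top-scoring lineages.
    """
    if len(lineage_panels) < 2:
        raise ConfigurationError("need at least two lineage panels")
    seen: set[str] = set()
    for name, genes in lineage_panels.items():
        overlap = seen & set(genes)
        if overlap:
            raise ConfigurationError(
                f"lineage panels overlap on {sorted(overlap)}")
        seen |= set(genes)

    scores = {}
    for name, genes in lineage_panels.items():
        present = [g for g in genes if g in normalized.var_names]
        if not present:
            warnings.warn(f"lineage panel {name!r} has no genes in the data",
                          stacklevel=2)
            scores[name] = np.zeros(normalized.n_obs)
            continue
        sub = normalized[:, present].X
        sub = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
        scores[name] = sub.mean(axis=1)
    score_df = pd.DataFrame(scores, index=normalized.obs_names.copy())

    above = score_df.gt(tau)
    is_doublet = above.sum(axis=1) >= 2
    order = np.argsort(-score_df.to_numpy(), axis=1, kind="stable")
    lineages = np.asarray(score_df.columns)
    return pd.DataFrame({
        "is_doublet": is_doublet,
        "lineage_1": lineages[order[:, 0]],
        "lineage_2": lineages[order[:, 1]],
    }, index=score_df.index)
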