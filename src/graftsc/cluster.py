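"""Normalization, variable-gene selection, PCA, SNN graph clustering,
Wilcoxon marker detection and marker-panel annotation.

The processing chain mirrors the standard droplet scRNA-seq workflow:
library-size log-normalization (scale 10,000), ~2000 variable genes by
standardized variance with a smooth mean-variance trend, z-scaling clipped
at +10, PCA on the first 10 components, Jaccard-weighted shared-nearest-
neighbor graph and modularity community detection at resolution 0.5,
one-vs-rest Wilcoxon rank-sum marker tests with min.pct and log-fold-change
prefilters at 0.25, and Benjamini-Hochberg adjustment within each cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .simulate import ConfigurationError

SNN_PRUNE = 1.0 / 15.0  # Jaccard weights below this are cut


@dataclass
class ClusterParams:
    n_hvg: int = 2000
    n_dims: int = 10
    k_neighbors: int = 20
    resolution: float = 0.5
    seed: int = 0


@dataclass
class ClusterAssignment:
    """Per-cell integer cluster ids plus the parameters that produced them."""

    labels: pd.Series
    params: dict = field(default_factory=dict)

    @property
    def clusters(self) -> list[int]:
        return sorted(self.labels.unique())


def log_normalize(counts: AnnData, scale: float = 10_000.0) -> AnnData:
    """ln(1 + count / cell_total * scale) per cell; zeros map to zeros."""
    X = counts.X.tocsr().astype(float) if sp.issparse(counts.X) \
        else sp.csr_matrix(np.asarray(counts.X, dtype=float))
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = counts.obs_names[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; filter first")
    norm = X.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = counts.copy()
    out.X = norm
    out.uns["normalization"] = {"scale_factor": scale, "method": "logNormalize"}
    return out


def select_variable_genes(counts: AnnData, n: int = 2000) -> list[str]:
    """Rank genes by standardized variance and return the top ``n``.

    Per-gene raw-count variance is compared to the variance expected from a
    lowess fit of log10(variance) on log10(mean); counts standardized by
    (mean, expected sd) are clipped at sqrt(n_cells) before the final
    variance is taken. Deterministic; operates on raw counts.
    """
    X = counts.X.tocsc() if sp.issparse(counts.X) else sp.csc_matrix(counts.X)
    n_cells = counts.n_obs
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean ** 2) * n_cells / max(n_cells - 1, 1)

    expressed = var > 0
    if expressed.sum() <= n:
        if expressed.sum() < n:
            warnings.warn(f"only {int(expressed.sum())} variable genes available; "
                          f"returning all", stacklevel=2)
        order = np.argsort(-var, kind="stable")
        return [counts.var_names[i] for i in order if var[i] > 0][:n]

    fit = lowess(np.log10(var[expressed]), np.log10(mean[expressed]),
                 frac=0.3, return_sorted=False)
    exp_sd = np.sqrt(10.0 ** fit)

    clip = np.sqrt(n_cells)
    std_var = np.zeros(counts.n_vars)
    idx = np.flatnonzero(expressed)
    Xe = X[:, idx]
    for j_local, (j, mu, sd) in enumerate(zip(idx, mean[idx], exp_sd)):
        col = np.asarray(Xe[:, j_local].todense()).ravel()
        z = np.minimum((col - mu) / sd, clip)
        std_var[j] = np.sum(z ** 2) / (n_cells - 1) \
            - (np.sum(z) ** 2) / (n_cells * (n_cells - 1))
    order = np.argsort(-std_var, kind="stable")[:n]
    return list(counts.var_names[order])


def scale_matrix(normalized: AnnData, genes: list[str] | None = None,
                 clip: float = 10.0) -> np.ndarray:
    """Gene-wise z-score of the normalized matrix, clipped at ``+clip``."""
    sub = normalized[:, genes] if genes is not None else normalized
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return np.minimum((X - mu) / sd, clip)


def run_pca(scaled: np.ndarray, n_dims: int = 10, seed: int = 0) -> np.ndarray:
    """PCA embedding with a fixed sign convention.

    Components are ordered by decreasing explained variance; each
    component's sign is fixed by forcing its largest-magnitude loading
    positive, making the embedding byte-stable across runs.
    """
    if scaled.shape[0] <= n_dims:
        raise ValueError(
            f"need more cells ({scaled.shape[0]}) than dimensions ({n_dims})")
    n_comp = min(n_dims, scaled.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(scaled)
    for k in range(n_comp):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            emb[:, k] *= -1.0
    return emb


def _snn_graph(embedding: np.ndarray, k_neighbors: int) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph (self included in k)."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sp.csr_matrix((np.ones(n * k_neighbors), (rows, idx.ravel())),
                        shape=(n, n))
    shared = (adj @ adj.T).tocoo()
    jac = shared.data / (2 * k_neighbors - shared.data)
    keep = jac >= SNN_PRUNE
    snn = sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])),
                        shape=(n, n))
    snn.setdiag(0)
    snn.eliminate_zeros()
    return snn


def cluster_graph(embedding: np.ndarray, k_neighbors: int = 20,
                  resolution: float = 0.5, seed: int = 0) -> ClusterAssignment:
    """Modularity community detection on the SNN graph of an embedding.

    Deterministic for a fixed seed; cluster ids are integers from 0,
    relabeled in decreasing cluster-size order.
    """
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    if not np.isfinite(embedding).all():
        raise ValueError("embedding contains non-finite values")
    snn = _snn_graph(embedding, k_neighbors)
    coo = sp.triu(snn, k=1).tocoo()
    g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(), resolution_parameter=resolution, seed=seed,
        n_iterations=-1)
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    relabel = {old: new for new, old in enumerate(sizes.index)}
    labels = pd.Series([relabel[c] for c in raw], dtype=int)
    return ClusterAssignment(
        labels=labels,
        params={"k_neighbors": k_neighbors, "resolution": resolution,
                "seed": seed, "n_dims": embedding.shape[1]})


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's auto policy).
    """
    return float(mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def wilcoxon_markers(normalized: AnnData, clusters: pd.Series,
                     min_pct: float = 0.25,
                     logfc_threshold: float = 0.25) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table per cluster.

    Genes are prefiltered to detection fraction >= ``min_pct`` on at least
    one side and |logFC| >= ``logfc_threshold`` (natural log of de-logged
    means); p-values are BH-adjusted within each cluster's tested family.
    Clusters with fewer than 3 cells are skipped with a warning.
    """
    labels = np.asarray(clusters)
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("marker testing requires at least two clusters")
    X = normalized.X.toarray() if sp.issparse(normalized.X) \
        else np.asarray(normalized.X, dtype=float)
    rows = []
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 3:
            warnings.warn(f"cluster {cl} has <3 cells; skipped", stacklevel=2)
            continue
        X_in, X_out = X[mask], X[~mask]
        pct_in = (X_in > 0).mean(axis=0)
        pct_out = (X_out > 0).mean(axis=0)
        lfc = np.log((np.expm1(X_in).mean(axis=0) + 1.0)
                     / (np.expm1(X_out).mean(axis=0) + 1.0))
        testable = ((pct_in >= min_pct) | (pct_out >= min_pct)) & \
            (np.abs(lfc) >= logfc_threshold)
        idx = np.flatnonzero(testable)
        if idx.size == 0:
            continue
        pvals = np.array([rank_sum_test(X_in[:, j], X_out[:, j]) for j in idx])
        padj = multipletests(pvals, method="fdr_bh")[1]
        for j, p, q in zip(idx, pvals, padj):
            rows.append({"cluster": cl, "gene": normalized.var_names[j],
                         "log_fold_change": lfc[j], "pct_in": pct_in[j],
                         "pct_out": pct_out[j], "p_value": p, "adjusted_p": q})
    table = pd.DataFrame(rows, columns=["cluster", "gene", "log_fold_change",
                                        "pct_in", "pct_out", "p_value",
                                        "adjusted_p"])
    return table.sort_values(["cluster", "p_value", "gene"],
                             kind="stable").reset_index(drop=True)


def annotate_by_markers(normalized: AnnData, clusters: pd.Series,
                        catalog: dict[str, list[str]]) -> pd.DataFrame:
    """Label each cluster by its best-scoring marker panel.

    Cluster score for a type is the mean over its panel genes of the mean
    normalized expression in the cluster; ties are broken by larger panel
    detection fraction, then lexicographically (recorded in ``tie``).
    """
    if not catalog:
        raise ConfigurationError("marker catalog is empty")
    present = {t: [g for g in genes if g in normalized.var_names]
               for t, genes in catalog.items()}
    missing = {t for t, genes in present.items() if not genes}
    if len(missing) == len(catalog):
        raise ConfigurationError("no catalog gene present in the data")
    for t in sorted(missing):
        warnings.warn(f"marker panel {t!r} has no genes in data", stacklevel=2)

    X = normalized.X.toarray() if sp.issparse(normalized.X) \
        else np.asarray(normalized.X, dtype=float)
    labels = np.asarray(clusters)
    rows = []
    for cl in sorted(pd.unique(labels)):
        mask = labels == cl
        scored = []
        for t in sorted(catalog):
            genes = present.get(t, [])
            if not genes:
                continue
            gi = [normalized.var_names.get_loc(g) for g in genes]
            score = float(X[np.ix_(mask, gi)].mean())
            detect = float((X[np.ix_(mask, gi)] > 0).mean())
            scored.append((t, score, detect))
        # best by score, then detection fraction, then lexicographic name
        scored.sort(key=lambda r: (-r[1], -r[2], r[0]))
        best = scored[0]
        tie = len(scored) > 1 and scored[1][1] == best[1] \
            and scored[1][2] == best[2]
        margin = best[1] - scored[1][1] if len(scored) > 1 else np.inf
        rows.append({"cluster": cl, "cell_type": best[0], "score": best[1],
                     "margin": margin, "tie": tie})
    return pd.DataFrame(rows).set_index("cluster")


def cluster_pipeline(counts: AnnData, params: ClusterParams | None = None
                     ) -> tuple[ClusterAssignment, AnnData, np.ndarray]:
    """normalize -> HVG -> scale -> PCA -> SNN cluster on raw counts.

    Returns the assignment, the normalized matrix (all genes) and the PCA
    embedding, so callers can reuse both for markers and annotation.
    """
    p = params or ClusterParams()
    norm = log_normalize(counts)
    hvg = select_variable_genes(counts, n=p.n_hvg)
    scaled = scale_matrix(norm, genes=hvg)
    emb = run_pca(scaled, n_dims=p.n_dims, seed=p.seed)
    assignment = cluster_graph(emb, k_neighbors=p.k_neighbors,
                               resolution=p.resolution, seed=p.seed)
    assignment.labels.index = counts.obs_names.copy()
    return assignment, norm, emb


def subcluster(counts: AnnData, cell_subset: list[str] | np.ndarray,
               params: ClusterParams | None = None,
               parent_label: str = "SUB") -> pd.Series:
    """Rerun the full clustering chain on a cell subset.

    Subcluster names are namespaced under ``parent_label`` (FB -> FB1..FBk,
    numbered from 1 in decreasing size order). Barcodes are conserved.
    """
    p = params or ClusterParams()
    subset = list(cell_subset)
    if not subset:
        raise ValueError("cell subset is empty")
    if len(subset) < p.k_neighbors + 1:
        raise ValueError(
            f"subset of {len(subset)} cells is smaller than k_neighbors+1")
    sub = counts[subset].copy()
    assignment, _, _ = cluster_pipeline(sub, params=p)
    named = assignment.labels.map(lambda c: f"{parent_label}{c + 1}")
    named.index = sub.obs_names.copy()
    return named
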