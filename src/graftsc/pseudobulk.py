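"""Pseudobulk TPM-like profiles, the n-of-1 max-gap differential filter,
matrisome scoring, and cell-type composition tables.

With no biological replicates (one biopsy per condition), conventional
replicated differential-expression models do not apply. Instead, per
(cell type, sample) group the mean of library-size-normalized per-cell
expression is rescaled to sum to 10,000 — a TPM-like composition — and a
gene is reported as differential when the largest of its per-sample values
is both above a floor (>2 TPM) and at least two-fold above the second
largest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .simulate import ConfigurationError

TPM_SCALE = 10_000.0


def pseudobulk_tpm(counts: AnnData, cell_groups: pd.Series,
                   scale: float = TPM_SCALE) -> pd.DataFrame:
    """TPM-like profile per group: genes x groups, each column sums to
    ``scale``.

    Per cell, counts are divided by the cell's total UMIs; the per-gene
    mean over the group's cells is then rescaled so the column sums to
    exactly ``scale``. Scale-invariant in the raw counts. The number of
    cells behind each column is recorded in ``DataFrame.attrs['n_cells']``.
    """
    X = counts.X.tocsr().astype(float) if sp.issparse(counts.X) \
        else sp.csr_matrix(np.asarray(counts.X, dtype=float))
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = counts.obs_names[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    frac = X.multiply(1.0 / totals[:, None]).tocsr()

    groups = cell_groups.loc[counts.obs_names]
    cols, n_cells = {}, {}
    for key, idx in groups.groupby(groups, observed=True).groups.items():
        rows = [counts.obs_names.get_loc(b) for b in idx]
        if not rows:
            warnings.warn(f"group {key!r} is empty; skipped", stacklevel=2)
            continue
        mean = np.asarray(frac[rows].mean(axis=0)).ravel()
        total = mean.sum()
        cols[key] = mean * (scale / total)
        n_cells[key] = len(rows)
    profile = pd.DataFrame(cols, index=counts.var_names.copy())
    profile.attrs["n_cells"] = n_cells
    profile.attrs["scale"] = scale
    return profile


def maxgap_de(profiles: pd.DataFrame, min_tpm: float = 2.0,
              min_ratio: float = 2.0) -> pd.DataFrame:
    """Per-gene max vs second-max filter across sample profiles.

    A gene passes when its maximal TPM is strictly above ``min_tpm`` and at
    least ``min_ratio``-fold above the second largest value (ratio +inf
    when the second is 0). Ties for the maximum are broken by column order
    and flagged.
    """
    if profiles.shape[1] < 2:
        raise ValueError("max-gap statistic needs >= 2 sample profiles")
    vals = profiles.to_numpy(dtype=float)
    order = np.argsort(-vals, axis=1, kind="stable")
    max_v = vals[np.arange(len(vals)), order[:, 0]]
    second_v = vals[np.arange(len(vals)), order[:, 1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second_v > 0, max_v / second_v,
                         np.where(max_v > 0, np.inf, np.nan))
    passes = (max_v > min_tpm) & (ratio >= min_ratio)
    tie = max_v == second_v
    return pd.DataFrame({
        "max_tpm": max_v, "second_tpm": second_v,
        "argmax_sample": np.asarray(profiles.columns)[order[:, 0]],
        "ratio": ratio, "passes": passes, "max_tie": tie,
    }, index=profiles.index.copy())


def pairwise_fold(profiles: pd.DataFrame, gene: str, sample_a: str,
                  sample_b: str) -> float:
    """TPM ratio of ``gene`` between two sample profiles (a over b).

    Returns +inf (with a warning) when the denominator is 0 but the
    numerator is not; raises KeyError for an absent gene.
    """
    if gene not in profiles.index:
        raise KeyError(f"gene {gene!r} absent from profiles")
    a = float(profiles.at[gene, sample_a])
    b = float(profiles.at[gene, sample_b])
    if b == 0:
        if a == 0:
            return np.nan
        warnings.warn(f"{gene}: zero TPM in {sample_b}; fold is +inf",
                      stacklevel=2)
        return np.inf
    return a / b


def matrisome_score(profiles: pd.DataFrame, catalog: dict[str, list[str]],
                    category: str, top_n: int = 10) -> pd.DataFrame:
    """log2(TPM+1) table for the top genes of one matrisome category.

    Genes are ranked by their maximum log2(TPM+1) across groups; the top
    ``top_n`` rows are returned with per-group values.
    """
    if category not in catalog:
        raise KeyError(f"category {category!r} not in matrisome catalog")
    genes = [g for g in catalog[category] if g in profiles.index]
    if not genes:
        warnings.warn(f"no gene of category {category!r} present in profiles",
                      stacklevel=2)
        return pd.DataFrame(columns=profiles.columns)
    log_vals = np.log2(profiles.loc[genes] + 1.0)
    ranked = log_vals.loc[log_vals.max(axis=1).sort_values(
        ascending=False, kind="stable").index]
    return ranked.head(top_n)


def composition_table(cell_types: pd.Series, samples: pd.Series,
                      immune_types: set[str] | None = None) -> pd.DataFrame:
    """Per-sample cell-type proportions (rows sum to 1) plus, when
    ``immune_types`` is given, the aggregate immune fraction."""
    df = pd.DataFrame({"cell_type": cell_types, "sample": samples})
    counts = pd.crosstab(df["sample"], df["cell_type"])
    props = counts.div(counts.sum(axis=1), axis=0)
    if immune_types is not None:
        present = [t for t in props.columns if t in immune_types]
        props["immune_fraction"] = props[present].sum(axis=1) if present else 0.0
    return props
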