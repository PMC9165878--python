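"""Synthetic multi-sample scRNA-seq generator with ground-truth labels.

Emulates the statistical structure the downstream chimerism analysis
assumes: sparse negative-binomial UMI counts with cell-type marker
structure, sex-concordant XIST / Y-gene detection with dropout (including
XIST-silent proximal-tubule-like types), configurable recipient/donor
mixture fractions per cell type, mitochondrial-content outlier cells, and
two-lineage doublets.

The generator is first-class, tested code: its defaults define the study
conditions under which the pipeline's recovery properties are asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .panels import DEFAULT_MARKER_PANELS, FEMALE_GENES, MALE_GENES, MT_GENES


class EmptyDatasetError(ValueError):
    """Raised when a configuration would produce zero genes or zero cells."""


class ConfigurationError(ValueError):
    """Raised for invalid simulator or analysis configuration."""


@dataclass
class SexPanel:
    """Sex-linked detection panel: female-specific and male-specific genes."""

    female_genes: tuple[str, ...] = tuple(FEMALE_GENES)
    male_genes: tuple[str, ...] = tuple(MALE_GENES)

    def __post_init__(self) -> None:
        if not self.female_genes or not self.male_genes:
            raise ConfigurationError("sex panel lists must be non-empty")
        if set(self.female_genes) & set(self.male_genes):
            raise ConfigurationError("sex panel lists must be disjoint")


@dataclass
class SampleSpec:
    """One biopsy sample: donor/recipient sexes and per-type cell counts.

    ``recipient_fraction_per_type`` gives, per cell type, the fraction of
    that type's cells carrying the *recipient's* sex signature (realized as
    an exact rounded count so the simulated truth matches the configured
    mixture). Types absent from the map default to donor origin (0.0).
    """

    sample_id: str
    donor_sex: str
    recipient_sex: str
    cells_per_type: dict[str, int] = field(default_factory=dict)
    recipient_fraction_per_type: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sex in (self.donor_sex, self.recipient_sex):
            if sex not in ("F", "M"):
                raise ConfigurationError(f"sex must be 'F' or 'M', got {sex!r}")
        if any(n < 0 for n in self.cells_per_type.values()):
            raise ConfigurationError("cells_per_type values must be >= 0")
        for t, f in self.recipient_fraction_per_type.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"recipient fraction for {t!r} must be in [0,1], got {f}")


@dataclass
class SimConfig:
    """Full simulator configuration; see module docstring for semantics."""

    samples: list[SampleSpec]
    genes: int = 600
    seed: int = 0
    nb_mean_range: tuple[float, float] = (0.2, 3.0)
    nb_dispersion: float = 0.5
    marker_boost: float = 50.0
    marker_off_mean: float = 0.05
    sex_detect_prob: float = 0.8
    xist_silent_types: tuple[str, ...] = ()
    doublet_rate: float = 0.0
    mito_outlier_rate: float = 0.0
    mito_outlier_range: tuple[float, float] = (0.30, 0.90)
    mito_baseline_range: tuple[float, float] = (0.01, 0.15)
    marker_panels: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if not self.samples:
            raise ConfigurationError("at least one SampleSpec is required")
        if not 0.0 <= self.sex_detect_prob <= 1.0:
            raise ConfigurationError("sex_detect_prob must be in [0,1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not 0.0 < self.nb_mean_range[0] <= self.nb_mean_range[1]:
            raise ConfigurationError("nb_mean_range must be positive and ordered")
        if self.marker_boost < 1.0:
            raise ConfigurationError("marker_boost must be >= 1")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ConfigurationError("doublet_rate must be in [0,1)")
        if not 0.0 <= self.mito_outlier_rate < 1.0:
            raise ConfigurationError("mito_outlier_rate must be in [0,1)")
        declared = self.cell_types()
        unknown = set(self.xist_silent_types) - set(declared)
        if unknown:
            raise ConfigurationError(
                f"xist_silent_types not among declared cell types: {sorted(unknown)}")

    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            for t in s.cells_per_type:
                seen.setdefault(t)
        return list(seen)

    def resolved_marker_panels(self) -> dict[str, list[str]]:
        """Marker panel per declared cell type (defaults for known kidney
        types, synthetic ``<TYPE>_MRK<i>`` symbols otherwise)."""
        panels = {}
        for t in self.cell_types():
            if self.marker_panels and t in self.marker_panels:
                panels[t] = list(self.marker_panels[t])
            elif t in DEFAULT_MARKER_PANELS:
                panels[t] = list(DEFAULT_MARKER_PANELS[t])
            else:
                panels[t] = [f"{t}_MRK{i + 1}" for i in range(5)]
        return panels


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
             n_cells: int) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (shape r = 1/dispersion)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p[None, :], size=(n_cells, mean.size))


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def generate_dataset(config: SimConfig) -> tuple[AnnData, pd.DataFrame]:
    """Generate a multi-sample UMI count matrix plus a per-cell truth table.

    Returns an AnnData (cells x genes, integer CSR counts, ``obs['sample']``
    set) and a truth DataFrame indexed by barcode with columns sample_id,
    cell_type, sex, origin, is_doublet, doublet_types and mito_fraction.
    Deterministic for a fixed ``config.seed``.
    """
    total_cells = sum(n for s in config.samples for n in s.cells_per_type.values())
    if config.genes <= 0 or total_cells == 0:
        raise EmptyDatasetError(
            f"empty dataset: {config.genes} background genes, {total_cells} cells")

    rng = np.random.default_rng(config.seed)
    panels = config.resolved_marker_panels()

    background = [f"BG{i + 1:05d}" for i in range(config.genes)]
    marker_genes: list[str] = []
    for genes in panels.values():
        for g in genes:
            if g not in marker_genes:
                marker_genes.append(g)
    sex_genes = list(FEMALE_GENES) + list(MALE_GENES)
    gene_names = background + [g for g in marker_genes if g not in background]
    gene_names += [g for g in MT_GENES if g not in gene_names]
    gene_names += [g for g in sex_genes if g not in gene_names]
    gene_index = pd.Index(gene_names)

    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gene_index)))
    # Lineage markers are near-silent outside their own lineage, as in real
    # droplet data; the boost below acts on this low off-type baseline.
    for g in marker_genes:
        base_mean[gene_index.get_loc(g)] = config.marker_off_mean
    # Sex-panel genes are driven purely by the detection model below.
    for g in sex_genes:
        base_mean[gene_index.get_loc(g)] = 0.0

    blocks: list[np.ndarray] = []
    records: list[dict] = []
    for spec in config.samples:
        for ctype, n in spec.cells_per_type.items():
            if n == 0:
                continue
            mean = base_mean.copy()
            for g in panels[ctype]:
                mean[gene_index.get_loc(g)] *= config.marker_boost
            blocks.append(_nb_draw(rng, mean, config.nb_dispersion, n))
            frac = spec.recipient_fraction_per_type.get(ctype, 0.0)
            n_rec = int(round(frac * n))
            origins = np.array(["recipient"] * n_rec + ["donor"] * (n - n_rec))
            rng.shuffle(origins)
            for origin in origins:
                sex = spec.recipient_sex if origin == "recipient" else spec.donor_sex
                records.append({
                    "sample_id": spec.sample_id, "cell_type": ctype,
                    "sex": sex, "origin": origin,
                    "is_doublet": False, "doublet_types": "",
                    "mito_fraction": 0.0,
                })

    counts = np.vstack(blocks).astype(np.int64)
    truth = pd.DataFrame.from_records(records)
    truth.index = pd.Index(
        [f"{r.sample_id}-{i + 1:05d}" for i, r in enumerate(truth.itertuples())],
        name="barcode")

    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({"sample": truth["sample_id"].to_numpy()},
                         index=truth.index.copy()),
        var=pd.DataFrame(index=gene_index.copy()),
    )

    adata = inject_sex_signal(adata, truth, SexPanel(), config.sex_detect_prob,
                              config.xist_silent_types, rng=rng)
    if config.doublet_rate > 0:
        adata, truth = inject_doublets(adata, truth, config.doublet_rate, rng=rng)
    adata = inject_mito(adata, truth, config.mito_outlier_rate,
                        config.mito_outlier_range, rng=rng,
                        baseline_range=config.mito_baseline_range)
    return adata, truth


def inject_sex_signal(adata: AnnData, truth: pd.DataFrame, panel: SexPanel,
                      sex_detect_prob: float,
                      xist_silent_types: tuple[str, ...] = (),
                      rng: np.random.Generator | None = None,
                      seed: int = 0) -> AnnData:
    """Overwrite sex-panel gene counts according to each cell's true sex.

    Male cells: each male-panel gene detected independently with probability
    ``sex_detect_prob`` (count drawn as 1 + Poisson(1)), female genes zero.
    Female cells: the converse, except cell types in ``xist_silent_types``
    where XIST stays zero (transcriptional silence of XIST seen in female
    proximal-tubule cells).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    for g in panel.female_genes + panel.male_genes:
        if g not in adata.var_names:
            raise ConfigurationError(f"sex-panel gene {g!r} missing from gene index")

    X = _dense(adata)
    is_male = (truth["sex"] == "M").to_numpy()
    is_female = ~is_male
    silent = truth["cell_type"].isin(xist_silent_types).to_numpy()

    def detected_counts(mask: np.ndarray) -> np.ndarray:
        col = np.zeros(adata.n_obs, dtype=np.int64)
        hit = mask & (rng.random(adata.n_obs) < sex_detect_prob)
        col[hit] = 1 + rng.poisson(1.0, size=int(hit.sum()))
        return col

    for g in panel.male_genes:
        X[:, adata.var_names.get_loc(g)] = detected_counts(is_male)
    for g in panel.female_genes:
        X[:, adata.var_names.get_loc(g)] = detected_counts(is_female & ~silent)

    out = adata.copy()
    out.X = sp.csr_matrix(X)
    return out


def inject_doublets(adata: AnnData, truth: pd.DataFrame, rate: float,
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> tuple[AnnData, pd.DataFrame]:
    """Replace pairs of singlets with summed two-lineage doublet columns.

    ``round(rate * n_cells)`` doublets are formed; each merges two cells of
    the same sample, same sex (keeps the sex-signal exclusivity invariant)
    and different cell types, removing both sources. Doublet columns are
    appended after the surviving singlets.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if rate == 0:
        return adata, truth
    if truth["cell_type"].nunique() < 2:
        raise ConfigurationError("doublet injection requires >= 2 cell types")

    n_doublets = int(round(rate * adata.n_obs))
    X = _dense(adata)
    available = np.ones(adata.n_obs, dtype=bool)
    strata = truth.groupby(["sample_id", "sex"], sort=False).indices

    pairs: list[tuple[int, int]] = []
    keys = list(strata)
    for _ in range(n_doublets):
        rng.shuffle(keys)
        chosen = None
        for key in keys:
            idx = [i for i in strata[key] if available[i]]
            types = truth["cell_type"].to_numpy()[idx]
            if len(set(types)) < 2:
                continue
            a = int(rng.choice(idx))
            others = [i for i in idx
                      if truth["cell_type"].iat[i] != truth["cell_type"].iat[a]]
            b = int(rng.choice(others))
            chosen = (a, b)
            break
        if chosen is None:
            warnings.warn("not enough mixable singlets; fewer doublets than "
                          "requested", stacklevel=2)
            break
        a, b = chosen
        available[a] = available[b] = False
        pairs.append((a, b))

    keep = np.flatnonzero(available)
    doublet_rows = np.stack([X[a] + X[b] for a, b in pairs]) if pairs else \
        np.empty((0, adata.n_vars), dtype=X.dtype)
    new_X = np.vstack([X[keep], doublet_rows])

    doublet_records = []
    for k, (a, b) in enumerate(pairs):
        ra, rb = truth.iloc[a], truth.iloc[b]
        doublet_records.append({
            "sample_id": ra["sample_id"],
            "cell_type": f"{ra['cell_type']}+{rb['cell_type']}",
            "sex": ra["sex"], "origin": ra["origin"],
            "is_doublet": True,
            "doublet_types": f"{ra['cell_type']}+{rb['cell_type']}",
            "mito_fraction": 0.0,
        })
    doublet_truth = pd.DataFrame.from_records(doublet_records)
    if len(doublet_truth):
        doublet_truth.index = pd.Index(
            [f"{r['sample_id']}-DBL{k + 1:04d}"
             for k, r in enumerate(doublet_records)], name="barcode")
    new_truth = pd.concat([truth.iloc[keep], doublet_truth])

    out = AnnData(
        X=sp.csr_matrix(new_X),
        obs=pd.DataFrame({"sample": new_truth["sample_id"].to_numpy()},
                         index=new_truth.index.copy()),
        var=adata.var.copy(),
    )
    return out, new_truth


def inject_mito(adata: AnnData, truth: pd.DataFrame, mito_outlier_rate: float,
                mito_outlier_range: tuple[float, float],
                rng: np.random.Generator | None = None, seed: int = 0,
                baseline_range: tuple[float, float] = (0.01, 0.15),
                n_outliers: int | None = None) -> AnnData:
    """Impose per-cell mitochondrial UMI fractions by rescaling MT- counts.

    Outlier cells (count ``n_outliers`` if given, else
    ``round(rate * n_cells)``) receive a fraction drawn uniformly from
    ``mito_outlier_range`` (which must lie strictly above 0.25); all other
    cells receive a baseline fraction below 0.25. Realized fractions are
    written back into ``truth['mito_fraction']`` in place.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if not 0.25 < mito_outlier_range[0] <= mito_outlier_range[1] <= 1.0:
        raise ConfigurationError(
            "mito_outlier_range must lie within (0.25, 1] and be ordered")
    if not 0.0 <= baseline_range[0] <= baseline_range[1] < 0.25:
        raise ConfigurationError("baseline_range must lie within [0, 0.25)")
    mt_idx = np.flatnonzero(adata.var_names.str.startswith("MT-"))
    if mt_idx.size == 0:
        raise ConfigurationError("gene index contains no MT- genes")

    n = adata.n_obs
    n_out = n_outliers if n_outliers is not None \
        else int(round(mito_outlier_rate * n))
    outliers = np.zeros(n, dtype=bool)
    if n_out > 0:
        outliers[rng.choice(n, size=n_out, replace=False)] = True

    target = rng.uniform(*baseline_range, size=n)
    target[outliers] = rng.uniform(*mito_outlier_range, size=n_out)

    X = _dense(adata)
    non_mt = np.delete(np.arange(adata.n_vars), mt_idx)
    rest = X[:, non_mt].sum(axis=1).astype(np.int64)
    realized = np.zeros(n)
    for i in range(n):
        r = int(rest[i])
        mt_total = int(round(target[i] * r / (1.0 - target[i]))) if r > 0 else 0
        if outliers[i] and mt_total == 0:
            mt_total = 1  # degenerate empty cell still exceeds the threshold
        X[i, mt_idx] = rng.multinomial(mt_total, np.full(mt_idx.size,
                                                         1.0 / mt_idx.size))
        realized[i] = mt_total / (mt_total + r) if (mt_total + r) > 0 else 0.0
    truth["mito_fraction"] = realized

    out = adata.copy()
    out.X = sp.csr_matrix(X)
    return out
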