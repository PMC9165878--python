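"""Donor/recipient origin assignment from sex-linked gene expression.

In a sex-mismatched transplant, XIST detection marks female cells and
Y-chromosome gene detection marks male cells; mapping each group's sex
call through the sample's donor/recipient sexes yields cell origin.
Y-gene evidence takes priority over XIST absence because XIST is
transcriptionally silent in some female parenchymal cell types (proximal
tubule), making the absence of female signal uninformative there; an
explicit parenchymal prior resolves those groups to donor origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .panels import GENE_ALIASES
from .simulate import ConfigurationError, SexPanel

__all__ = ["SexPanel", "SamplePair", "sex_detect_cells", "call_group_sex",
           "assign_origin", "origin_composition", "per_cell_origin",
           "genotype_concordance"]


@dataclass(frozen=True)
class SamplePair:
    """Donor and recipient sex for one sample; informative iff mismatched."""

    sample_id: str
    donor_sex: str
    recipient_sex: str

    def __post_init__(self) -> None:
        for sex in (self.donor_sex, self.recipient_sex):
            if sex not in ("F", "M"):
                raise ConfigurationError(f"sex must be 'F' or 'M', got {sex!r}")

    @property
    def informative(self) -> bool:
        return self.donor_sex != self.recipient_sex


def _resolve_genes(genes: tuple[str, ...], var_names: pd.Index
                   ) -> tuple[list[str], list[str]]:
    found, missing = [], []
    for g in genes:
        name = g if g in var_names else GENE_ALIASES.get(g, g)
        (found if name in var_names else missing).append(name)
    return found, missing


def sex_detect_cells(counts: AnnData, panel: SexPanel | None = None
                     ) -> pd.DataFrame:
    """Per-cell boolean detection of the female and male panels.

    ``female_detect`` = any female-panel (XIST) UMI > 0; ``male_detect`` =
    any male-panel (Y gene) UMI > 0. Missing panel genes are tolerated and
    recorded in ``DataFrame.attrs['missing_genes']``; a fully absent panel
    raises.
    """
    panel = panel or SexPanel()
    f_found, f_missing = _resolve_genes(panel.female_genes, counts.var_names)
    m_found, m_missing = _resolve_genes(panel.male_genes, counts.var_names)
    if not f_found and not m_found:
        raise ConfigurationError("no sex-panel gene present in the data")
    missing = f_missing + m_missing
    if missing:
        warnings.warn(f"sex-panel genes absent from data: {missing}",
                      stacklevel=2)

    X = counts.X if sp.issparse(counts.X) else sp.csr_matrix(counts.X)

    def any_detect(genes: list[str]) -> np.ndarray:
        if not genes:
            return np.zeros(counts.n_obs, dtype=bool)
        gi = [counts.var_names.get_loc(g) for g in genes]
        return np.asarray((X[:, gi] > 0).sum(axis=1)).ravel() > 0

    out = pd.DataFrame({"female_detect": any_detect(f_found),
                        "male_detect": any_detect(m_found)},
                       index=counts.obs_names.copy())
    out.attrs["missing_genes"] = missing
    return out


def call_group_sex(detections: pd.DataFrame, grouping: pd.DataFrame,
                   min_cells: int = 10, tau_detect: float = 0.05,
                   margin: float = 2.0) -> pd.DataFrame:
    """Call each (cluster x sample) group female, male, or ambiguous.

    With fM/fF the group's male/female detection fractions: call M when
    fM >= tau_detect and fM >= margin * fF; call F when fF >= tau_detect,
    fF >= margin * fM and fM < tau_detect (Y evidence outranks XIST because
    XIST-silent female types produce fF = 0); otherwise ambiguous. Groups
    below ``min_cells`` are still called but flagged low-confidence.

    ``grouping`` needs columns ``cluster`` and ``sample`` aligned to
    ``detections``'s index.
    """
    df = grouping.loc[detections.index, ["cluster", "sample"]].copy()
    df["female_detect"] = detections["female_detect"].to_numpy()
    df["male_detect"] = detections["male_detect"].to_numpy()
    rows = []
    for (cluster, sample), grp in df.groupby(["cluster", "sample"], sort=True,
                                             observed=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"empty group ({cluster}, {sample}); skipped",
                          stacklevel=2)
            continue
        f_m = grp["male_detect"].mean()
        f_f = grp["female_detect"].mean()
        if f_m >= tau_detect and f_m >= margin * f_f:
            call = "M"
        elif f_f >= tau_detect and f_f >= margin * f_m and f_m < tau_detect:
            call = "F"
        else:
            call = "ambiguous"
        rows.append({"cluster": cluster, "sample": sample, "n_cells": n,
                     "fraction_male_detect": f_m, "fraction_female_detect": f_f,
                     "sex_call": call, "low_confidence": n < min_cells})
    return pd.DataFrame(rows)


def assign_origin(sex_calls: pd.DataFrame, pairs: dict[str, SamplePair],
                  parenchymal_types: set[str] | None = None,
                  group_cell_types: dict | None = None) -> pd.DataFrame:
    """Map per-group sex calls to donor/recipient origin.

    For a mismatched pair, a sex call equal to the donor (recipient) sex
    yields donor (recipient) origin; an ambiguous call on a parenchymal
    cell type falls back to donor origin (flagged "sex-uninformative,
    parenchymal prior", covering XIST-silent female tubule groups) and is
    otherwise left ambiguous. Same-sex pairs are always unassignable.

    ``group_cell_types`` optionally maps cluster id -> cell-type label for
    the parenchymal fallback.
    """
    parenchymal_types = parenchymal_types or set()
    group_cell_types = group_cell_types or {}
    out = sex_calls.copy()
    origins, flags = [], []
    for row in out.itertuples():
        pair = pairs.get(row.sample)
        if pair is None:
            raise ConfigurationError(f"no SamplePair for sample {row.sample!r}")
        if not pair.informative:
            origins.append("unassignable")
            flags.append("same-sex pair")
            continue
        ctype = group_cell_types.get(row.cluster, row.cluster)
        if row.sex_call == pair.donor_sex:
            origins.append("donor")
            flags.append("")
        elif row.sex_call == pair.recipient_sex:
            origins.append("recipient")
            flags.append("")
        elif row.sex_call == "ambiguous" and ctype in parenchymal_types:
            origins.append("donor")
            flags.append("sex-uninformative, parenchymal prior")
        else:
            origins.append("ambiguous")
            flags.append("")
    out["origin"] = origins
    out["flag"] = flags
    return out


def per_cell_origin(detections: pd.DataFrame, samples: pd.Series,
                    pairs: dict[str, SamplePair]) -> pd.Series:
    """Per-cell origin from per-cell sex detection (no group pooling).

    A cell detecting only the male panel is M, only the female panel F,
    neither or both ambiguous; origin then follows the sample pair. Dropout
    makes this noisier than group-level calling; it exists for resolving
    origin mixtures *within* a group (e.g. the fibroblast pool).
    """
    sex = np.where(detections["male_detect"] & ~detections["female_detect"], "M",
          np.where(detections["female_detect"] & ~detections["male_detect"], "F",
                   "ambiguous"))
    out = []
    for s, call in zip(samples.loc[detections.index], sex):
        pair = pairs.get(s)
        if pair is None:
            raise ConfigurationError(f"no SamplePair for sample {s!r}")
        if not pair.informative:
            out.append("unassignable")
        elif call == pair.donor_sex:
            out.append("donor")
        elif call == pair.recipient_sex:
            out.append("recipient")
        else:
            out.append("ambiguous")
    return pd.Series(out, index=detections.index, name="origin")


def origin_composition(cell_origins: pd.Series, cell_types: pd.Series,
                       samples: pd.Series) -> pd.DataFrame:
    """Per (sample, cell type) origin counts and recipient fraction.

    ``recipient_fraction`` = n_recipient / (n_donor + n_recipient), NaN when
    no cell of the group received a donor or recipient call.
    """
    df = pd.DataFrame({"origin": cell_origins, "cell_type": cell_types,
                       "sample": samples}).loc[cell_origins.index]
    rows = []
    for (sample, ctype), grp in df.groupby(["sample", "cell_type"], sort=True,
                                           observed=True):
        n_donor = int((grp["origin"] == "donor").sum())
        n_recipient = int((grp["origin"] == "recipient").sum())
        n_ambiguous = int(len(grp) - n_donor - n_recipient)
        denom = n_donor + n_recipient
        rows.append({
            "sample": sample, "cell_type": ctype, "n_donor": n_donor,
            "n_recipient": n_recipient, "n_ambiguous": n_ambiguous,
            "recipient_fraction": n_recipient / denom if denom else np.nan,
        })
    return pd.DataFrame(rows)


def genotype_concordance(cell_origins: pd.Series,
                         genotype_clusters: pd.Series) -> pd.DataFrame:
    """Cross-tabulate sex-based origin calls against an external per-cell
    genotype clustering (e.g. variant-based demultiplexing), for
    verification that the two partitions agree."""
    common = cell_origins.index.intersection(genotype_clusters.index)
    return pd.crosstab(cell_origins.loc[common], genotype_clusters.loc[common])
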