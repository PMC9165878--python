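"""Shared fixtures: tiny hand-built matrices and a simulated three-sample
sex-mismatched dataset reused across module tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from graftsc.origin import SamplePair
from graftsc.simulate import SampleSpec, SimConfig, generate_dataset


def make_adata(counts: np.ndarray, genes: list[str],
               barcodes: list[str] | None = None,
               samples: list[str] | None = None) -> AnnData:
    """Cells x genes AnnData from a dense array."""
    counts = np.asarray(counts)
    barcodes = barcodes or [f"cell{i + 1}" for i in range(counts.shape[0])]
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    if samples is not None:
        adata.obs["sample"] = samples
    return adata


def mismatched_config(n_per_type: int = 60, seed: int = 0,
                      **overrides) -> SimConfig:
    """Three-biopsy design: one same-sex control and two sex-mismatched
    allografts with fully recipient-derived immune infiltrates."""
    types = {"PT": n_per_type, "FB": n_per_type, "EC": n_per_type,
             "TC": n_per_type, "MAC": n_per_type, "BC.PLASMA": n_per_type}
    samples = [
        SampleSpec("HK", "F", "F", dict(types)),
        SampleSpec("AK1", "M", "F", dict(types),
                   {"TC": 1.0, "MAC": 1.0, "BC.PLASMA": 1.0, "FB": 0.6}),
        SampleSpec("AK2", "F", "M", dict(types),
                   {"TC": 1.0, "MAC": 1.0, "BC.PLASMA": 1.0}),
    ]
    defaults = dict(samples=samples, genes=600, seed=seed,
                    xist_silent_types=("PT",), marker_boost=50.0)
    defaults.update(overrides)
    return SimConfig(**defaults)


def pairs_for(config: SimConfig) -> dict[str, SamplePair]:
    return {s.sample_id: SamplePair(s.sample_id, s.donor_sex, s.recipient_sex)
            for s in config.samples}


@pytest.fixture(scope="session")
def sim_dataset():
    """Simulated dataset with doublets and mito outliers, plus its truth."""
    config = mismatched_config(n_per_type=60, seed=11, doublet_rate=0.02,
                               mito_outlier_rate=0.05)
    adata, truth = generate_dataset(config)
    return config, adata, truth


@pytest.fixture(scope="session")
def clean_sim_dataset():
    """Simulated dataset without doublets or mito outliers."""
    config = mismatched_config(n_per_type=60, seed=5)
    adata, truth = generate_dataset(config)
    return config, adata, truth
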