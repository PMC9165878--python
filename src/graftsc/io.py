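"""Readers and writers: 10x-style MTX triplets, TSV tables, catalogs.

The on-disk layout follows the 10x Genomics convention: a MatrixMarket
coordinate file with genes as rows and cells as columns (1-based indices),
a features TSV and a barcodes TSV. Internally the matrix is transposed to
cells x genes. All readers are gzip-transparent by file suffix.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData


class MtxParseError(ValueError):
    """Malformed MTX triplet (bad header or mismatched dimensions)."""


def _open(path: Path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(directory: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        p = directory / f"{stem}{suffix}"
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def read_mtx_triplet(source: str | Path, features: str | Path | None = None,
                     barcodes: str | Path | None = None) -> AnnData:
    """Read a matrix.mtx / features.tsv / barcodes.tsv triplet.

    ``source`` is either a directory holding the three conventionally named
    files (``matrix.mtx``, ``features.tsv`` or ``genes.tsv``,
    ``barcodes.tsv``, optionally gzipped) or the matrix file itself with
    the two companions passed explicitly. Duplicate gene symbols are
    disambiguated by numeric suffix with a warning.
    """
    source = Path(source)
    if source.is_dir():
        matrix_path = _find(source, "matrix.mtx")
        try:
            features_path = _find(source, "features.tsv")
        except FileNotFoundError:
            features_path = _find(source, "genes.tsv")
        barcodes_path = _find(source, "barcodes.tsv")
    else:
        if features is None or barcodes is None:
            raise ValueError("features and barcodes paths required when "
                             "source is a file")
        matrix_path, features_path, barcodes_path = source, Path(features), \
            Path(barcodes)

    try:
        with _open(matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except ValueError as exc:
        raise MtxParseError(f"{matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat.T)  # genes x cells on disk -> cells x genes

    feat = pd.read_csv(_open(features_path), sep="\t", header=None)
    symbols = feat.iloc[:, 1] if feat.shape[1] >= 2 else feat.iloc[:, 0]
    symbols = symbols.astype(str)
    bc = pd.read_csv(_open(barcodes_path), sep="\t", header=None)
    barcodes_list = bc.iloc[:, 0].astype(str)

    if len(symbols) != mat.shape[1]:
        raise MtxParseError(
            f"{features_path}: {len(symbols)} features but matrix has "
            f"{mat.shape[1]} gene rows")
    if len(barcodes_list) != mat.shape[0]:
        raise MtxParseError(
            f"{barcodes_path}: {len(barcodes_list)} barcodes but matrix has "
            f"{mat.shape[0]} cell columns")

    if symbols.duplicated().any():
        dups = symbols[symbols.duplicated()].unique()
        warnings.warn(f"duplicate gene symbols disambiguated: {list(dups)[:5]}",
                      stacklevel=2)
        symbols = pd.Index(symbols).where(
            ~pd.Index(symbols).duplicated(),
            [f"{s}-{i}" for i, s in enumerate(symbols)])

    return AnnData(X=mat,
                   obs=pd.DataFrame(index=pd.Index(barcodes_list, name="barcode")),
                   var=pd.DataFrame(index=pd.Index(symbols, name="gene")))


def write_mtx_triplet(adata: AnnData, directory: str | Path) -> None:
    """Write an AnnData as a 10x-style triplet (genes x cells on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(X.T))
    pd.DataFrame({"id": adata.var_names, "symbol": adata.var_names}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False)


def write_table(df: pd.DataFrame, path: str | Path, comment: str = "",
                index: bool = True) -> None:
    """TSV writer with an optional leading ``#`` convention header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_matrisome_catalog(path: str | Path) -> dict[str, list[str]]:
    """Two-column (category, gene) TSV -> category -> gene list map."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["category", "gene"])
    catalog: dict[str, list[str]] = {}
    for cat, grp in df.groupby("category", sort=False):
        catalog[cat] = list(grp["gene"])
    seen: set[str] = set()
    for cat, genes in catalog.items():
        overlap = seen & set(genes)
        if overlap:
            raise ValueError(f"matrisome categories overlap on {sorted(overlap)}")
        seen |= set(genes)
    return catalog


def write_matrisome_catalog(catalog: dict[str, list[str]],
                            path: str | Path) -> None:
    rows = [(cat, g) for cat, genes in catalog.items() for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_sample_pairs(path: str | Path) -> dict:
    """sample_id / donor_sex / recipient_sex TSV -> SamplePair map."""
    from .origin import SamplePair
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "donor_sex", "recipient_sex"}
    if not required <= set(df.columns):
        raise ValueError(f"sample-pair table needs columns {sorted(required)}")
    return {r.sample_id: SamplePair(r.sample_id, r.donor_sex, r.recipient_sex)
            for r in df.itertuples()}


def read_marker_catalog(path: str | Path) -> dict[str, list[str]]:
    """Two-column (cell_type, gene) TSV -> marker panel map."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["cell_type", "gene"])
    return {t: list(g["gene"]) for t, g in df.groupby("cell_type", sort=False)}
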