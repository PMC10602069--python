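"""Readers and writers for the pipeline's plain-text formats.

Counts come in as Matrix Market triplets (``matrix.mtx`` with
``features.tsv``/``barcodes.tsv`` sidecars, the 10x convention: genes as
rows) or as a dense CSV (genes as rows, header = cell IDs).  Cell metadata,
phenotypes, bulk prior tables, and all stage outputs are CSV; gene sets are
GMT.  Output numbers use the default pandas formatting (scientific
notation where needed), UTF-8, comma separators.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import InvalidInputError
from .inference import FitResult
from .pseudobulk import CellDataset, PseudobulkDataset, mito_flags

__all__ = [
    "read_counts_mtx", "write_counts_mtx",
    "read_counts_csv", "write_counts_csv",
    "read_cell_metadata", "read_phenotypes", "read_bulk_prior_table",
    "read_gmt", "write_gmt", "read_gene_list", "write_gene_list",
    "build_cell_dataset", "write_pseudobulk", "read_pseudobulk",
    "write_fit_result", "write_screen_result", "write_enrichment",
]


# --- count matrices ---------------------------------------------------------

def read_counts_mtx(directory, matrix="matrix.mtx", features="features.tsv",
                    barcodes="barcodes.tsv"):
    """(counts genes x cells, gene_ids, cell_ids) from an MTX triplet directory."""
    d = Path(directory)
    m = spio.mmread(d / matrix)
    counts = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=float)
    gene_ids = pd.read_csv(d / features, sep="\t", header=None)[0].astype(str).to_numpy()
    cell_ids = pd.read_csv(d / barcodes, sep="\t", header=None)[0].astype(str).to_numpy()
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise InvalidInputError(
            f"matrix shape {counts.shape} does not match features x barcodes "
            f"({len(gene_ids)} x {len(cell_ids)})"
        )
    return counts, gene_ids, cell_ids


def write_counts_mtx(directory, counts, gene_ids, cell_ids, matrix="matrix.mtx",
                     features="features.tsv", barcodes="barcodes.tsv"):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(d / matrix, sparse.coo_matrix(np.asarray(counts, dtype=float)))
    pd.Series(gene_ids).to_csv(d / features, sep="\t", header=False, index=False)
    pd.Series(cell_ids).to_csv(d / barcodes, sep="\t", header=False, index=False)


def read_counts_csv(path):
    """Dense fallback: genes as rows, first column gene IDs, header = cell IDs."""
    df = pd.read_csv(path, index_col=0)
    return (
        df.to_numpy(dtype=float),
        df.index.astype(str).to_numpy(),
        df.columns.astype(str).to_numpy(),
    )


def write_counts_csv(path, counts, gene_ids, cell_ids):
    pd.DataFrame(np.asarray(counts, dtype=float), index=pd.Index(gene_ids, name="gene_id"),
                 columns=cell_ids).to_csv(path)


# --- tables -----------------------------------------------------------------

def _require(df: pd.DataFrame, cols, what: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} lacks required columns {missing}")
    return df


def read_cell_metadata(path) -> pd.DataFrame:
    """cell_id, donor_id, probability (one row per cell)."""
    df = _require(pd.read_csv(path), ("cell_id", "donor_id", "probability"), "cell metadata")
    df["cell_id"] = df["cell_id"].astype(str)
    df["donor_id"] = df["donor_id"].astype(str)
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """donor_id, group (0/1), optional covariate columns."""
    df = _require(pd.read_csv(path), ("donor_id", "group"), "phenotype table")
    df["donor_id"] = df["donor_id"].astype(str)
    return df


def read_bulk_prior_table(path) -> pd.DataFrame:
    df = _require(
        pd.read_csv(path), ("gene_id", "coefficient", "sampling_variance"), "bulk prior table"
    )
    df["gene_id"] = df["gene_id"].astype(str)
    return df


# --- gene sets --------------------------------------------------------------

def read_gmt(path) -> dict:
    """GMT: one set per line, ``name<TAB>description<TAB>gene1<TAB>...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InvalidInputError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path, gene_sets: dict, description: str = "na"):
    lines = [
        "\t".join([name, description, *map(str, genes)])
        for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list[str]:
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]


def write_gene_list(path, genes):
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


# --- assembled objects ------------------------------------------------------

def build_cell_dataset(counts, gene_ids, cell_ids, metadata: pd.DataFrame,
                       mito_prefix: str = "MT-") -> CellDataset:
    """Join a count matrix with per-cell metadata into a CellDataset."""
    meta = metadata.set_index(metadata["cell_id"].astype(str))
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise InvalidInputError(
            f"{len(missing)} cell(s) missing from metadata (e.g. {missing[:3]})"
        )
    meta = meta.loc[list(map(str, cell_ids))]
    return CellDataset(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        donor_of_cell=meta["donor_id"].to_numpy(dtype=str),
        weight_of_cell=meta["probability"].to_numpy(dtype=float),
        mito_flag=mito_flags(gene_ids, prefix=mito_prefix),
    )


def write_pseudobulk(pb: PseudobulkDataset, y_path, donors_path):
    """Two CSVs: the genes x donors Y matrix and the donor table."""
    pd.DataFrame(pb.Y, index=pd.Index(pb.gene_ids, name="gene_id"),
                 columns=pb.donors).to_csv(y_path)
    donor_tbl = pd.DataFrame({"donor_id": pb.donors, "n_cells_used": pb.n_cells_used})
    if pb.group is not None:
        donor_tbl["group"] = pb.group.astype(int)
    if pb.x2 is not None:
        donor_tbl["x2"] = pb.x2
    donor_tbl.to_csv(donors_path, index=False)


def read_pseudobulk(y_path, donors_path) -> PseudobulkDataset:
    ydf = pd.read_csv(y_path, index_col=0)
    donor_tbl = pd.read_csv(donors_path)
    _require(donor_tbl, ("donor_id",), "donor table")
    donor_tbl["donor_id"] = donor_tbl["donor_id"].astype(str)
    if list(ydf.columns.astype(str)) != list(donor_tbl["donor_id"]):
        raise InvalidInputError("donor order mismatch between Y matrix and donor table")
    return PseudobulkDataset(
        Y=ydf.to_numpy(dtype=float),
        gene_ids=ydf.index.astype(str).to_numpy(),
        donors=donor_tbl["donor_id"].to_numpy(),
        x2=donor_tbl["x2"].to_numpy(dtype=float) if "x2" in donor_tbl else None,
        group=donor_tbl["group"].to_numpy(dtype=float) if "group" in donor_tbl else None,
        n_cells_used=donor_tbl.get(
            "n_cells_used", pd.Series(np.zeros(len(donor_tbl), dtype=int))
        ).to_numpy(),
    )


def write_fit_result(fit: FitResult, path):
    fit.to_frame().to_csv(path, index=False)


def write_screen_result(result, path):
    tbl = result.table.copy()
    tbl.insert(1, "method", result.method)
    tbl.to_csv(path, index=False)


def write_enrichment(table: pd.DataFrame, path):
    table.to_csv(path, index=False)
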