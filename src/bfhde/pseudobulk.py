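"""QC filtering of gene x cell matrices and per-donor pseudo-bulk construction.

The aggregation here is *probability weighted*: each cell carries a
probability of belonging to the target cell type (e.g. alveolar
macrophages), supplied by an external classifier, and the per-donor
expression of a gene is the weighted average of that gene's counts across
the donor's cells with those probabilities as weights.  The same
probabilities, averaged per donor and negative-log transformed, form the
continuous covariate ``x2`` of the downstream regression.

Filtering conventions (all configurable):

* genes are kept when their mean across all current cells is strictly
  greater than 0.1;
* cells are dropped when their detected-gene count falls strictly below the
  2nd percentile of the per-cell distribution (linear-interpolation
  percentile), or when mitochondrial genes (name prefix ``MT-``,
  case-insensitive) make up more than 10% of their total counts;
* both cell rules are evaluated on the pre-filter distribution, and the
  gene filter runs before the cell filter by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, InvalidInputError

__all__ = [
    "CellDataset",
    "PseudobulkDataset",
    "mito_flags",
    "filter_genes",
    "filter_cells",
    "align_common_genes",
    "aggregate_weighted",
    "aggregate_hard_assigned",
    "make_x2",
]

DEFAULT_MITO_PREFIX = "MT-"


def mito_flags(gene_ids, prefix: str = DEFAULT_MITO_PREFIX, case_insensitive: bool = True):
    """Boolean mask of mitochondrial genes by name prefix."""
    ids = np.asarray(gene_ids, dtype=str)
    if case_insensitive:
        return np.char.startswith(np.char.upper(ids), prefix.upper())
    return np.char.startswith(ids, prefix)


@dataclass
class CellDataset:
    """Dense gene x cell expression matrix with per-cell donor and weight labels.

    ``weight_of_cell`` holds the target-cell-type probability in [0, 1];
    ``mito_flag`` marks mitochondrial genes (derived from ``gene_ids`` when
    not given).  ``filter_log`` accumulates a record per applied filter.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    donor_of_cell: np.ndarray
    weight_of_cell: np.ndarray
    mito_flag: np.ndarray | None = None
    filter_log: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        self.donor_of_cell = np.asarray(self.donor_of_cell, dtype=str)
        self.weight_of_cell = np.asarray(self.weight_of_cell, dtype=float)
        g, c = self.counts.shape
        if self.gene_ids.shape != (g,):
            raise InvalidInputError("gene_ids length must match count-matrix rows")
        if len(set(self.gene_ids)) != g:
            raise InvalidInputError("gene_ids must be unique")
        if not (self.cell_ids.shape == self.donor_of_cell.shape == self.weight_of_cell.shape == (c,)):
            raise InvalidInputError("per-cell arrays must match count-matrix columns")
        if len(set(self.cell_ids)) != c:
            raise InvalidInputError("cell_ids must be unique")
        if np.any((self.weight_of_cell < 0) | (self.weight_of_cell > 1)):
            raise InvalidInputError("cell weights must lie in [0, 1]")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        if self.mito_flag is None:
            self.mito_flag = mito_flags(self.gene_ids)
        self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
        if self.mito_flag.shape != (g,):
            raise InvalidInputError("mito_flag length must match gene count")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def donors(self) -> np.ndarray:
        """Donor identifiers in first-appearance order."""
        return pd.unique(self.donor_of_cell)

    def _subset(self, gene_mask=None, cell_mask=None, log_entry=None) -> "CellDataset":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else gene_mask
        cm = np.ones(self.n_cells, bool) if cell_mask is None else cell_mask
        log = list(self.filter_log)
        if log_entry is not None:
            log.append(log_entry)
        return CellDataset(
            counts=self.counts[np.ix_(gm, cm)],
            gene_ids=self.gene_ids[gm],
            cell_ids=self.cell_ids[cm],
            donor_of_cell=self.donor_of_cell[cm],
            weight_of_cell=self.weight_of_cell[cm],
            mito_flag=self.mito_flag[gm],
            filter_log=log,
        )


@dataclass
class PseudobulkDataset:
    """Per-donor pseudo-bulk matrix plus the regression covariates.

    ``Y`` is genes x donors; ``x2`` is the transformed mean probability per
    donor (absent for hard-assigned aggregation, which fits a
    two-coefficient model); ``group`` is attached from a phenotype table.
    """

    Y: np.ndarray
    gene_ids: np.ndarray
    donors: np.ndarray
    x2: np.ndarray | None
    group: np.ndarray | None
    n_cells_used: np.ndarray
    filter_log: list = field(default_factory=list)

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.donors = np.asarray(self.donors, dtype=str)
        if self.Y.shape != (len(self.gene_ids), len(self.donors)):
            raise InvalidInputError("Y must be genes x donors")

    @property
    def n_genes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_donors(self) -> int:
        return self.Y.shape[1]

    def attach_groups(self, donor_table: pd.DataFrame) -> "PseudobulkDataset":
        """Attach binary group labels from a (donor_id, group) table."""
        tbl = donor_table.set_index(donor_table["donor_id"].astype(str))
        missing = [d for d in self.donors if d not in tbl.index]
        if missing:
            raise InvalidInputError(f"donors missing from phenotype table: {missing}")
        self.group = tbl.loc[list(self.donors), "group"].to_numpy(dtype=float)
        if not set(np.unique(self.group)) <= {0.0, 1.0}:
            raise InvalidInputError("group labels must be binary 0/1")
        return self


def filter_genes(ds: CellDataset, threshold: float = 0.1) -> CellDataset:
    """Keep genes whose mean expression across current cells is > threshold (strict)."""
    if ds.n_genes == 0 or ds.n_cells == 0:
        raise EmptyResultError("empty dataset")
    means = ds.counts.mean(axis=1)
    keep = means > threshold
    if not keep.any():
        raise EmptyResultError(
            f"gene filter at threshold {threshold} removed all {ds.n_genes} genes "
            f"(max mean {means.max():.4g})"
        )
    entry = {
        "filter": "genes_mean_gt",
        "threshold": threshold,
        "n_in": ds.n_genes,
        "n_removed": int((~keep).sum()),
        "n_out": int(keep.sum()),
    }
    return ds._subset(gene_mask=keep, log_entry=entry)


def filter_cells(
    ds: CellDataset, mito_max: float = 0.10, detected_pct: float = 2.0
) -> CellDataset:
    """Drop low-complexity and high-mitochondrial cells.

    A cell is removed when its detected-gene count (entries > 0) is strictly
    below the ``detected_pct`` percentile of the per-cell distribution, or
    when its mitochondrial count fraction exceeds ``mito_max``.  Both rules
    use the pre-filter distribution; zero-total cells are removed with a
    warning since their mitochondrial fraction is undefined.
    """
    detected = (ds.counts > 0).sum(axis=0)
    cutoff = np.percentile(detected, detected_pct)  # linear interpolation
    low_complexity = detected < cutoff

    total = ds.counts.sum(axis=0)
    mito_total = ds.counts[ds.mito_flag, :].sum(axis=0)
    zero_total = total == 0
    if zero_total.any():
        warnings.warn(
            f"{int(zero_total.sum())} cell(s) with zero total counts removed "
            "(mitochondrial fraction undefined)",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero_total, np.nan, mito_total / total)
    high_mito = np.where(zero_total, True, mito_frac > mito_max)

    drop = low_complexity | high_mito
    keep = ~drop
    if not keep.any():
        raise EmptyResultError("cell filter removed all cells")
    entry = {
        "filter": "cells_qc",
        "mito_max": mito_max,
        "detected_pct": detected_pct,
        "detected_cutoff": float(cutoff),
        "n_in": ds.n_cells,
        "n_removed_low_complexity": int(low_complexity.sum()),
        "n_removed_high_mito": int((high_mito & ~low_complexity).sum()),
        "n_out": int(keep.sum()),
    }
    return ds._subset(cell_mask=keep, log_entry=entry)


def align_common_genes(ds_a: CellDataset, ds_b: CellDataset):
    """Restrict both datasets to the sorted intersection of their gene lists."""
    common = sorted(set(ds_a.gene_ids) & set(ds_b.gene_ids))
    if not common:
        raise EmptyResultError("no genes in common between the two datasets")

    def take(ds: CellDataset) -> CellDataset:
        pos = {g: i for i, g in enumerate(ds.gene_ids)}
        idx = np.array([pos[g] for g in common])
        entry = {"filter": "align_common_genes", "n_in": ds.n_genes, "n_out": len(common)}
        out = CellDataset(
            counts=ds.counts[idx, :],
            gene_ids=ds.gene_ids[idx],
            cell_ids=ds.cell_ids,
            donor_of_cell=ds.donor_of_cell,
            weight_of_cell=ds.weight_of_cell,
            mito_flag=ds.mito_flag[idx],
            filter_log=list(ds.filter_log) + [entry],
        )
        return out

    return take(ds_a), take(ds_b)


def make_x2(ds: CellDataset) -> np.ndarray:
    """Negative natural log of the donor-mean cell-type probability.

    One value per donor, in :attr:`CellDataset.donors` order.  Averaging
    happens before the log ("average then negative-log"); a donor whose mean
    probability is zero has no defined value and raises.
    """
    out = np.empty(len(ds.donors))
    for i, d in enumerate(ds.donors):
        m = ds.weight_of_cell[ds.donor_of_cell == d].mean()
        if m <= 0:
            raise InvalidInputError(f"donor {d!r} has mean probability 0; -log undefined")
        out[i] = -np.log(m)
    return out


def aggregate_weighted(ds: CellDataset) -> PseudobulkDataset:
    """Probability-weighted pseudo-bulk: Y[g, d] = sum_i w_i c_gi / sum_i w_i.

    The weighted average is normalized by the total weight, so Y is
    invariant to a global rescaling of the probabilities.  Also computes the
    ``x2`` covariate via :func:`make_x2`.  A donor with zero total weight
    has no defined average and raises.
    """
    donors = ds.donors
    Y = np.empty((ds.n_genes, len(donors)))
    n_used = np.empty(len(donors), dtype=int)
    for i, d in enumerate(donors):
        sel = ds.donor_of_cell == d
        w = ds.weight_of_cell[sel]
        if w.sum() <= 0:
            raise InvalidInputError(f"donor {d!r} has zero total weight; weighted mean undefined")
        Y[:, i] = ds.counts[:, sel] @ w / w.sum()
        n_used[i] = int(sel.sum())
    return PseudobulkDataset(
        Y=Y,
        gene_ids=ds.gene_ids,
        donors=donors,
        x2=make_x2(ds),
        group=None,
        n_cells_used=n_used,
        filter_log=list(ds.filter_log) + [{"aggregation": "weighted"}],
    )


def aggregate_hard_assigned(ds: CellDataset, prob_cutoff: float = 0.5) -> PseudobulkDataset:
    """Unweighted mean over cells called as the target type (weight >= cutoff).

    The classical pseudo-bulk baseline: threshold the probability, average
    the qualifying cells per donor.  Donors with no qualifying cell are
    excluded with a warning; no ``x2`` covariate is produced (downstream
    model has intercept and group only).
    """
    qualifies = ds.weight_of_cell >= prob_cutoff
    if not qualifies.any():
        raise EmptyResultError(f"no cell reaches probability cutoff {prob_cutoff}")
    donors, cols, n_used, skipped = [], [], [], []
    for d in ds.donors:
        sel = (ds.donor_of_cell == d) & qualifies
        if not sel.any():
            skipped.append(str(d))
            continue
        donors.append(d)
        cols.append(ds.counts[:, sel].mean(axis=1))
        n_used.append(int(sel.sum()))
    if skipped:
        warnings.warn(
            f"donors with no cell above cutoff {prob_cutoff} excluded: {skipped}",
            UserWarning,
            stacklevel=2,
        )
    return PseudobulkDataset(
        Y=np.column_stack(cols),
        gene_ids=ds.gene_ids,
        donors=np.asarray(donors, dtype=str),
        x2=None,
        group=None,
        n_cells_used=np.asarray(n_used, dtype=int),
        filter_log=list(ds.filter_log)
        + [{"aggregation": "hard_assigned", "prob_cutoff": prob_cutoff, "donors_excluded": skipped}],
    )
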