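"""Informative priors for the disease-group coefficient from bulk RNA-seq summaries.

Bulk RNA-seq case/control cohorts are typically far larger than single-cell
ones, so the covariate-adjusted group difference estimated per gene in bulk
is a natural prior center for the same gene's group coefficient in the
pseudo-bulk single-cell model.  The bulk sampling variance of that
difference is, however, usually very small relative to the effect, and
using it directly would pin the posterior to the bulk estimate; the prior
variance is therefore taken as the *square root* of the bulk sampling
variance, which inflates sub-unit variances toward a more moderate
dispersion (a deliberately heuristic rule, dimensionally inconsistent but
used as stated; set ``literal=True`` for the untransformed variance).

Coefficients without bulk information (intercept, probability covariate,
and any gene absent from the bulk table) keep the non-informative
N(0, 100) prior.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidPriorError
from .inference import PriorSpec, RegressionData, fit_frequentist

__all__ = [
    "prior_from_bulk",
    "bulk_coefficients",
    "noninformative_prior",
    "assemble_gene_prior",
    "gene_prior_source",
]

BULK_TABLE_COLUMNS = ("gene_id", "coefficient", "sampling_variance")


def _check_bulk_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BULK_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"bulk prior table lacks columns {missing}")
    if table["gene_id"].duplicated().any():
        raise InvalidInputError("bulk prior table has duplicated gene_id entries")
    if (table["sampling_variance"] < 0).any():
        raise InvalidInputError("sampling_variance must be nonnegative")
    return table


def prior_from_bulk(
    coefficient: float, sampling_variance: float, literal: bool = False
) -> tuple[float, float]:
    """(prior mean, prior variance) from one bulk DE summary row.

    mean = bulk coefficient; variance = sqrt(sampling variance) by default
    (``literal=True`` uses the sampling variance unchanged).
    """
    if sampling_variance <= 0:
        raise InvalidPriorError(
            "sampling_variance must be > 0 (a zero-variance prior is degenerate)"
        )
    var = float(sampling_variance) if literal else float(np.sqrt(sampling_variance))
    return float(coefficient), var


def bulk_coefficients(
    expr: pd.DataFrame,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene adjusted group difference from a bulk samples x genes matrix.

    For each gene, OLS of expression on (intercept, group, covariates); the
    returned table holds the group coefficient and its squared standard
    error, i.e. exactly what :func:`prior_from_bulk` consumes.
    """
    group = np.asarray(group, dtype=float).ravel()
    n = len(expr)
    if group.shape[0] != n:
        raise InvalidInputError("group length must match number of bulk samples")
    cols = [np.ones(n), group]
    names = ["intercept", "group"]
    if covariates is not None:
        if len(covariates) != n:
            raise InvalidInputError("covariate rows must match number of bulk samples")
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if n < X.shape[1] + 1:
        raise InvalidInputError(
            f"need at least {X.shape[1] + 1} samples for {X.shape[1]} coefficients"
        )
    rows = []
    for gene in expr.columns:
        data = RegressionData(Y=expr[gene].to_numpy(dtype=float), X=X, names=tuple(names))
        fit = fit_frequentist(data)
        rows.append(
            {
                "gene_id": str(gene),
                "coefficient": fit["group"]["estimate"],
                "sampling_variance": fit["group"]["se"] ** 2,
            }
        )
    return pd.DataFrame(rows)


def noninformative_prior(p: int, bayes_index=None) -> PriorSpec:
    """N(0, 100) on every coefficient; partition per ``bayes_index`` (default: all Bayesian)."""
    return PriorSpec.noninformative(p, bayes_index=bayes_index)


def assemble_gene_prior(
    gene: str,
    table: pd.DataFrame,
    p: int = 3,
    bayes_index: int = 1,
    literal: bool = False,
) -> PriorSpec:
    """Mixed prior for one gene: bulk-informed at ``bayes_index``, N(0, 100) elsewhere.

    The partition mask is True only at ``bayes_index`` (the hybrid default:
    one Bayesian coefficient, the rest frequentist).  A gene missing from
    the table falls back to the fully non-informative prior with a notice,
    keeping the gene universe intact for downstream enrichment.
    """
    if not 0 <= bayes_index < p:
        raise InvalidInputError(f"bayes_index {bayes_index} out of range for p={p}")
    _check_bulk_table(table)
    mean = np.zeros(p)
    var = np.full(p, 100.0)
    mask = np.zeros(p, dtype=bool)
    mask[bayes_index] = True
    hit = table.loc[table["gene_id"].astype(str) == str(gene)]
    if hit.empty:
        warnings.warn(
            f"gene {gene!r} absent from bulk prior table; using non-informative prior",
            UserWarning,
            stacklevel=2,
        )
    else:
        row = hit.iloc[0]
        mean[bayes_index], var[bayes_index] = prior_from_bulk(
            row["coefficient"], row["sampling_variance"], literal=literal
        )
    return PriorSpec(mean=mean, variance=var, partition=mask)


def gene_prior_source(
    table: pd.DataFrame, p: int = 3, bayes_index: int = 1, literal: bool = False
) -> Callable[[str], PriorSpec]:
    """Vectorized gene -> PriorSpec lookup over a bulk table (silent fallback).

    Returns a callable suitable for :func:`bfhde.screen.screen_genes`; genes
    absent from the table get the non-informative prior without a per-gene
    warning (the screen logs the count instead).
    """
    _check_bulk_table(table)
    lookup = {
        str(r.gene_id): (float(r.coefficient), float(r.sampling_variance))
        for r in table.itertuples()
    }

    def source(gene: str) -> PriorSpec:
        mean = np.zeros(p)
        var = np.full(p, 100.0)
        mask = np.zeros(p, dtype=bool)
        mask[bayes_index] = True
        if str(gene) in lookup:
            coef, sv = lookup[str(gene)]
            mean[bayes_index], var[bayes_index] = prior_from_bulk(coef, sv, literal=literal)
        return PriorSpec(mean=mean, variance=var, partition=mask)

    return source
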