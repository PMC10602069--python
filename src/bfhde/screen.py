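"""Per-gene differential-expression screening with BH-FDR and effect-size cuts.

Each gene in a pseudo-bulk dataset is fit with one of the inference methods
(frequentist OLS, conjugate Bayes, or the hybrid), the group-coefficient
p-values are Benjamini-Hochberg adjusted across all successfully fitted
genes, and a gene is selected when its adjusted p-value falls below
``alpha`` (default 0.01) and its absolute group estimate reaches
``effect_min`` (default 0.585, i.e. log2(1.5) on a log2 scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError
from .inference import (
    PriorSpec,
    RegressionData,
    fit_bayes_conjugate,
    fit_frequentist,
    fit_hybrid_em,
)
from .priors import noninformative_prior
from .pseudobulk import PseudobulkDataset

__all__ = ["ScreenResult", "bh_adjust", "screen_genes", "METHODS"]

logger = logging.getLogger(__name__)

METHODS = ("frequentist", "bayes", "hybrid")


@dataclass
class ScreenResult:
    """Per-gene estimates and selection flags plus the screen's settings."""

    table: pd.DataFrame  # gene, estimate, se, pvalue, adj_pvalue, selected
    method: str
    alpha: float
    effect_min: float
    n_genes: int

    @property
    def selected_genes(self) -> list[str]:
        sel = self.table.loc[self.table["selected"].fillna(False).astype(bool), "gene"]
        return [str(g) for g in sel]

    @property
    def tested_genes(self) -> list[str]:
        ok = self.table["pvalue"].notna()
        return [str(g) for g in self.table.loc[ok, "gene"]]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("pvalues must be a nonempty 1-d array")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_genes(
    pb: PseudobulkDataset,
    method: str = "hybrid",
    priors: Callable[[str], PriorSpec] | None = None,
    alpha: float = 0.01,
    effect_min: float = 0.585,
    em_tol: float = 1e-8,
    em_max_iter: int = 100,
) -> ScreenResult:
    """Fit every gene, adjust group-coefficient p-values, select DE genes.

    Parameters
    ----------
    pb : PseudobulkDataset
        Must have binary ``group`` attached; the design is (intercept,
        group) plus ``x2`` when the dataset carries one.
    method : {"frequentist", "bayes", "hybrid"}
    priors : callable gene -> PriorSpec, optional
        Per-gene prior source (see :func:`bfhde.priors.gene_prior_source`).
        Ignored by the frequentist method; defaults to the non-informative
        prior with the group coefficient Bayesian.
    alpha, effect_min : float
        Selection thresholds: BH-adjusted p < alpha and |estimate| >=
        effect_min, both applied to the group coefficient.

    Genes whose fit fails are reported with NA and excluded from the BH
    universe.  The residual variance is estimated per gene.
    """
    if method not in METHODS:
        raise InvalidInputError(f"method must be one of {METHODS}")
    if pb.group is None:
        raise InvalidInputError("pseudobulk dataset has no group labels attached")
    group = np.asarray(pb.group, dtype=float)
    for g01 in (0.0, 1.0):
        if (group == g01).sum() < 2:
            raise InvalidInputError("need at least 2 donors per group")

    cols = [np.ones(pb.n_donors), group]
    names = ["intercept", "group"]
    if pb.x2 is not None:
        cols.append(np.asarray(pb.x2, dtype=float))
        names.append("x2")
    X = np.column_stack(cols)
    p = X.shape[1]
    group_idx = names.index("group")
    if priors is None:
        default_prior = noninformative_prior(p, bayes_index=group_idx)
        priors = lambda gene: default_prior  # noqa: E731

    rows, n_failed = [], 0
    for gi, gene in enumerate(pb.gene_ids):
        data = RegressionData(Y=pb.Y[gi], X=X, names=tuple(names))
        try:
            if method == "frequentist":
                fit = fit_frequentist(data)
            elif method == "bayes":
                fit = fit_bayes_conjugate(data, priors(gene))
            else:
                fit = fit_hybrid_em(data, priors(gene), tol=em_tol, max_iter=em_max_iter)
            b1 = fit["group"]
            rows.append((str(gene), b1["estimate"], b1["se"], b1["pvalue"]))
        except Exception as exc:  # fit failure: report NA, drop from BH universe
            n_failed += 1
            logger.warning("gene %s: fit failed (%s)", gene, exc)
            rows.append((str(gene), np.nan, np.nan, np.nan))
    if n_failed:
        logger.warning("%d gene(s) failed to fit and were excluded from FDR control", n_failed)

    table = pd.DataFrame(rows, columns=["gene", "estimate", "se", "pvalue"])
    ok = table["pvalue"].notna()
    adj = pd.Series(np.nan, index=table.index)
    if ok.any():
        adj[ok] = bh_adjust(table.loc[ok, "pvalue"].to_numpy())
    table["adj_pvalue"] = adj
    table["selected"] = (
        (table["adj_pvalue"] < alpha) & (table["estimate"].abs() >= effect_min)
    ).astype("boolean")
    table.loc[~ok, "selected"] = pd.NA
    return ScreenResult(
        table=table, method=method, alpha=alpha, effect_min=effect_min, n_genes=int(ok.sum())
    )
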