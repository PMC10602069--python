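"""Hypergeometric over-representation analysis of gene sets.

For an experiment list of size R drawn from a background universe of size
N, a pathway of size n (after intersecting with the background), and an
overlap of r genes, the enrichment p-value is the inclusive upper tail

    p = P(X >= r),   X ~ Hypergeometric(N, n, R),

and the z-score is the overlap standardized by the hypergeometric moments

    z = (r - Rn/N) / sqrt( R (n/N) (1 - n/N) (N - R)/(N - 1) ).

Tail probabilities are accumulated in log space (log-gamma based pmf +
logsumexp), so values far below double underflow of individual terms are
still computed accurately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .exceptions import EmptyResultError, InvalidInputError
from .screen import bh_adjust

__all__ = ["EnrichmentResult", "hypergeom_enrichment", "run_enrichment"]


@dataclass
class EnrichmentResult:
    """One pathway's overlap counts and enrichment statistics."""

    pathway: str
    r: int
    R: int
    n: int
    N: int
    zscore: float
    pvalue: float
    qvalue: float = np.nan


def _validate_counts(r: int, R: int, n: int, N: int) -> None:
    if min(r, R, n, N) < 0 or N == 0:
        raise InvalidInputError("counts must be nonnegative with N > 0")
    if R > N or n > N:
        raise InvalidInputError("list and term sizes cannot exceed the background size")
    if r > min(R, n):
        raise InvalidInputError("overlap cannot exceed either list size")
    if r < max(0, R + n - N):
        raise InvalidInputError("overlap below the feasible minimum for these sizes")


def hypergeom_enrichment(r: int, R: int, n: int, N: int) -> tuple[float, float]:
    """(z-score, upper-tail p-value) for an overlap of r genes.

    ``R`` is the experiment-list size, ``n`` the pathway size, ``N`` the
    background size.  The p-value includes r itself; r = 0 therefore gives
    p = 1 exactly.
    """
    _validate_counts(r, R, n, N)
    mean = R * n / N
    if N == 1 or n == 0 or n == N or R == 0 or R == N:
        sd = 0.0
    else:
        sd = np.sqrt(R * (n / N) * (1 - n / N) * (N - R) / (N - 1))
    z = np.inf if sd == 0 and r != mean else (0.0 if sd == 0 else (r - mean) / sd)

    if r == 0:
        return float(z), 1.0  # inclusive tail covers the whole support
    k = np.arange(r, min(R, n) + 1)
    logp = hypergeom.logpmf(k, N, n, R)
    p = float(np.exp(logsumexp(logp))) if k.size else 0.0
    return float(z), min(p, 1.0)


def run_enrichment(
    selected_genes,
    gene_sets: dict,
    background,
    q_max: float = 0.05,
    p_max: float | None = None,
) -> pd.DataFrame:
    """Score every gene set against a selected-gene list within a background.

    Gene sets are intersected with the background before sizing; sets empty
    after intersection are skipped.  q-values are BH across all tested
    sets.  The returned table is filtered to ``qvalue < q_max`` (or, when
    ``p_max`` is given instead, to ``pvalue < p_max``) and sorted by
    ascending q-value then p-value.

    Columns: pathway, r, R, n, N, zscore, pvalue, qvalue.
    """
    background = set(map(str, background))
    if not background:
        raise EmptyResultError("background gene universe is empty")
    selected = set(map(str, selected_genes))
    stray = selected - background
    if stray:
        raise InvalidInputError(
            f"{len(stray)} selected gene(s) not in the background universe "
            f"(e.g. {sorted(stray)[:3]})"
        )
    N = len(background)
    R = len(selected)

    rows = []
    for name, members in gene_sets.items():
        term = set(map(str, members)) & background
        if not term:
            continue
        n = len(term)
        r = len(term & selected)
        z, p = hypergeom_enrichment(r, R, n, N)
        rows.append({"pathway": str(name), "r": r, "R": R, "n": n, "N": N,
                     "zscore": z, "pvalue": p})
    out = pd.DataFrame(rows, columns=["pathway", "r", "R", "n", "N", "zscore", "pvalue"])
    if out.empty:
        out["qvalue"] = pd.Series(dtype=float)
        return out
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    if p_max is not None:
        out = out[out["pvalue"] < p_max]
    else:
        out = out[out["qvalue"] < q_max]
    return out.sort_values(["qvalue", "pvalue", "pathway"]).reset_index(drop=True)
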