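"""Synthetic single-cell cohorts with known ground truth for pipeline testing.

The generator emulates the structure of a two-group (control vs disease)
single-cell cohort analyzed through probability-weighted pseudo-bulk:

* two donor groups (defaults 10 control / 12 case, the cohort size the
  pipeline is designed around), each donor contributing a configurable
  number of cells;
* each cell is target-type (e.g. alveolar macrophage) with probability
  ``target_fraction``; its classifier probability (the aggregation weight)
  is drawn from a Beta component per true type, sharply separated by
  default — Beta(20, 1) for target cells, Beta(1, 20) for the rest — as a
  well-trained classifier would produce;
* gene expression is continuous and nonnegative (normal around a per-gene
  baseline, clipped at zero): DE genes gain ``beta1_effect`` in target
  cells of case donors, every gene carries a per-donor random intercept
  (sd ``donor_sd``) and per-cell noise (sd ``noise_sd``), and a random
  ``sparsity`` fraction of entries is zeroed to mimic the zero excess of
  droplet data;
* mitochondrial genes (names ``MT-...``) are scaled per cell so that the
  mitochondrial fraction follows a Beta law, giving the QC filters
  realistic work;
* a bulk-prior table carries each gene's true effect plus noise, and a GMT
  collection contains one pathway enriched for true DE genes among random
  decoys.

Everything derives from one seed through named independent substreams, so
outputs are bitwise reproducible and adding draws to one stage never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .inference import RegressionData
from .pseudobulk import CellDataset

__all__ = ["SynthConfig", "SynthData", "generate_dataset", "generate_toy_regression"]

_STREAMS = ("cells", "expression", "mito", "bulk", "gene_sets")


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort; defaults are the package's study conditions."""

    n_control: int = 10
    n_case: int = 12
    cells_per_donor: int | tuple[int, int] = 200
    n_genes: int = 300
    frac_de: float = 0.1
    beta1_effect: float = 1.0
    target_fraction: float = 0.5
    prob_target: tuple[float, float] = (20.0, 1.0)
    prob_nontarget: tuple[float, float] = (1.0, 20.0)
    base_range: tuple[float, float] = (3.0, 6.0)
    noise_sd: float = 0.5
    donor_sd: float = 0.25
    sparsity: float = 0.03
    mito_n_genes: int | None = None  # default: 5% of n_genes
    mito_fraction_dist: tuple[float, float] = (2.0, 40.0)
    prior_noise_sd: float = 0.1
    n_gene_sets: int = 20
    gene_set_size: tuple[int, int] = (15, 50)
    enriched_set_frac_de: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if min(self.n_control, self.n_case) < 1 or self.n_genes < 1:
            raise InvalidInputError("donor and gene counts must be positive")
        if not 0 <= self.frac_de <= 1:
            raise InvalidInputError("frac_de must lie in [0, 1]")
        if not 0 <= self.target_fraction <= 1:
            raise InvalidInputError("target_fraction must lie in [0, 1]")
        if not 0 <= self.sparsity < 1:
            raise InvalidInputError("sparsity must lie in [0, 1)")
        if self.noise_sd <= 0 or self.prior_noise_sd < 0 or self.donor_sd < 0:
            raise InvalidInputError("noise scales must be nonnegative (noise_sd > 0)")
        cpd = self.cells_per_donor
        if isinstance(cpd, int):
            ok = cpd >= 1
        else:
            ok = len(cpd) == 2 and 1 <= cpd[0] <= cpd[1]
        if not ok:
            raise InvalidInputError("cells_per_donor must be a positive int or (lo, hi)")

    @property
    def n_mito(self) -> int:
        if self.mito_n_genes is not None:
            return self.mito_n_genes
        return max(1, round(0.05 * self.n_genes))


class SynthData(NamedTuple):
    """Generator output: inputs for every pipeline stage plus ground truth."""

    cells: CellDataset
    donors: pd.DataFrame        # donor_id, group
    bulk_prior: pd.DataFrame    # gene_id, coefficient, sampling_variance
    gene_sets: dict             # name -> list of gene_ids
    gene_truth: pd.DataFrame    # gene_id, is_de, true_effect, is_mito
    cell_truth: pd.DataFrame    # cell_id, donor_id, is_target, probability


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_dataset(cfg: SynthConfig) -> SynthData:
    """Draw one full synthetic cohort (deterministic given ``cfg.seed``)."""
    rng = _streams(cfg.seed)

    # --- donors and cells ---------------------------------------------------
    n_donors = cfg.n_control + cfg.n_case
    donor_ids = np.array([f"D{i:03d}" for i in range(n_donors)])
    group = np.concatenate([np.zeros(cfg.n_control), np.ones(cfg.n_case)])
    donors = pd.DataFrame({"donor_id": donor_ids, "group": group.astype(int)})

    r_cells = rng["cells"]
    if isinstance(cfg.cells_per_donor, int):
        n_cells_donor = np.full(n_donors, cfg.cells_per_donor)
    else:
        lo, hi = cfg.cells_per_donor
        n_cells_donor = r_cells.integers(lo, hi + 1, size=n_donors)
    donor_of_cell = np.repeat(donor_ids, n_cells_donor)
    n_cells = len(donor_of_cell)
    cell_ids = np.array([f"C{i:06d}" for i in range(n_cells)])
    is_target = r_cells.random(n_cells) < cfg.target_fraction
    prob = np.where(
        is_target,
        r_cells.beta(*cfg.prob_target, size=n_cells),
        r_cells.beta(*cfg.prob_nontarget, size=n_cells),
    )

    # --- genes --------------------------------------------------------------
    n_mito = cfg.n_mito
    n_regular = cfg.n_genes - n_mito
    gene_ids = np.array(
        [f"MT-G{i:04d}" for i in range(n_mito)] + [f"G{i:04d}" for i in range(n_regular)]
    )
    r_expr = rng["expression"]
    regular_idx = np.arange(n_mito, cfg.n_genes)
    n_de = int(round(cfg.frac_de * n_regular))
    de_idx = np.sort(r_expr.choice(regular_idx, size=n_de, replace=False))
    true_effect = np.zeros(cfg.n_genes)
    true_effect[de_idx] = cfg.beta1_effect
    base = r_expr.uniform(*cfg.base_range, size=cfg.n_genes)

    # --- expression ---------------------------------------------------------
    group_of_cell = group[np.searchsorted(donor_ids, donor_of_cell)]
    donor_pos = np.searchsorted(donor_ids, donor_of_cell)
    donor_shift = r_expr.normal(0.0, cfg.donor_sd, size=(cfg.n_genes, n_donors))
    mean = (
        base[:, None]
        + true_effect[:, None] * (group_of_cell * is_target)[None, :]
        + donor_shift[:, donor_pos]
    )
    counts = np.clip(mean + r_expr.normal(0.0, cfg.noise_sd, size=mean.shape), 0.0, None)
    if cfg.sparsity > 0:
        counts[r_expr.random(counts.shape) < cfg.sparsity] = 0.0

    # mitochondrial rows rescaled so the per-cell mito fraction follows a Beta law
    r_mito = rng["mito"]
    phi = r_mito.beta(*cfg.mito_fraction_dist, size=n_cells)
    nonmito_total = counts[n_mito:, :].sum(axis=0)
    mito_total = phi / (1.0 - phi) * nonmito_total
    split = r_mito.dirichlet(np.ones(n_mito), size=n_cells).T  # n_mito x cells
    counts[:n_mito, :] = mito_total[None, :] * split

    cells = CellDataset(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        donor_of_cell=donor_of_cell,
        weight_of_cell=prob,
    )

    # --- bulk prior table ---------------------------------------------------
    r_bulk = rng["bulk"]
    coef = true_effect + r_bulk.normal(0.0, cfg.prior_noise_sd, size=cfg.n_genes)
    sv = max(cfg.prior_noise_sd, 1e-3) ** 2
    bulk_prior = pd.DataFrame(
        {"gene_id": gene_ids, "coefficient": coef, "sampling_variance": sv}
    )

    # --- gene sets ----------------------------------------------------------
    r_sets = rng["gene_sets"]
    gene_sets: dict[str, list[str]] = {}
    de_genes = gene_ids[de_idx]
    lo, hi = cfg.gene_set_size
    lo, hi = min(lo, cfg.n_genes), min(hi, cfg.n_genes)  # small universes
    if n_de > 0 and cfg.n_gene_sets > 0:
        size = int(r_sets.integers(lo, hi + 1))
        k_de = min(n_de, int(round(cfg.enriched_set_frac_de * size)))
        members = list(r_sets.choice(de_genes, size=k_de, replace=False))
        pool = np.setdiff1d(gene_ids, members)
        members += list(r_sets.choice(pool, size=size - k_de, replace=False))
        gene_sets["pathway_enriched"] = sorted(members)
    for i in range(max(0, cfg.n_gene_sets - len(gene_sets))):
        size = int(r_sets.integers(lo, hi + 1))
        gene_sets[f"pathway_random_{i:02d}"] = sorted(
            r_sets.choice(gene_ids, size=size, replace=False)
        )

    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": true_effect != 0,
            "true_effect": true_effect,
            "is_mito": np.arange(cfg.n_genes) < n_mito,
        }
    )
    cell_truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor_id": donor_of_cell,
            "is_target": is_target,
            "probability": prob,
        }
    )
    return SynthData(cells, donors, bulk_prior, gene_sets, gene_truth, cell_truth)


def generate_toy_regression(
    n: int, beta, sigma: float, seed: int = 0
) -> RegressionData:
    """Small donor-level regression instance: intercept, balanced binary group, x2.

    ``Y = X beta + N(0, sigma^2)``; ``x2`` is uniform on [0.2, 1.5] (the
    range a negative-log mean probability typically occupies).  Deterministic
    given ``seed``.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if len(beta) != 3:
        raise InvalidInputError("beta must have 3 entries (intercept, group, x2)")
    if n <= len(beta):
        raise InvalidInputError("n must exceed the number of coefficients")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    group = np.zeros(n)
    group[rng.permutation(n)[: n // 2]] = 1.0
    x2 = rng.uniform(0.2, 1.5, size=n)
    X = np.column_stack([np.ones(n), group, x2])
    noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    return RegressionData(Y=X @ beta + noise, X=X, names=("intercept", "group", "x2"))
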