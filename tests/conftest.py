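import numpy as np
import pytest

from bfhde import CellDataset, RegressionData, SynthConfig, generate_dataset


def random_regression(seed, n=20, p=3, sigma=0.7):
    """Full-rank random instance with intercept, binary group, continuous x2."""
    rng = np.random.default_rng(seed)
    group = (np.arange(n) % 2).astype(float)
    extras = [rng.normal(size=n) for _ in range(p - 2)]
    X = np.column_stack([np.ones(n), group, *extras])
    beta = rng.normal(scale=1.0, size=p)
    Y = X @ beta + rng.normal(scale=sigma, size=n)
    names = ("intercept", "group") + tuple(f"x{j}" for j in range(2, p))
    return RegressionData(Y=Y, X=X, names=names), beta


@pytest.fixture
def toy_cells():
    """Tiny hand-checkable cell dataset: 3 genes (1 mito), 6 cells, 2 donors."""
    counts = np.array(
        [
            [1.0, 0.0, 2.0, 4.0, 0.0, 1.0],   # MT-CO1
            [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],   # GA
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # GB (all zero)
        ]
    )
    return CellDataset(
        counts=counts,
        gene_ids=np.array(["MT-CO1", "GA", "GB"]),
        cell_ids=np.array([f"c{i}" for i in range(6)]),
        donor_of_cell=np.array(["d1", "d1", "d1", "d2", "d2", "d2"]),
        weight_of_cell=np.array([0.9, 0.5, 0.1, 1.0, 0.2, 0.4]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by pipeline-level tests."""
    cfg = SynthConfig(n_genes=80, cells_per_donor=60, frac_de=0.15, seed=42)
    return cfg, generate_dataset(cfg)
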