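import numpy as np
import pandas as pd
import pytest

from xformscan import ExpressionMatrix, depth_scaled_scenario, simulate_counts

try:  # derandomize hypothesis when present
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 cells x 3 genes with two batches and two cell types."""
    values = np.array(
        [
            [1.0, 1.0, 2.0],
            [0.0, 2.0, 2.0],
            [3.0, 4.0, 0.0],
            [5.0, 0.0, 5.0],
        ]
    )
    meta = pd.DataFrame(
        {
            "batch": ["b0", "b0", "b1", "b1"],
            "cell_type": ["t0", "t1", "t0", "t1"],
        },
        index=pd.Index([f"c{i}" for i in range(4)], name="cell_id"),
    )
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(4)],
        gene_ids=["g0", "g1", "g2"],
        meta=meta,
    )


@pytest.fixture
def random_positive_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.gamma(2.0, 2.0, size=(30, 12)) + 0.01
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(30)],
        gene_ids=[f"g{j}" for j in range(12)],
        meta=pd.DataFrame(
            {"batch": ["b0"] * 15 + ["b1"] * 15},
            index=pd.Index([f"c{i}" for i in range(30)], name="cell_id"),
        ),
    )


@pytest.fixture(scope="session")
def depth_scenario() -> ExpressionMatrix:
    """Depth-only batch effect: 3 types x 2 batches, depth x5, 600 cells."""
    return simulate_counts(depth_scaled_scenario(seed=1))


@pytest.fixture(scope="session")
def small_depth_scenario() -> ExpressionMatrix:
    """Smaller variant for slower downstream stages (300 cells, 100 genes)."""
    return simulate_counts(
        depth_scaled_scenario(
            n_types=3, n_batches=2, cells_per_type_per_batch=50, n_genes=100, seed=2
        )
    )
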