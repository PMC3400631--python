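import numpy as np
import pytest

from dbomm import ExpressionMatrix, FitConfig


@pytest.fixture(scope="session")
def fast_config():
    """Reduced component search used where fit quality is not under test."""
    return FitConfig(g_max=3, n_restarts=2, seed=0)


@pytest.fixture()
def small_expr():
    """10-gene, 30-condition matrix with two planted co-regulated pairs."""
    rng = np.random.default_rng(42)
    values = rng.normal(8.0, 1.0, size=(10, 30))
    values[1] = values[0] * 0.9 + rng.normal(0, 0.3, 30)
    values[3] = -values[2] * 0.8 + rng.normal(0, 0.3, 30) + 16
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(10)],
        condition_ids=[f"c{j}" for j in range(30)],
    )
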