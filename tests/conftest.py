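import numpy as np
import pandas as pd
import pytest

from stemprofiler import ExpressionMatrix, GeneSet, SyntheticConfig


@pytest.fixture
def tiny_matrix():
    """3 probes x 2 samples, hand-written values."""
    df = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 7.0]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2"],
    )
    return ExpressionMatrix(values=df)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.uniform(1.0, 100.0, size=(50, 12)),
        index=[f"P{i}" for i in range(50)],
        columns=[f"S{j}" for j in range(12)],
    )
    return ExpressionMatrix(values=df)


@pytest.fixture
def small_config():
    return SyntheticConfig(n_probes=400, n_samples=30, n_reference=4,
                           subset_size=80, n_altered=40, seed=7)


def pearson_oracle(x, y):
    """Textbook sum-formula Pearson, coded independently of the package."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den
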