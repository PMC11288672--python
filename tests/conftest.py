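import numpy as np
import pytest

from lmdr.state_space import EmbeddingMatrix, TimeSeriesTable, build_embedding


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def logistic_series():
    """50-point chaotic logistic-map series (r = 3.8)."""
    x = 0.4
    vals = []
    for _ in range(60):
        x = 3.8 * x * (1 - x)
        vals.append(x)
    vals = np.array(vals[10:])
    return TimeSeriesTable(np.arange(len(vals), dtype=float), vals[:, None], ["x"])


@pytest.fixture
def linear_map():
    """A fixed stable 3x3 map with complex dynamics, used as a known truth."""
    return np.array([[0.6, 0.2, -0.1], [0.1, 0.5, 0.2], [-0.2, 0.1, 0.7]])


def make_linear_embedding(A, m=200, seed=0, noise=0.0):
    """Embedding of one-step transitions of x -> Ax sampled across the space.

    A decaying linear map collapses a single orbit onto its dominant
    eigenspace, so transitions are sampled from many random starting states
    to keep the design full-rank while every pair still satisfies the exact
    linear dynamics.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(m, A.shape[0]))
    Y = X @ A.T
    if noise:
        Y = Y + rng.normal(0, noise, Y.shape)
    return EmbeddingMatrix(
        X=X,
        targets=Y[:, 0],
        column_roles=[f"x{i + 1}" for i in range(A.shape[0])],
        target_variable="x1",
        row_times=np.arange(m, dtype=float),
    ), Y


@pytest.fixture
def two_var_series(rng):
    """Coupled noisy two-variable series for generic embedding tests."""
    m = 80
    x = np.empty(m)
    y = np.empty(m)
    x[0], y[0] = 0.4, 0.3
    for t in range(m - 1):
        x[t + 1] = 3.7 * x[t] * (1 - x[t]) - 0.05 * x[t] * y[t]
        y[t + 1] = 3.6 * y[t] * (1 - y[t]) - 0.05 * x[t] * y[t]
    return TimeSeriesTable(np.arange(m, dtype=float), np.column_stack([x, y]), ["x", "y"])


@pytest.fixture
def small_embedding(two_var_series):
    return build_embedding(two_var_series, target="x", coordinates=["x", "y"], n_lags=0)
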