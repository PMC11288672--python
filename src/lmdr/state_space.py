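"""State-space reconstruction: time-series containers, delay/multivariate
embeddings, anisotropic (local-manifold) distances and neighbour weights.

The central object is the embedding matrix ``X`` (m rows of E-dimensional
reconstructed states) together with one-step-ahead targets.  Distances between
states can be stretched per coordinate by a non-negative E x E locality matrix
``Theta``::

    d_ij(Theta) = || (x_i - x_j) Theta ||_2

and converted to local regression weights

    w_ij(Theta) = exp(-d_ij(Theta) / dbar_i)

where ``dbar_i`` is the mean Euclidean (Theta = I) distance from state i to
the other states.  With ``Theta = theta * I`` this reduces exactly to the
classic S-map weighting ``w_ij = exp(-theta d_ij / dbar_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "TimeSeriesTable",
    "EmbeddingMatrix",
    "LocalityMatrix",
    "DistanceMatrix",
    "WeightMatrix",
    "build_embedding",
    "lmd_distance",
    "euclidean_distance",
    "lmd_weights",
    "smap_weights",
]


@dataclass
class TimeSeriesTable:
    """Equally spaced multivariate time series (wide format).

    Parameters
    ----------
    time : (m_raw,) strictly increasing sample times.
    values : (m_raw, n_var) observations, no missing values.
    names : n_var column labels.
    """

    time: np.ndarray
    values: np.ndarray
    names: list[str]
    spacing_rtol: float = 1e-6

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.time.shape[0]:
            raise ValueError("time and values row counts differ")
        if self.values.shape[1] != len(self.names):
            raise ValueError("names do not match value columns")
        if len(self.time) < 2:
            raise ValueError("need at least two samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        dt = steps.mean()
        if np.any(np.abs(steps - dt) > self.spacing_rtol * max(abs(dt), 1.0)):
            raise ValueError("sampling interval is not constant")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing/non-finite values; impute or drop upstream")

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def dt(self) -> float:
        return float(np.diff(self.time).mean())

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}; have {self.names}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time", self.time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeSeriesTable":
        if "time" not in df.columns:
            raise ValueError("expected a 'time' column (wide format)")
        names = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(float), df[names].to_numpy(float), names)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class EmbeddingMatrix:
    """Reconstructed state vectors with aligned one-step-ahead targets.

    ``X[k]`` is the state at time ``row_times[k]``; ``targets[k]`` is the
    prediction target (the target variable one sample later).
    """

    X: np.ndarray
    targets: np.ndarray
    column_roles: list[str]
    target_variable: str
    row_times: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.targets.shape[0]:
            raise ValueError("targets misaligned with X rows")
        if self.X.shape[1] != len(self.column_roles):
            raise ValueError("column_roles do not match X columns")
        if self.X.shape[1] < 1 or self.X.shape[0] < 1:
            raise ValueError("empty embedding")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def E(self) -> int:
        return self.X.shape[1]


@dataclass
class LocalityMatrix:
    """Non-negative E x E matrix Theta stretching the distance metric.

    ``diagonal_only`` restricts optimization to per-coordinate scaling (the
    default in the benchmark analyses); the identity recovers the Euclidean
    metric.
    """

    theta: np.ndarray
    diagonal_only: bool = True

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.theta.shape[0] != self.theta.shape[1]:
            raise ValueError("theta must be square")
        if np.any(self.theta < 0):
            raise ValueError("theta entries must be non-negative")
        if self.diagonal_only and np.any(self.theta != np.diag(np.diag(self.theta))):
            raise ValueError("off-diagonal entries must be 0 in diagonal_only mode")

    @property
    def E(self) -> int:
        return self.theta.shape[0]

    @classmethod
    def identity(cls, E: int, diagonal_only: bool = True) -> "LocalityMatrix":
        return cls(np.eye(E), diagonal_only=diagonal_only)

    @classmethod
    def scalar(cls, theta: float, E: int) -> "LocalityMatrix":
        return cls(float(theta) * np.eye(E))


@dataclass
class DistanceMatrix:
    """m x m pairwise distances plus the row means used as weight normalizers.

    ``row_means`` holds the Euclidean (Theta = I) row means for the LMD metric
    and the metric's own row means for the baseline metrics; the diagonal
    self-distance is excluded from the mean.
    """

    d: np.ndarray
    metric_tag: str
    row_means: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.row_means = np.asarray(self.row_means, dtype=float)
        if self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if self.row_means.shape[0] != self.d.shape[0]:
            raise ValueError("row_means misaligned")

    @property
    def m(self) -> int:
        return self.d.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.d).to_csv(path, index=False)


@dataclass
class WeightMatrix:
    """m x m local weights in (0, 1]; w_ii = 1 (zero self-distance)."""

    w: np.ndarray
    theta_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite weights")

    @property
    def m(self) -> int:
        return self.w.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.w).to_csv(path, index=False)


def build_embedding(
    series: TimeSeriesTable,
    target: str,
    coordinates: list[str] | None = None,
    n_lags: int = 0,
) -> EmbeddingMatrix:
    """Build a multivariate embedding with optional lags of the target.

    Columns are the listed coordinate variables at time t followed by the
    target at t-1, ..., t-n_lags; the prediction target is the target variable
    at t+1.  Rows whose lags or target fall outside the series are dropped.
    """
    if coordinates is None:
        coordinates = list(series.names)
    if target not in coordinates:
        raise ValueError(f"target {target!r} must be among coordinates {coordinates}")
    if n_lags < 0:
        raise ValueError("n_lags must be >= 0")
    m_raw = len(series)
    if n_lags + 2 >= m_raw:
        raise ValueError(
            f"series of length {m_raw} too short for n_lags={n_lags} "
            "(need n_lags + 2 < length)"
        )
    cols = [series.column(c) for c in coordinates]
    y = series.column(target)

    t_idx = np.arange(n_lags, m_raw - 1)  # rows needing t-n_lags .. t+1
    blocks = [c[t_idx] for c in cols]
    roles = list(coordinates)
    for lag in range(1, n_lags + 1):
        blocks.append(y[t_idx - lag])
        roles.append(f"{target}(t-{lag})")
    X = np.column_stack(blocks)
    zero_var = np.ptp(X, axis=0) == 0
    if np.any(zero_var):
        warnings.warn(
            f"zero-variance embedding column(s): {[roles[j] for j in np.flatnonzero(zero_var)]}",
            stacklevel=2,
        )
    return EmbeddingMatrix(
        X=X,
        targets=y[t_idx + 1],
        column_roles=roles,
        target_variable=target,
        row_times=series.time[t_idx],
    )


def _row_means_offdiag(d: np.ndarray) -> np.ndarray:
    """Mean of each row excluding the diagonal self-distance."""
    m = d.shape[0]
    if m < 2:
        raise ValueError("need at least two states")
    return (d.sum(axis=1) - np.diag(d)) / (m - 1)


def euclidean_distance(X: EmbeddingMatrix) -> DistanceMatrix:
    """Ordinary Euclidean distance matrix (Theta = I) with its row means."""
    d = cdist(X.X, X.X)
    return DistanceMatrix(d=d, metric_tag="euclidean", row_means=_row_means_offdiag(d))


def lmd_distance(X: EmbeddingMatrix, theta: LocalityMatrix) -> DistanceMatrix:
    """Locally weighted distance d_ij = ||(x_i - x_j) Theta||_2.

    ``row_means`` are always the Euclidean (Theta = I) row means, so the
    locality matrix only enters the weight numerator.
    """
    if theta.E != X.E:
        raise ValueError(f"theta is {theta.E}x{theta.E} but embedding has E={X.E}")
    XT = X.X @ theta.theta
    d = cdist(XT, XT)
    d_euc = cdist(X.X, X.X)
    return DistanceMatrix(d=d, metric_tag="lmd", row_means=_row_means_offdiag(d_euc))


def lmd_weights(dist: DistanceMatrix, normalizer: str = "euclidean") -> WeightMatrix:
    """LMD weights w_ij = exp(-d_ij(Theta) / dbar_i(I)).

    ``normalizer="euclidean"`` (default) uses the Euclidean row means carried
    by the distance matrix; ``"own"`` renormalizes by the Theta-weighted
    distance's own row means (alternative reading of the definition).
    """
    if normalizer == "euclidean":
        dbar = dist.row_means
    elif normalizer == "own":
        dbar = _row_means_offdiag(dist.d)
    else:
        raise ValueError("normalizer must be 'euclidean' or 'own'")
    if np.any(dbar <= 0):
        raise ValueError("degenerate embedding: some state equals all others (zero row mean)")
    return WeightMatrix(w=np.exp(-dist.d / dbar[:, None]))


def smap_weights(dist: DistanceMatrix, theta_scalar: float) -> WeightMatrix:
    """Uniform-localization weights w_ij = exp(-theta d_ij / dbar_i).

    ``dbar_i`` is the row mean carried by ``dist`` (each baseline metric uses
    its own row means).  ``theta_scalar = 0`` gives the global linear map.
    """
    if theta_scalar < 0:
        raise ValueError("theta_scalar must be >= 0")
    dbar = dist.row_means
    if np.any(dbar <= 0):
        raise ValueError("degenerate embedding: zero distance row mean")
    return WeightMatrix(
        w=np.exp(-theta_scalar * dist.d / dbar[:, None]),
        theta_info={"theta_scalar": float(theta_scalar), "metric": dist.metric_tag},
    )
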