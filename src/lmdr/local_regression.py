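"""Sequential locally weighted linear fits with ridge regularization.

For each embedding row k a weighted linear model

    xhat(t_k + 1) = c_k0 + sum_j c_kj x_j(t_k)

is fitted over all other rows with weights w_kj, either by the ridge closed
form

    c_k = (X^T W_k X + n lambda I)^{-1} X^T W_k x'

(intercept column appended and excluded from the penalty) or, for the
unregularized S-map route, by solving the weighted system b = A c
(b = {w_kj x'_j}, A = {w_kj x_j}) with an SVD pseudo-inverse.  Row k itself is
always left out of its own fit, so predictions are leave-one-out and the
coefficient rows approximate the local Jacobian elements
d x_target(t+1) / d x_j(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .state_space import EmbeddingMatrix, LocalityMatrix, WeightMatrix, lmd_distance, lmd_weights

__all__ = [
    "RidgeConfig",
    "LocalFitSeries",
    "SkillReport",
    "fit_local_model",
    "sequential_fit",
    "loocv_rmse",
    "jacobian_series",
]

_SVD_RCOND = 1e-10  # relative singular-value cutoff for the pseudo-inverse


@dataclass(frozen=True)
class RidgeConfig:
    """Regularization settings for the local linear fits.

    lambda_ : ridge penalty; the objective is
        (1/n) (x' - Xc)^T W_k (x' - Xc) + lambda ||c||^2.
    solver : "ridge_closed_form" (analytic ridge solution) or "svd"
        (pseudo-inverse of the weighted system; ignores lambda_).
    penalize_intercept : include the intercept in ||c||^2 (off by default;
        penalizing it would break translation invariance).
    """

    lambda_: float = 0.0
    solver: str = "ridge_closed_form"
    penalize_intercept: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.solver not in ("ridge_closed_form", "svd"):
            raise ValueError("solver must be 'ridge_closed_form' or 'svd'")


@dataclass
class SkillReport:
    """Out-of-sample forecast skill (leave-one-out predictions only)."""

    rmse: float
    pearson_rho: float
    n_predictions: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "pearson_rho": self.pearson_rho,
            "n_predictions": self.n_predictions,
        }


@dataclass
class LocalFitSeries:
    """Per-time-step local linear models for one prediction target.

    ``coefficients[k]`` approximates the Jacobian row
    d x_target(t_k + 1) / d x_j(t_k) over the embedding columns.
    """

    intercepts: np.ndarray
    coefficients: np.ndarray
    predictions: np.ndarray
    target_variable: str
    column_roles: list[str]
    row_times: np.ndarray
    method: str = "LMDr"
    meta: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.coefficients.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coefficients, columns=self.column_roles)
        df.insert(0, "intercept", self.intercepts)
        df.insert(0, "prediction", self.predictions)
        df.insert(0, "time", self.row_times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, np.ones(X.shape[0])])


def fit_local_model(
    X: EmbeddingMatrix | np.ndarray,
    target: np.ndarray,
    weights_row: np.ndarray,
    config: RidgeConfig = RidgeConfig(),
    exclude: set[int] | frozenset[int] = frozenset(),
) -> tuple[float, np.ndarray]:
    """Fit one locally weighted linear model; returns (intercept, coefficients).

    Rows in ``exclude`` get zero weight.  With the ridge solver the penalty is
    n*lambda on the squared coefficient norm (n = rows entering the fit); with
    the SVD solver the weighted system is solved by pseudo-inverse.
    """
    Xm = X.X if isinstance(X, EmbeddingMatrix) else np.asarray(X, float)
    y = np.asarray(target, float)
    w = np.asarray(weights_row, float).copy()
    if np.any(w < 0):
        raise ValueError("negative weights")
    for k in exclude:
        w[k] = 0.0
    active = w > 0
    n = int(active.sum())
    E = Xm.shape[1]
    if n < E + 2:
        raise ValueError(f"only {n} rows with positive weight; need at least E+2={E + 2}")
    A = _design(Xm[active])
    yw = y[active]
    ww = w[active]
    if config.solver == "svd":
        # Eq-style weighted system: scale BOTH sides by w, then pinv.
        coef = np.linalg.pinv(ww[:, None] * A, rcond=_SVD_RCOND) @ (ww * yw)
    else:
        G = A.T @ (ww[:, None] * A)
        rhs = A.T @ (ww * yw)
        pen = np.eye(E + 1)
        if not config.penalize_intercept:
            pen[E, E] = 0.0
        try:
            coef = np.linalg.solve(G + n * config.lambda_ * pen, rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular weighted normal matrix; raise lambda_ (ridge) to regularize"
            ) from err
    return float(coef[E]), coef[:E]


def _batched_fits(
    Xm: np.ndarray,
    y: np.ndarray,
    W: np.ndarray,
    config: RidgeConfig,
) -> np.ndarray:
    """Solve all m local fits at once; W has excluded entries already zeroed.

    Returns (m, E+1) array of [coefficients..., intercept].
    """
    m, E = Xm.shape
    A = _design(Xm)
    if config.solver == "svd":
        out = np.empty((m, E + 1))
        for k in range(m):
            wk = W[k]
            out[k] = np.linalg.pinv(wk[:, None] * A, rcond=_SVD_RCOND) @ (wk * y)
        return out
    G = np.einsum("kj,ji,jl->kil", W, A, A, optimize=True)
    rhs = (W * y) @ A
    n = (W > 0).sum(axis=1)
    pen = np.eye(E + 1)
    if not config.penalize_intercept:
        pen[E, E] = 0.0
    G = G + (n * config.lambda_)[:, None, None] * pen
    try:
        return np.linalg.solve(G, rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        # fall back row-wise so the failing row index can be reported
        out = np.empty((m, E + 1))
        for k in range(m):
            try:
                out[k] = np.linalg.solve(G[k], rhs[k])
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular normal matrix at row k={k}; raise lambda_"
                ) from err
        return out


def sequential_fit(
    X: EmbeddingMatrix,
    theta: LocalityMatrix | None = None,
    config: RidgeConfig = RidgeConfig(),
    weights: WeightMatrix | None = None,
    exclusion_radius: int = 0,
    method: str = "LMDr",
) -> LocalFitSeries:
    """Fit the full sequence of local models, one per embedding row.

    Weights come either from ``weights`` (baseline S-map variants) or from the
    LMD metric under ``theta``.  Each row k is excluded from its own fit
    (leave-one-out; ``exclusion_radius`` additionally drops temporal
    neighbours within that many rows), then its target is predicted.
    """
    if weights is None:
        if theta is None:
            theta = LocalityMatrix.identity(X.E)
        weights = lmd_weights(lmd_distance(X, theta))
    W = weights.w.copy()
    m = X.m
    if W.shape != (m, m):
        raise ValueError("weight matrix does not match embedding rows")
    idx = np.arange(m)
    mask = np.abs(idx[:, None] - idx[None, :]) <= exclusion_radius
    W[mask] = 0.0
    coefs = _batched_fits(X.X, X.targets, W, config)
    A = _design(X.X)
    preds = np.einsum("ki,ki->k", A, coefs)
    return LocalFitSeries(
        intercepts=coefs[:, -1],
        coefficients=coefs[:, :-1],
        predictions=preds,
        target_variable=X.target_variable,
        column_roles=list(X.column_roles),
        row_times=X.row_times,
        method=method,
        meta={
            "lambda": config.lambda_,
            "solver": config.solver,
            "exclusion_radius": exclusion_radius,
        },
    )


def loocv_rmse(fits: LocalFitSeries, targets: np.ndarray) -> SkillReport:
    """Leave-one-out RMSE and Pearson rho; the RMSE is the annealing energy."""
    y = np.asarray(targets, float)
    p = fits.predictions
    ok = np.isfinite(p) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 valid predictions")
    resid = p[ok] - y[ok]
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(p[ok]) == 0 or np.std(y[ok]) == 0:
        rho = float("nan")
    else:
        rho = float(pearsonr(p[ok], y[ok])[0])
    return SkillReport(rmse=rmse, pearson_rho=rho, n_predictions=int(ok.sum()))


def jacobian_series(fits: list[LocalFitSeries]) -> np.ndarray:
    """Stack per-variable coefficient rows into a Jacobian time series.

    ``fits`` holds one LocalFitSeries per system variable, all on the same
    embedding rows whose first columns are the system variables in order.
    Returns (m, n_sys, n_sys); entry [k, i, j] estimates
    d x_i(t_k + 1) / d x_j(t_k).  Lag-column coefficients (if any) are not
    part of the returned matrices — they are lag effects, not inter-variable
    Jacobians.
    """
    n_sys = len(fits)
    if n_sys < 1:
        raise ValueError("need at least one fit series")
    m = fits[0].m
    times = fits[0].row_times
    for f in fits:
        if f.m != m or not np.array_equal(f.row_times, times):
            raise ValueError("fit series are not aligned on the same embedding rows")
    J = np.empty((m, n_sys, n_sys))
    for i, f in enumerate(fits):
        J[:, i, :] = f.coefficients[:, :n_sys]
    return J


def jacobians_to_frame(J: np.ndarray, times: np.ndarray) -> pd.DataFrame:
    """Long-format (time, i, j, value) table of a Jacobian sequence."""
    m, n, _ = J.shape
    t, i, j = np.meshgrid(np.arange(m), np.arange(n), np.arange(n), indexing="ij")
    return pd.DataFrame(
        {
            "time": np.asarray(times)[t.ravel()],
            "i": i.ravel(),
            "j": j.ravel(),
            "value": J.ravel(),
        }
    )
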