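"""Alternative distance metrics and the uniform-localization S-map baselines.

Three baseline metrics share the scalar-theta weighting of the classic S-map:

* Euclidean — the original S-map distance;
* multi-view — the mean of Euclidean distances measured in the best
  low-dimensional coordinate-subset "views", ranked by simplex-projection
  forecast skill (MDR S-map);
* geodesic — shortest-path distance on a symmetrized k-nearest-neighbour
  graph of the attractor (GD S-map).

``smap_baseline_fit`` grid-searches the scalar locality parameter theta and
returns the leave-one-out-RMSE-minimizing fit series.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil, sqrt

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist
from sklearn.neighbors import kneighbors_graph

from .local_regression import LocalFitSeries, RidgeConfig, SkillReport, loocv_rmse, sequential_fit
from .state_space import (
    DistanceMatrix,
    EmbeddingMatrix,
    _row_means_offdiag,
    euclidean_distance,
    smap_weights,
)

__all__ = [
    "ViewEnsemble",
    "GeodesicConfig",
    "multiview_distance",
    "geodesic_distance",
    "smap_baseline_fit",
    "metric_distance",
]

DEFAULT_THETA_GRID = np.round(np.arange(0, 20.0001, 0.1), 10)


@dataclass
class ViewEnsemble:
    """Coordinate-subset views for the multi-view distance.

    views : list of column-index tuples; by default all non-empty subsets of
        the embedding columns up to ``max_views``, ordered by size then
        lexicographically.
    n_top : number of best-forecasting views averaged
        (default ceil(sqrt(n_views)), the usual multiview-embedding choice).
    """

    views: list[tuple[int, ...]]
    n_top: int | None = None
    view_skills: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.views or any(len(v) == 0 for v in self.views):
            raise ValueError("every view must be a non-empty column subset")
        if self.n_top is not None and not (1 <= self.n_top <= len(self.views)):
            raise ValueError("n_top out of range")

    @classmethod
    def enumerate(cls, E: int, max_views: int = 50, n_top: int | None = None) -> "ViewEnsemble":
        views: list[tuple[int, ...]] = []
        for size in range(1, E + 1):
            for combo in combinations(range(E), size):
                views.append(combo)
                if len(views) >= max_views:
                    return cls(views=views, n_top=n_top)
        return cls(views=views, n_top=n_top)


@dataclass
class GeodesicConfig:
    """Neighbourhood graph settings for the geodesic metric."""

    k_neighbors: int | None = None  # None -> min(10, m-1)
    fallback: str = "bridge"  # connect components via their shortest inter-component edge

    def __post_init__(self) -> None:
        if self.k_neighbors is not None and self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        if self.fallback not in ("bridge", "error"):
            raise ValueError("fallback must be 'bridge' or 'error'")


def _simplex_loo_rmse(Xv: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out simplex-projection RMSE within one view's coordinates.

    Each point is forecast from its E_v + 1 nearest neighbours with
    exponential weights exp(-d/d_min) (uniform when d_min = 0).
    """
    m, Ev = Xv.shape
    n_nb = min(Ev + 1, m - 1)
    d = cdist(Xv, Xv)
    np.fill_diagonal(d, np.inf)
    preds = np.empty(m)
    order = np.argsort(d, axis=1, kind="stable")[:, :n_nb]
    for i in range(m):
        nb = order[i]
        dn = d[i, nb]
        dmin = dn[0]
        w = np.ones(n_nb) if dmin == 0 else np.exp(-dn / dmin)
        preds[i] = np.sum(w * y[nb]) / np.sum(w)
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def multiview_distance(X: EmbeddingMatrix, ensemble: ViewEnsemble | None = None) -> DistanceMatrix:
    """Average Euclidean distance over the top forecasting views.

    Views are scored by leave-one-out simplex-projection RMSE against the
    embedding's one-step-ahead targets; the ``n_top`` best are averaged with
    equal weight (per-view distances are not rescaled by view dimension).
    """
    if ensemble is None:
        ensemble = ViewEnsemble.enumerate(X.E)
    for v in ensemble.views:
        if any(j < 0 or j >= X.E for j in v):
            raise ValueError(f"view {v} has out-of-range columns for E={X.E}")
    skills = np.array([_simplex_loo_rmse(X.X[:, list(v)], X.targets) for v in ensemble.views])
    if not np.any(np.isfinite(skills)):
        raise ValueError("all views degenerate (no finite forecast skill)")
    ensemble.view_skills = skills
    n_top = ensemble.n_top if ensemble.n_top is not None else ceil(sqrt(len(ensemble.views)))
    top = np.argsort(skills, kind="stable")[:n_top]
    d = np.zeros((X.m, X.m))
    for t in top:
        cols = list(ensemble.views[t])
        d += cdist(X.X[:, cols], X.X[:, cols])
    d /= len(top)
    return DistanceMatrix(d=d, metric_tag="multiview", row_means=_row_means_offdiag(d))


def geodesic_distance(X: EmbeddingMatrix, config: GeodesicConfig = GeodesicConfig()) -> DistanceMatrix:
    """Shortest-path distance on the symmetrized k-NN graph of the attractor.

    Disconnected components are bridged by their single shortest
    inter-component Euclidean edge (default fallback), so the result is
    finite and symmetric.
    """
    m = X.m
    k = config.k_neighbors if config.k_neighbors is not None else min(10, m - 1)
    if m <= k:
        raise ValueError(f"m={m} too small for k_neighbors={k}")
    G = kneighbors_graph(X.X, n_neighbors=k, mode="distance")
    G = G.maximum(G.T)  # symmetrize: keep an edge if either endpoint lists it
    full = None
    while True:
        n_comp, labels = connected_components(G, directed=False)
        if n_comp == 1:
            break
        if config.fallback == "error":
            raise ValueError(f"k-NN graph has {n_comp} components")
        if full is None:
            full = cdist(X.X, X.X)
        # bridge the two closest components with one edge
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if labels[i] != labels[j] and full[i, j] < best[0]:
                    best = (full[i, j], i, j)
        _, bi, bj = best
        G = G.tolil()
        G[bi, bj] = G[bj, bi] = full[bi, bj]
        G = csr_matrix(G)
    d = shortest_path(csr_matrix(G), method="D", directed=False)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(d=d, metric_tag="geodesic", row_means=_row_means_offdiag(d))


def metric_distance(
    X: EmbeddingMatrix,
    metric: str,
    ensemble: ViewEnsemble | None = None,
    geodesic_config: GeodesicConfig | None = None,
) -> DistanceMatrix:
    """Dispatch to the named baseline metric."""
    if metric == "euclidean":
        return euclidean_distance(X)
    if metric == "multiview":
        return multiview_distance(X, ensemble)
    if metric == "geodesic":
        return geodesic_distance(X, geodesic_config or GeodesicConfig())
    raise ValueError(f"unknown metric {metric!r}")


def smap_baseline_fit(
    X: EmbeddingMatrix,
    metric: str = "euclidean",
    theta_grid: np.ndarray | None = None,
    config: RidgeConfig = RidgeConfig(lambda_=0.0, solver="svd"),
    ensemble: ViewEnsemble | None = None,
    geodesic_config: GeodesicConfig | None = None,
) -> tuple[float, LocalFitSeries, SkillReport]:
    """Grid-search the scalar locality parameter for one baseline metric.

    Returns (best_theta, fits at best theta, skill).  Ties in leave-one-out
    RMSE are broken toward the smallest theta.  The noise-grid benchmark uses
    the unregularized SVD route; the empirical pipeline passes a ridge config.
    """
    if theta_grid is None:
        theta_grid = DEFAULT_THETA_GRID
    theta_grid = np.asarray(theta_grid, float)
    if theta_grid.size == 0:
        raise ValueError("empty theta grid")
    if np.any(theta_grid < 0):
        raise ValueError("theta must be >= 0")
    dist = metric_distance(X, metric, ensemble=ensemble, geodesic_config=geodesic_config)
    tag = {"euclidean": "euclid_smap", "multiview": "mdr_smap", "geodesic": "gd_smap"}[metric]
    best: tuple[float, LocalFitSeries, SkillReport] | None = None
    n_failed = 0
    for th in theta_grid:
        try:
            fits = sequential_fit(
                X, weights=smap_weights(dist, float(th)), config=config, method=tag
            )
            skill = loocv_rmse(fits, X.targets)
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        if best is None or skill.rmse < best[2].rmse:
            fits.meta["theta_scalar"] = float(th)
            fits.meta["metric"] = metric
            best = (float(th), fits, skill)
    if best is None:
        raise RuntimeError(f"all {n_failed} grid fits failed for metric {metric!r}")
    return best
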