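"""Temperature-parallel simulated annealing over (lambda, Theta).

Instead of a single cooling schedule, k Metropolis chains run at fixed
temperatures spanning [T_min, T_max]; after every round of mutations,
adjacent-temperature chains may exchange their full (lambda, Theta, energy)
state with probability

    P(T_i, T_j) = 1                              if dT * dE < 0
                  exp(-dT * dE / (T_i * T_j))    otherwise.

The energy is the leave-one-out forecast RMSE of the sequential local
regression under the candidate (lambda, Theta).  Proposals perturb both
lambda and Theta with folded-Gaussian steps: lambda_new = |lambda_old + d|,
Theta_new = |Theta_old + D| with d, D_ij ~ N(0, sigma_delta); in
diagonal-only mode the off-diagonal entries of Theta stay pinned at zero.

Each chain consumes an independent random stream spawned from the master
seed, and exchanges use a dedicated stream, so results are bit-reproducible
regardless of how chains are scheduled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .local_regression import LocalFitSeries, RidgeConfig, SkillReport, loocv_rmse, sequential_fit
from .state_space import EmbeddingMatrix, LocalityMatrix

__all__ = [
    "TPSAConfig",
    "AnnealingChain",
    "TPSAResult",
    "mutate",
    "metropolis_accept",
    "exchange_step",
    "find_best_theta",
]


@dataclass(frozen=True)
class TPSAConfig:
    """Annealing schedule.  Temperatures default to a geometric ladder over
    [1e-4 * E0, 1.0 * E0] where E0 is the initial (Theta=I, lambda=0) RMSE,
    which scales the schedule to the data."""

    n_chains: int = 8
    t_min: float | None = None   # None -> 1e-4 * initial energy
    t_max: float | None = None   # None -> 1.0 * initial energy
    sigma_delta: float = 0.05
    sigma_lambda: float | None = None  # None -> sigma_delta / 10
    n_mutations_per_round: int = 100
    n_exchange_rounds: int = 100
    master_seed: int = 0
    diagonal_only: bool = True
    optimize_lambda: bool = True  # False: keep lambda fixed at the ridge config's value

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.sigma_delta <= 0:
            raise ValueError("sigma_delta must be > 0")
        if self.n_mutations_per_round < 1 or self.n_exchange_rounds < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.t_min is not None and self.t_max is not None and not (self.t_min <= self.t_max):
            raise ValueError("need t_min <= t_max")


@dataclass
class AnnealingChain:
    """One fixed-temperature Metropolis chain over (lambda, Theta)."""

    temperature: float
    current_lambda: float
    current_theta: LocalityMatrix
    current_energy: float
    best_lambda: float
    best_theta: LocalityMatrix
    best_energy: float
    rng: np.random.Generator

    def record_if_best(self) -> None:
        if self.current_energy < self.best_energy:
            self.best_energy = self.current_energy
            self.best_lambda = self.current_lambda
            self.best_theta = self.current_theta


@dataclass
class TPSAResult:
    best_theta: LocalityMatrix
    best_lambda: float
    skill: SkillReport
    fits: LocalFitSeries
    trace: pd.DataFrame
    meta: dict = field(default_factory=dict)


def mutate(
    lambda_old: float,
    theta_old: LocalityMatrix,
    sigma_delta: float,
    rng: np.random.Generator,
    sigma_lambda: float | None = None,
) -> tuple[float, LocalityMatrix]:
    """Folded-Gaussian proposal: reflection at 0 keeps parameters non-negative.

    The ridge penalty moves on a much finer natural scale than the locality
    entries, so its perturbation uses ``sigma_lambda`` (default
    ``sigma_delta / 10``); Theta entries use ``sigma_delta``.
    """
    if sigma_delta <= 0:
        raise ValueError("sigma_delta must be > 0")
    if sigma_lambda is None:
        sigma_lambda = sigma_delta / 10.0
    lam = abs(lambda_old + rng.normal(0.0, sigma_lambda))
    E = theta_old.E
    th = theta_old.theta.copy()
    if theta_old.diagonal_only:
        idx = np.diag_indices(E)
        th[idx] = np.abs(th[idx] + rng.normal(0.0, sigma_delta, size=E))
    else:
        th = np.abs(th + rng.normal(0.0, sigma_delta, size=(E, E)))
    return lam, LocalityMatrix(th, diagonal_only=theta_old.diagonal_only)


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept downhill moves always; uphill with probability exp(-dE/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e < 0:
        return True
    return bool(rng.random() < np.exp(-delta_e / temperature))


def exchange_step(
    chains: list[AnnealingChain],
    rng: np.random.Generator,
    offset: int = 0,
) -> list[AnnealingChain]:
    """Attempt swaps between adjacent-temperature chains (in place).

    ``offset`` (0 or 1) selects which adjacent pairs are considered so that
    alternating rounds cover both pairings.  The swapped state is the full
    (lambda, Theta, energy) triple; temperatures stay attached to chains.
    """
    k = len(chains)
    if k < 2:
        return chains
    for lo in range(offset % 2, k - 1, 2):
        a, b = chains[lo], chains[lo + 1]
        dT = a.temperature - b.temperature
        dE = a.current_energy - b.current_energy
        x = dT * dE
        if x < 0:
            accept = True
        else:
            accept = rng.random() < np.exp(-x / (a.temperature * b.temperature))
        if accept:
            a.current_lambda, b.current_lambda = b.current_lambda, a.current_lambda
            a.current_theta, b.current_theta = b.current_theta, a.current_theta
            a.current_energy, b.current_energy = b.current_energy, a.current_energy
            a.record_if_best()
            b.record_if_best()
    return chains


def _energy_factory(X: EmbeddingMatrix, target: np.ndarray, ridge: RidgeConfig):
    """LOO-RMSE energy with memoization ((lambda, Theta) -> RMSE).

    The Euclidean row means (the weight normalizer, independent of Theta) are
    precomputed once; each candidate only recomputes the Theta-weighted
    distances.
    """
    from scipy.spatial.distance import cdist

    from .state_space import _row_means_offdiag

    d_euc = cdist(X.X, X.X)
    dbar = _row_means_offdiag(d_euc)[:, None]
    cache: dict[tuple, float] = {}
    y = np.asarray(target, float)
    m, E = X.X.shape
    A = np.column_stack([X.X, np.ones(m)])
    pen = np.eye(E + 1)
    if not ridge.penalize_intercept:
        pen[E, E] = 0.0
    # Gram stacks via one GEMM: B holds the upper-triangle products A_i A_l,
    # so X^T W_k X for every k is W @ B reshaped into symmetric matrices
    iu = np.triu_indices(E + 1)
    B = A[:, iu[0]] * A[:, iu[1]]
    C = y[:, None] * A

    def energy(lam: float, theta: LocalityMatrix) -> float:
        # inlined leave-one-out fit paths (hot loop); results agree with
        # sequential_fit to solver precision
        key = (lam, theta.theta.tobytes())
        if key in cache:
            return cache[key]
        XT = X.X @ theta.theta
        W = np.exp(-cdist(XT, XT) / dbar)
        np.fill_diagonal(W, 0.0)
        G = np.empty((m, E + 1, E + 1))
        if ridge.solver == "svd":
            # w-scaled least squares (the b = Ac route): normal equations of
            # the w^2-weighted problem with a tiny trace-scaled floor playing
            # the pseudo-inverse cutoff's stabilizing role (agrees with the
            # exact route to ~1e-4 relative in energy)
            W2 = W * W
            WB = W2 @ B
            G[:, iu[0], iu[1]] = WB
            G[:, iu[1], iu[0]] = WB
            tr = np.einsum("kii->k", G) / (E + 1)
            G += (1e-8 * tr)[:, None, None] * np.eye(E + 1)
            rhs = W2 @ C
        else:
            WB = W @ B
            G[:, iu[0], iu[1]] = WB
            G[:, iu[1], iu[0]] = WB
            G += ((m - 1) * lam) * pen
            rhs = W @ C
        coefs = np.linalg.solve(G, rhs[:, :, None])[:, :, 0]
        preds = np.einsum("ki,ki->k", A, coefs)
        e = float(np.sqrt(np.mean((preds - y) ** 2)))
        cache[key] = e
        return e

    return energy


def find_best_theta(
    X: EmbeddingMatrix,
    target: np.ndarray | None = None,
    config: TPSAConfig = TPSAConfig(),
    ridge: RidgeConfig = RidgeConfig(lambda_=0.0, solver="ridge_closed_form"),
) -> TPSAResult:
    """Optimize (lambda, Theta) by TPSA, minimizing leave-one-out RMSE.

    Every chain starts from lambda = 0, Theta = I.  Each round runs
    ``n_mutations_per_round`` Metropolis steps per chain followed by one
    exchange attempt between adjacent temperatures; the global best-so-far
    across chains is returned together with a per-chain energy trace.
    """
    if target is None:
        target = X.targets
    energy = _energy_factory(X, target, ridge)

    theta0 = LocalityMatrix.identity(X.E, diagonal_only=config.diagonal_only)
    lam0 = 0.0 if config.optimize_lambda else ridge.lambda_
    sig_lam = config.sigma_lambda if config.optimize_lambda else 0.0
    e0 = energy(lam0, theta0)
    scale = e0 if e0 > 0 else 1.0
    t_min = config.t_min if config.t_min is not None else 1e-4 * scale
    t_max = config.t_max if config.t_max is not None else 1.0 * scale
    if config.n_chains == 1:
        temps = np.array([t_min])
    else:
        temps = np.geomspace(t_min, t_max, config.n_chains)

    ss = np.random.SeedSequence(config.master_seed)
    streams = ss.spawn(config.n_chains + 1)
    exch_rng = np.random.default_rng(streams[-1])
    chains = [
        AnnealingChain(
            temperature=float(T),
            current_lambda=lam0,
            current_theta=theta0,
            current_energy=e0,
            best_lambda=lam0,
            best_theta=theta0,
            best_energy=e0,
            rng=np.random.default_rng(streams[i]),
        )
        for i, T in enumerate(temps)
    ]

    trace_rows = []
    for rnd in range(config.n_exchange_rounds):
        for ci, ch in enumerate(chains):
            for _ in range(config.n_mutations_per_round):
                lam_new, th_new = mutate(
                    ch.current_lambda,
                    ch.current_theta,
                    config.sigma_delta,
                    ch.rng,
                    sigma_lambda=sig_lam,
                )
                try:
                    e_new = energy(lam_new, th_new)
                except (np.linalg.LinAlgError, ValueError) as err:
                    raise RuntimeError(
                        f"energy evaluation failed (chain {ci}, round {rnd}): {err}"
                    ) from err
                if metropolis_accept(e_new - ch.current_energy, ch.temperature, ch.rng):
                    ch.current_lambda = lam_new
                    ch.current_theta = th_new
                    ch.current_energy = e_new
                    ch.record_if_best()
        exchange_step(chains, exch_rng, offset=rnd)
        for ci, ch in enumerate(chains):
            trace_rows.append(
                {
                    "round": rnd,
                    "chain": ci,
                    "temperature": ch.temperature,
                    "current_energy": ch.current_energy,
                    "best_energy": ch.best_energy,
                }
            )

    best = min(chains, key=lambda c: c.best_energy)
    cfg_best = RidgeConfig(
        lambda_=best.best_lambda, solver=ridge.solver, penalize_intercept=ridge.penalize_intercept
    )
    fits = sequential_fit(X, theta=best.best_theta, config=cfg_best, method="LMDr")
    skill = loocv_rmse(fits, target)
    trace = pd.DataFrame(trace_rows)
    return TPSAResult(
        best_theta=best.best_theta,
        best_lambda=best.best_lambda,
        skill=skill,
        fits=fits,
        trace=trace,
        meta={
            "n_chains": config.n_chains,
            "t_min": float(t_min),
            "t_max": float(t_max),
            "sigma_delta": config.sigma_delta,
            "n_mutations_per_round": config.n_mutations_per_round,
            "n_exchange_rounds": config.n_exchange_rounds,
            "master_seed": config.master_seed,
            "diagonal_only": config.diagonal_only,
            "initial_energy": e0,
        },
    )
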