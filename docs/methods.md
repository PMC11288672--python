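# Methods

## The estimation problem

Given an equally sampled multivariate time series, the package reconstructs
a state space whose rows are state vectors `x_k ∈ R^E` (system variables
and/or lags of a prediction target) and fits, for every time index `k`, a
locally weighted linear model of the one-step map,

    x̂(t_k + 1) = c_k0 + Σ_j c_kj x_j(t_k).

The coefficient rows `c_k` approximate the Jacobian elements of the
underlying dynamics — ecology's time-varying per-capita interaction
strengths — and the fitted models double as one-step forecasts. This is the
S-map scheme; the package's contribution is the *local manifold distance*
that decides which states count as neighbours.

## Distances and weights

The classic S-map weights every state by
`w_kj = exp(-θ d_kj / d̄_k)` with a single scalar locality parameter θ and
Euclidean distances `d_kj`. When the state dependence of the dynamics
differs between coordinates (e.g. a functional response saturating in prey
density but not in predator density), uniform localization mis-ranks
neighbours. The local manifold distance replaces θ with a non-negative
E × E locality matrix Θ,

    d_kj(Θ) = ‖(x_k − x_j) Θ‖₂,
    w_kj(Θ) = exp(−d_kj(Θ) / d̄_k(I)),

where `d̄_k(I)` is the mean Euclidean distance from state k to the others
(diagonal excluded; keeping the normalizer at Θ = I confines Θ's effect to
the numerator — the alternative normalization by the Θ-weighted row means is
available as `lmd_weights(..., normalizer="own")`). With Θ = θ·I this
reduces exactly to the classic weighting, which the tests assert to 1e−12.
In all shipped analyses Θ is diagonal (per-coordinate stretching); the full
matrix is supported via `diagonal_only=False`.

Two published uniform-localization variants are provided as baselines with
the same scalar-θ weighting: the multi-view distance (mean Euclidean
distance over the best-forecasting coordinate-subset "views", views scored
by leave-one-out simplex projection, top `ceil(sqrt(n_views))` kept,
enumeration capped at 50 subsets ordered by size then lexicographically) and
the geodesic distance (shortest paths on the symmetrized k-nearest-neighbour
graph, k = min(10, m−1); disconnected components are bridged by their single
shortest inter-component edge). Their baselines grid-search θ over 0..20 by
0.1, ties to the smaller θ.

## Local fits

Each row's model is fitted over all other rows (row k is always excluded
from its own fit — leave-one-out; a temporal exclusion radius is available,
default 0). Two solvers:

* **ridge closed form** — minimizes
  `(1/n) (x' − Xc)ᵀ W_k (x' − Xc) + λ‖c‖²` via
  `c = (XᵀW_kX + nλI)⁻¹ XᵀW_k x'`, with a constant column appended for the
  intercept and excluded from the penalty (penalizing it would break
  translation invariance); `n` is the number of rows entering the fit.
* **svd** — solves the w-scaled system `b = Ac` (`b = {w_kj x'_j}`,
  `A = {w_kj x_j}`) by pseudo-inverse with relative singular-value cutoff
  1e−10. This is the classic unregularized S-map route.

The two solvers are deliberately distinct: the SVD route's weight placement
(w, not √w) and hard cutoff behave differently from Tikhonov damping in
thin, strongly localized neighbourhoods, and the package's own comparisons
showed the distinction matters for Jacobian quality at low noise. In the
synthetic benchmark **all** methods (LMDr and the three baselines) use the
unregularized SVD route so that only the distance measure differs between
them; the ridge path carries the empirical pipeline, where sampling noise
is substantial.

## Optimizing the locality matrix

The leave-one-out forecast RMSE is the objective ("energy"). It is
non-convex in Θ, so it is minimized by temperature-parallel simulated
annealing: `k` Metropolis chains at fixed temperatures (geometric ladder
between `t_min` and `t_max`), each proposing folded-Gaussian moves
`Θ_new = |Θ_old + Δ|`, `λ_new = |λ_old + δ|` and accepting uphill moves with
probability `exp(−ΔE/T)`; after every round of mutations, adjacent
temperatures may swap their full (λ, Θ, energy) state with probability 1
when `ΔT·ΔE < 0` and `exp(−ΔT·ΔE/(T_i T_j))` otherwise (pairings alternate
even/odd offsets between rounds). Chains start from λ = 0, Θ = I.

Defaults and their reasoning:

* `n_chains = 8`, `t_min = 1e−4·E₀`, `t_max = 1·E₀` with E₀ the initial
  energy — scaling the ladder to the data makes acceptance rates
  comparable across problems.
* `sigma_delta = 0.05` for Θ entries. The penalty λ lives on a scale about
  two orders finer than Θ (useful λ ≲ 1e−2 vs useful θ up to ~40), so λ
  proposals use a separate `sigma_lambda` (default `sigma_delta/10`);
  sharing one scale lets λ moves dominate the accept/reject decision and
  stalls the Θ walk.
* `n_mutations_per_round = 100`, `n_exchange_rounds = 100`. The shipped
  analyses use smaller schedules (see below) chosen as this package's own
  single-CPU working sizes; all are recorded in each result's metadata.
* `optimize_lambda = False` freezes λ at the ridge config's value — used by
  the benchmark, where regularization is switched off by design.

Reproducibility: each chain consumes an independent `SeedSequence`-spawned
stream and exchanges use a dedicated stream, so results are bit-identical
for a given `master_seed` regardless of scheduling. Energies are memoized
within a run (exchanges revisit states); carried energies are valid because
the objective is deterministic.

The annealer's hot loop evaluates the energy with vectorized batched
normal-equation solves; for the SVD route it uses the w²-weighted normal
equations with a 1e−8 trace-scaled Tikhonov floor standing in for the
pseudo-inverse cutoff. This agrees with the exact per-row route to ~1e−4
relative (asserted in tests) and is an order of magnitude faster; final
reported fits always go through the exact solver.

## Synthetic benchmark systems

Five systems with analytic Jacobians (all verified against central
differences at random admissible states):

* **predatorFR** (discrete, n = 3): one prey with Ricker-logistic growth and
  two predators with Beddington-DeAngelis functional responses,
  `x1' = x1 exp(r(1−x1) − Σ_i a_i x_i/(1 + a_i h_i x1 + w_i x_i))`,
  `x_i' = x_i exp(e_i a_i x1/(1 + a_i h_i x1 + w_i x_i) − d_i)`.
  Two parameter cases: "case1" (more efficient predation by predator 2,
  equal interference) and "case2" (equal attack rates, stronger interference
  within predator 3). Both parameter sets were chosen by numerical search
  for chaotic three-species coexistence (positive largest Lyapunov exponent
  along the attractor, all species bounded away from extinction).
* **Lorenz63** (continuous, n = 3): canonical (σ, ρ, β) = (10, 28, 8/3),
  sampling stride τ = 25 integration steps.
* **5CLM** (discrete, n = 5): logistic maps on a ring,
  `x_i' = x_i (r_i(1−x_i) − Σ β_ij x_j)`, growth rates 3.58–3.80, symmetric
  nearest-neighbour competition β = 0.05.
* **5CFC** (continuous, n = 5): a food chain with Holling type II links and
  weak top-predator self-limitation; parameters chosen so all five levels
  persist with sustained oscillation; τ = 50.
* **MulInt** (discrete, n = 20): multispecies Ricker
  `x_i' = x_i exp(r_i(1 − (Ax)_i))` with a fixed seeded random interaction
  matrix (connectance 0.15, off-diagonal strengths U(−0.05, 0.05), unit
  self-regulation, r_i ∈ U(2.2, 2.7)).

Noise follows the shared law: process noise `δ_i ~ N(0, σ_proc·SD(x_i))`
enters the dynamics (`x(t+1) = f(x(t)+δ(t))` discrete; `dx/dt = f(x+δ)`
continuous, δ redrawn once per RK4 step of size 0.01 and held through the
four stages); observation error `ε_i ~ N(0, σ_obs·SD(x_i))` is added after
sampling. `SD(x_i)` comes from a long noise-free reference run of the same
model (cached), since the realized noisy series' SD would make the noise
law self-referential. Burn-in: 500 steps discrete / 5×10⁴ integration steps
continuous. Ecological maps clip states at 1e−12 and a run is rejected
(re-seeded, up to 5 attempts) only if a species' median over the final
quarter sits at the floor — transient dips with recovery are genuine
dynamics and are kept.

True Jacobians are the analytic `∂f/∂x` along the clean (observation-error
free) trajectory; continuous-time Jacobians are discretized as
`K(t) = expm(dt·τ·J(t))` so that they are comparable with one-step-ahead
regression coefficients (scipy's Padé-based `expm`; checked against a
30-term series truncation and the semigroup identity at 1e−10).

## The noise-grid benchmark

For each model, noise cell (σ_proc, σ_obs ∈ {0.001, 0.051, 0.101}) and
replicate, the full variable set is embedded (no lags), each method fits
every variable as the target, and skill is the Pearson correlation between
the pooled true and estimated Jacobian elements (all time points and all
estimated positions pooled; a per-variable breakdown is emitted alongside,
and intercepts are excluded — they have no true counterpart). Study sizes
are m = 200 (discrete) and m = 300 (continuous) with 10 replicates per cell;
the shipped acceptance run scales this to one model (predatorFR), two cells
and 5 replicates, with a TPSA schedule of 4 chains × 60 mutations × 50
rounds and σ_δ = 0.3 — sizes chosen as this package's single-CPU working
configuration. Cell seeds derive deterministically from the master seed via
CRC-stamped `SeedSequence`s; per-cell failures are recorded as missing and
the run continues.

## Empirical predator-prey pipeline

For a two-species count series (prey `Pa`, predator `Dn`, 12-h cadence):

1. standardize each species to zero mean, unit variance (sample SD, n−1);
2. select the embedding dimension E ∈ 2..10 per species by leave-one-out
   simplex projection (E+1 nearest neighbours, weights `exp(−d/d_min)`,
   uniform when d_min = 0; ties to the smaller E);
3. embed as (Pa(t), Dn(t), target lags t−1..t−(E−2) if E > 2);
4. fit LMDr (TPSA with ridge, λ optimized) and the MDR S-map (multi-view
   distance, θ grid 0..20 by 0.1, ridge penalty selected from a small
   geometric λ grid by leave-one-out RMSE);
5. report the interspecific Jacobians — the coefficient on the *other*
   species' t-column only; lag-column coefficients are lag effects and are
   kept separate;
6. repeat under the sampling-error model
   `σ_Pa(t) = 0.417·Pa(t)^0.5`, `σ_Dn(t) = 0.164·Dn(t)^0.5` (noise added to
   raw counts before standardization, negatives clipped to zero, 100
   replicates by default, each independently seeded); replicates reuse the
   clean run's selected E so only the noise varies;
7. summarize Jacobian-vs-density relationships with quadratic polynomial
   fits; replicate fits give pointwise 95 % bands over a density grid.

### The synthetic fixture

The package ships no experimental counts. `make_protozoa_fixture` generates
a stand-in from a discrete Rosenzweig-MacArthur-style map with a Holling
type II functional response at realistic count scales (prey ~150,
predator ~50 per sample), plus lognormal demographic noise of scale 0.05
per step — live cultures are not deterministic, and an exactly periodic
noise-free attractor makes embedding-dimension selection degenerate
(near-tied simplex skill across E). The `condition` toggle lowers the
attack rate (with demographic rates re-balanced to keep the cycle), mimicking
prey of poorer nutritional quality. Because the generating model is known,
the fixture's analytic Jacobians provide a sign oracle: predation negative
(`∂Pa(t+1)/∂Dn(t) < 0`), feeding positive (`∂Dn(t+1)/∂Pa(t) > 0`) at every
realized state.

What passing on the fixture does and does not show: it validates the full
pipeline mechanics and sign/density-dependence recovery under a known
two-species law with count-scale sampling noise; it does not establish
performance on real microcosm data, which has unmodelled structure
(resource dynamics through the bacterial food supply, demographic
covariance, observation protocol drift).

## Numerical choices

* Ridge intercept: unpenalized by default (`penalize_intercept` flag
  available); the λ = 0 closed form falls back to a pseudo-inverse with
  relative cutoff 1e−10 if the normal matrix is singular.
* Weight normalizer row means exclude the diagonal zero.
* Distance/weight degeneracies (a state identical to all others) raise
  rather than silently producing uniform weights.
* Zero-variance embedding columns warn and proceed (their Θ entries are
  free parameters with no effect).
* Baseline grid ties break toward the smallest θ; view-skill ties keep the
  earlier-enumerated view.
* The anisotropy toy regression target carries noise of SD 0.3 so that the
  locality/variance trade-off has an interior optimum; an essentially
  noise-free target rewards unbounded localization and has no well-defined
  optimal Θ.

## Known limitations

* The annealer is a stochastic optimizer on a rugged landscape; at the
  shipped single-CPU schedules occasional runs converge to inferior Θ. The
  benchmark criteria are therefore stated on medians over replicates.
* The linear mutation kernel cannot resolve λ below ~σ_λ; in regimes where
  the optimal penalty is effectively zero the SVD route (regularization
  off) is the appropriate configuration, as in the benchmark.
* Multi-view enumeration is capped (default 50 views) and the top-view
  count is a convention (`ceil(sqrt(n_views))`); both are exposed in
  `ViewEnsemble` and recorded in outputs.
* Continuous-time process noise is injected per RK4 step, not as a proper
  SDE discretization.
* Irregular sampling, missing values and multi-step-ahead forecasting are
  out of scope.
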