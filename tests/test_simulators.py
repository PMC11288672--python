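import numpy as np
import pytest

from lmdr.simulators import (
    MODEL_NAMES,
    NoiseSpec,
    discretize_jacobian,
    get_model,
    reference_sd,
    simulate,
    simulate_continuous,
    simulate_discrete,
    true_jacobian,
)


def _fd_jacobian(model, x, h=1e-6):
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (model.f(x + e) - model.f(x - e)) / (2 * h)
    return J


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_analytic_jacobian_matches_finite_differences(name):
    model = get_model(name)
    rng = np.random.default_rng(0)
    for _ in range(20):
        if name == "Lorenz63":
            x = rng.uniform(-20, 20, 3)
            x[2] = abs(x[2])
        else:
            x = rng.uniform(0.05, 0.9, model.dimension)
        Ja = model.jacobian(x)
        Jf = _fd_jacobian(model, x)
        np.testing.assert_allclose(Ja, Jf, rtol=1e-4, atol=1e-7)


class TestDiscreteSimulation:
    def test_noise_free_determinism(self):
        model = get_model("predatorFR")
        a = simulate_discrete(model, 60, NoiseSpec(0, 0, seed=1))
        b = simulate_discrete(model, 60, NoiseSpec(0, 0, seed=1))
        np.testing.assert_array_equal(a.clean.values, b.clean.values)
        np.testing.assert_array_equal(a.observed.values, a.clean.values)

    def test_requested_length(self):
        out = simulate_discrete(get_model("5CLM"), 200, NoiseSpec(0.001, 0.001, seed=2))
        assert len(out.observed) == 200
        assert out.true_jacobians.shape == (200, 5, 5)

    def test_scalar_logistic_fixed_point(self):
        # independent closed-form check on a custom one-dimensional model
        from lmdr.simulators import ModelSpec

        model = ModelSpec(
            name="logistic_r2",
            time_type="discrete",
            dimension=1,
            parameters={"r": 2.0},
            rhs=lambda x, p: p["r"] * x * (1 - x),
            analytic_jacobian=lambda x, p: np.array([[p["r"] * (1 - 2 * x[0])]]),
            x0=np.array([0.3]),
        )
        x = model.x0.copy()
        for _ in range(30):
            x = model.f(x)
        assert x[0] == pytest.approx(0.5, abs=1e-6)
        assert model.jacobian(x)[0, 0] == pytest.approx(0.0, abs=1e-5)

    def test_observation_error_magnitude_law(self):
        model = get_model("5CLM")
        sd = reference_sd(model)
        out = simulate_discrete(model, 200, NoiseSpec(0.0, 0.101, seed=3))
        resid = out.observed.values - out.clean.values
        np.testing.assert_allclose(resid.std(axis=0), 0.101 * sd, rtol=0.25)

    def test_process_noise_magnitude_law(self):
        # injected noise SD per variable ~ sigma_proc * SD(x_i): measure by
        # comparing one-step predictions of the noise-free map to realized steps
        model = get_model("5CLM")
        sd = reference_sd(model)
        out = simulate_discrete(model, 2000, NoiseSpec(0.051, 0.0, seed=4))
        v = out.clean.values
        # invert: x(t+1) = f(x(t) + delta) with small delta ~ f(x) + J delta
        implied = []
        for t in range(len(v) - 1):
            J = model.jacobian(v[t])
            if np.linalg.cond(J) > 20:  # skip steps where inversion amplifies error
                continue
            implied.append(np.linalg.solve(J, v[t + 1] - model.f(v[t])))
        implied = np.array(implied)
        assert len(implied) > 300
        # robust scale (linearization leaves heavy tails)
        mad_sigma = 1.4826 * np.median(np.abs(implied - np.median(implied, 0)), 0)
        np.testing.assert_allclose(mad_sigma, 0.051 * sd, rtol=0.3)


class TestContinuousSimulation:
    def test_lorenz_bounded(self):
        out = simulate_continuous(get_model("Lorenz63"), 200, NoiseSpec(0, 0, seed=1),
                                  burn_in_steps=10_000)
        assert np.max(np.abs(out.clean.values)) < 100

    def test_rk4_step_halving_convergence(self):
        # short horizon from identical initial state: chaotic divergence has
        # no time to act, so the difference reflects integrator error only
        model = get_model("Lorenz63")
        a = simulate_continuous(model, 5, NoiseSpec(0, 0, seed=1), dt=0.01, tau=10,
                                burn_in_steps=0)
        b = simulate_continuous(model, 5, NoiseSpec(0, 0, seed=1), dt=0.005, tau=20,
                                burn_in_steps=0)
        rel = np.abs(a.clean.values - b.clean.values) / (np.abs(b.clean.values) + 1e-9)
        assert np.max(rel) < 1e-4

    def test_observation_error_added_after_sampling(self):
        model = get_model("Lorenz63")
        sd = reference_sd(model)
        out = simulate_continuous(model, 300, NoiseSpec(0.0, 0.101, seed=2),
                                  burn_in_steps=5000)
        resid = out.observed.values - out.clean.values
        np.testing.assert_allclose(resid.std(axis=0), 0.101 * sd, rtol=0.10)

    def test_jacobians_are_discretized(self):
        model = get_model("Lorenz63")
        out = simulate_continuous(model, 20, NoiseSpec(0, 0, seed=1), burn_in_steps=2000)
        x = out.clean.values[0]
        expected = discretize_jacobian(model.jacobian(x), out.sampling_interval)
        np.testing.assert_allclose(out.true_jacobians[0], expected, atol=1e-12)


class TestDiscretizeJacobian:
    def test_zero_matrix_gives_identity(self):
        np.testing.assert_allclose(discretize_jacobian(np.zeros((3, 3)), 10), np.eye(3))

    def test_diagonal_closed_form(self):
        J = np.diag([0.7, -1.2])
        K = discretize_jacobian(J, 100)  # 0.01 * 100 = 1
        np.testing.assert_allclose(K, np.diag([np.exp(0.7), np.exp(-1.2)]), rtol=1e-12)

    def test_matches_truncated_series(self, rng):
        J = rng.normal(size=(3, 3))
        K = discretize_jacobian(J, 25)
        M = 0.01 * 25 * J
        S = np.eye(3)
        term = np.eye(3)
        for i in range(1, 30):
            term = term @ M / i
            S = S + term
        np.testing.assert_allclose(K, S, atol=1e-10)

    def test_semigroup_property(self, rng):
        J = rng.normal(size=(4, 4)) * 0.5
        K_sum = discretize_jacobian(J, 30)
        K_prod = discretize_jacobian(J, 10) @ discretize_jacobian(J, 20)
        np.testing.assert_allclose(K_sum, K_prod, atol=1e-10)

    def test_rejects_nonfinite(self):
        J = np.array([[np.inf, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            discretize_jacobian(J, 1)


class TestTrueJacobianSigns:
    def test_predator_prey_sign_structure(self):
        # predation hurts the prey, prey density rewards the predator
        out = simulate_discrete(get_model("predatorFR"), 100, NoiseSpec(0, 0, seed=1))
        J = out.true_jacobians
        assert np.all(J[:, 0, 1] < 0)  # d x1' / d x2 < 0
        assert np.all(J[:, 0, 2] < 0)  # d x1' / d x3 < 0
        assert np.all(J[:, 1, 0] > 0)  # d x2' / d x1 > 0
        assert np.all(J[:, 2, 0] > 0)  # d x3' / d x1 > 0

    def test_linear_model_constant_jacobian(self):
        from lmdr.simulators import ModelSpec
        from lmdr.state_space import TimeSeriesTable

        A = np.array([[0.5, 0.1], [-0.2, 0.8]])
        model = ModelSpec(
            name="linear", time_type="discrete", dimension=2, parameters={},
            rhs=lambda x, p: A @ x,
            analytic_jacobian=lambda x, p: A.copy(),
            x0=np.array([1.0, 1.0]),
        )
        clean = TimeSeriesTable(np.arange(5.0), np.ones((5, 2)), ["x1", "x2"])
        J = true_jacobian(model, clean)
        np.testing.assert_allclose(J, np.tile(A, (5, 1, 1)))
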