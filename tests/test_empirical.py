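import numpy as np
import pytest

from lmdr.empirical import (
    SamplingErrorModel,
    analyze_experiment,
    make_protozoa_fixture,
    perturb_with_sampling_error,
    quadratic_response_summary,
    run_protozoa_analysis,
    select_embedding_dimension,
    standardize,
)
from lmdr.state_space import TimeSeriesTable
from lmdr.tpsa import TPSAConfig

LEAN_TPSA = TPSAConfig(
    n_chains=3, sigma_delta=0.5, sigma_lambda=0.01,
    n_mutations_per_round=15, n_exchange_rounds=12,
)


def _experiment(vals):
    from lmdr.empirical import ProtozoaExperiment

    return ProtozoaExperiment(
        series=TimeSeriesTable(
            np.arange(len(vals)) * 0.5, np.asarray(vals, float), ["Pa", "Dn"]
        ),
        name="toy",
    )


class TestStandardize:
    def test_symmetric_triple(self):
        ts = TimeSeriesTable(np.arange(3.0), np.array([[1.0], [2.0], [3.0]]), ["x"])
        out, params = standardize(ts)
        np.testing.assert_allclose(out.values[:, 0], [-1, 0, 1])  # sample SD = 1
        assert params["x"]["mean"] == 2.0 and params["x"]["sd"] == 1.0

    def test_idempotent(self, two_var_series):
        once, _ = standardize(two_var_series)
        twice, _ = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_affine_invariant(self, two_var_series):
        shifted = TimeSeriesTable(
            two_var_series.time.copy(),
            3.5 * two_var_series.values + 11.0,
            list(two_var_series.names),
        )
        a, _ = standardize(two_var_series)
        b, _ = standardize(shifted)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_zero_variance_rejected(self):
        ts = TimeSeriesTable(np.arange(4.0), np.ones((4, 1)), ["x"])
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(ts)


class TestSimplexEmbedding:
    def test_smooth_oscillation_forecast_is_near_perfect(self):
        # dense noise-free sine: skill saturates already at E=2, so the
        # selected E adds no material improvement over the smallest candidate
        from lmdr.empirical import _simplex_forecast_rmse

        t = np.arange(0, 40, 0.25)
        x = np.sin(t)
        E = select_embedding_dimension(x)
        assert _simplex_forecast_rmse(x, E) < 0.03 * x.std()
        assert _simplex_forecast_rmse(x, 2) < 1.3 * _simplex_forecast_rmse(x, E)

    def test_candidate_range_is_2_to_10(self):
        # white noise: every E admissible, a value is still returned
        rng = np.random.default_rng(0)
        E = select_embedding_dimension(rng.normal(size=120))
        assert 2 <= E <= 10

    def test_white_noise_rmse_near_series_sd(self):
        from lmdr.empirical import _simplex_forecast_rmse

        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        for E in (2, 5, 9):
            rmse = _simplex_forecast_rmse(x, E)
            assert 0.8 < rmse / x.std() < 1.4

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="too short"):
            select_embedding_dimension(np.arange(8.0))


class TestSamplingError:
    def test_zero_counts_unchanged(self):
        vals = np.zeros((10, 2))
        vals[:, 0] = [0, 10, 0, 5, 0, 2, 0, 8, 1, 0]
        vals[:, 1] = 1.0
        exp = _experiment(vals)
        pert = perturb_with_sampling_error(exp, SamplingErrorModel(seed=1), 0)
        zero_rows = vals[:, 0] == 0
        np.testing.assert_array_equal(pert.series.values[zero_rows, 0], 0.0)

    def test_noise_sd_matches_printed_law(self):
        # Pa = 100 -> SD = 0.417 * 10 = 4.17
        vals = np.full((2000, 2), 100.0)
        exp = _experiment(vals)
        model = SamplingErrorModel(seed=2)
        draws = perturb_with_sampling_error(exp, model, 0).series.values
        assert draws[:, 0].std() == pytest.approx(0.417 * 10, rel=0.05)
        assert draws[:, 1].std() == pytest.approx(0.164 * 10, rel=0.05)

    def test_counts_clipped_at_zero(self):
        vals = np.full((500, 2), 1.0)  # tiny counts, noise can go negative
        pert = perturb_with_sampling_error(_experiment(vals), SamplingErrorModel(seed=3), 1)
        assert np.all(pert.series.values >= 0)

    def test_replicates_differ_but_are_reproducible(self):
        exp = make_protozoa_fixture(m=60, seed=4)
        model = SamplingErrorModel(seed=9)
        a0 = perturb_with_sampling_error(exp, model, 0)
        a0b = perturb_with_sampling_error(exp, model, 0)
        a1 = perturb_with_sampling_error(exp, model, 1)
        np.testing.assert_array_equal(a0.series.values, a0b.series.values)
        assert not np.array_equal(a0.series.values, a1.series.values)


class TestFixture:
    def test_count_scale_and_oscillation(self):
        exp = make_protozoa_fixture(m=70, seed=1)
        v = exp.series.values
        assert 50 < v[:, 0].mean() < 500  # prey counts
        assert 5 < v[:, 1].mean() < 150  # predator counts
        assert (v.std(0) / v.mean(0)).min() > 0.3  # sustained cycles

    def test_truth_has_predator_prey_signs(self):
        _, J = make_protozoa_fixture(m=70, seed=1, return_truth=True)
        assert np.all(J[:, 0, 1] < 0)
        assert np.all(J[:, 1, 0] > 0)

    def test_cadence_is_half_day(self):
        exp = make_protozoa_fixture(m=20, seed=0)
        assert exp.series.dt == pytest.approx(0.5)


class TestAnalysis:
    def test_clean_run_sign_recovery(self):
        exp = make_protozoa_fixture(m=70, seed=1)
        res = analyze_experiment(exp, methods=("LMDr",), seed=3, tpsa=LEAN_TPSA)
        by = {r.target: r for r in res}
        assert (by["Pa"].cross_jacobian < 0).mean() > 0.8  # predator hurts prey
        assert (by["Dn"].cross_jacobian > 0).mean() > 0.8  # prey feeds predator

    def test_clean_run_deterministic(self):
        exp = make_protozoa_fixture(m=60, seed=2)
        a = analyze_experiment(exp, methods=("LMDr",), seed=5, tpsa=LEAN_TPSA)
        b = analyze_experiment(exp, methods=("LMDr",), seed=5, tpsa=LEAN_TPSA)
        np.testing.assert_array_equal(a[0].cross_jacobian, b[0].cross_jacobian)

    def test_zero_replicates_skips_noise_path(self):
        exp = make_protozoa_fixture(m=60, seed=3)
        out = run_protozoa_analysis(
            [exp], methods=("LMDr",), error_model=SamplingErrorModel(n_replicates=0),
            seed=1, tpsa=LEAN_TPSA,
        )
        r = out[exp.name]
        assert r["replicates"] == []
        assert len(r["clean"]) == 2
        assert not r["functional_response"].empty

    def test_quadratic_summary_band_contains_clean_fit_mostly(self):
        exp = make_protozoa_fixture(m=60, seed=4)
        clean = analyze_experiment(exp, methods=("LMDr",), seed=2, tpsa=LEAN_TPSA)
        dims = {r.target: r.embedding_dim for r in clean}
        model = SamplingErrorModel(n_replicates=12, seed=6)
        reps = [
            analyze_experiment(
                perturb_with_sampling_error(exp, model, i),
                methods=("LMDr",), seed=2, embedding_dims=dims, tpsa=LEAN_TPSA,
            )
            for i in range(model.n_replicates)
        ]
        summ = quadratic_response_summary(clean, reps, density_axis="Pa")
        inside = (summ.clean_fit >= summ.band_lo) & (summ.clean_fit <= summ.band_hi)
        # unbiased noise model: the replicate band straddles the clean curve
        assert inside.mean() >= 0.5
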