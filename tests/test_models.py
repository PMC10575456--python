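"""ELM, PSO and the delegated PLS/RF regressors."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from wheatcgi.models import (
    ELMModel,
    PSOConfig,
    fit_elm,
    fit_pls,
    fit_pso_elm,
    fit_rf,
    predict_elm,
    pso_optimize,
)


def make_regression(rng, n=30, p=4, noise=0.1):
    x = rng.uniform(-2, 2, size=(n, p))
    w = rng.normal(size=p)
    y = x @ w + noise * rng.normal(size=n)
    return x, y


class TestELM:
    def test_interpolates_when_hidden_matches_samples(self, rng):
        x, y = make_regression(rng, n=6, p=2)
        model = fit_elm(x, y, n_hidden=6, seed=0)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-6)

    def test_output_weights_match_least_squares_oracle(self, rng):
        x, y = make_regression(rng)
        model = fit_elm(x, y, n_hidden=5, seed=1)
        h = model.hidden(x)
        beta_oracle, *_ = np.linalg.lstsq(h, y, rcond=None)
        np.testing.assert_allclose(model.output_weights, beta_oracle, atol=1e-8)

    def test_same_seed_identical_models(self, rng):
        x, y = make_regression(rng)
        a = fit_elm(x, y, seed=7)
        b = fit_elm(x, y, seed=7)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)

    def test_predict_shapes(self, rng):
        x, y = make_regression(rng)
        model = fit_elm(x, y)
        assert predict_elm(model, x).shape == (len(y),)
        assert np.isscalar(float(model.predict(x[0])))

    def test_feature_count_mismatch_rejected(self, rng):
        x, y = make_regression(rng)
        model = fit_elm(x, y)
        with pytest.raises(ValueError, match="features"):
            model.predict(x[:, :2])

    def test_out_of_range_features_finite(self, rng):
        x, y = make_regression(rng)
        model = fit_elm(x, y)
        assert np.isfinite(model.predict(10 * x)).all()

    def test_constant_feature_warns(self, rng):
        x, y = make_regression(rng)
        x[:, 0] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            fit_elm(x, y)

    def test_json_round_trip(self, rng):
        x, y = make_regression(rng)
        model = fit_elm(x, y, seed=5)
        back = ELMModel.from_json(model.to_json())
        np.testing.assert_allclose(back.predict(x), model.predict(x))


class TestPSO:
    def test_sphere_minimized(self):
        best, trace = pso_optimize(
            lambda p: float(np.sum(p ** 2)), dim=3, config=PSOConfig(seed=0)
        )
        assert trace[-1] < 1e-2

    def test_trace_nonincreasing(self):
        _, trace = pso_optimize(
            lambda p: float(np.sum(np.abs(p))), dim=4, config=PSOConfig(seed=1)
        )
        assert (np.diff(trace) <= 0).all()

    def test_constant_fitness(self):
        _, trace = pso_optimize(lambda p: 3.5, dim=2, config=PSOConfig(seed=2, max_iter=10))
        assert trace[-1] == pytest.approx(3.5)

    def test_positions_respect_box_bounds(self):
        seen = []

        def fitness(p):
            seen.append(p.copy())
            return float(np.sum(p ** 2))

        pso_optimize(fitness, dim=3, config=PSOConfig(seed=3, max_iter=20))
        arr = np.array(seen)
        assert arr.min() >= -1.0 and arr.max() <= 1.0

    def test_non_finite_fitness_names_particle(self):
        with pytest.raises(ValueError, match="particle"):
            pso_optimize(lambda p: float("nan"), dim=2, config=PSOConfig(seed=0, max_iter=2))

    def test_seed_reproducible(self):
        f = lambda p: float(np.sum(p ** 2))
        a, ta = pso_optimize(f, 3, PSOConfig(seed=9, max_iter=20))
        b, tb = pso_optimize(f, 3, PSOConfig(seed=9, max_iter=20))
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ta, tb)

    @pytest.mark.parametrize(
        "kwargs", [{"n_particles": 1}, {"max_iter": 0}, {"c1": 0.0},
                   {"velocity_bounds": (1.0, -1.0)}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PSOConfig(**kwargs)


class TestPSOELM:
    small = PSOConfig(max_iter=30, n_particles=15, seed=0)

    def test_trace_nonincreasing(self, rng):
        x, y = make_regression(rng)
        fr = fit_pso_elm(x, y, n_hidden=4, pso=self.small)
        assert (np.diff(fr.fitness_trace) <= 0).all()

    def test_noise_free_linear_target_fits_tightly(self, rng):
        x, y = make_regression(rng, n=40, noise=0.0)
        fr = fit_pso_elm(x, y, n_hidden=5, pso=PSOConfig(max_iter=60, n_particles=20, seed=1))
        pred = fr.model.predict(x)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_swarm_beats_random_draw_on_training_objective(self, rng):
        """Median over seeds: PSO training RMSE <= plain ELM training RMSE."""
        deltas = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            x, y = make_regression(local, n=25, p=3, noise=0.3)
            elm = fit_elm(x, y, n_hidden=4, seed=seed)
            rmse_elm = float(np.sqrt(np.mean((elm.predict(x) - y) ** 2)))
            fr = fit_pso_elm(
                x, y, n_hidden=4, pso=PSOConfig(max_iter=25, n_particles=12, seed=seed)
            )
            rmse_pso = float(np.sqrt(np.mean((fr.model.predict(x) - y) ** 2)))
            deltas.append(rmse_pso - rmse_elm)
        assert np.median(deltas) <= 0

    def test_seed_reproducible(self, rng):
        x, y = make_regression(rng)
        a = fit_pso_elm(x, y, pso=self.small)
        b = fit_pso_elm(x, y, pso=self.small)
        np.testing.assert_array_equal(a.model.output_weights, b.model.output_weights)


class TestDelegatedModels:
    def test_pls_full_components_reproduces_ols(self, rng):
        x, y = make_regression(rng, n=40, p=4)
        pls = fit_pls(x, y, n_components=4)
        ols = LinearRegression().fit(x, y)
        np.testing.assert_allclose(pls.predict(x), ols.predict(x), atol=1e-8)

    def test_pls_component_cap_warns(self, rng):
        x, y = make_regression(rng, n=10, p=2)
        with pytest.warns(UserWarning, match="reduced"):
            fit_pls(x, y, n_components=5)

    def test_rf_honors_hyperparameters(self, rng):
        x, y = make_regression(rng)
        rf = fit_rf(x, y, n_trees=100, min_leaf=5, seed=0)
        params = rf.estimator.get_params()
        assert params["n_estimators"] == 100
        assert params["min_samples_leaf"] == 5

    def test_pls_default_components(self, rng):
        x, y = make_regression(rng, p=6)
        pls = fit_pls(x, y)
        assert pls.estimator.get_params()["n_components"] == 3

    def test_rf_on_pure_noise_has_no_skill(self):
        """Validation R^2 on an unrelated target stays near zero."""
        r2s = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            x = local.uniform(size=(54, 5))
            y = local.normal(size=54)
            rf = fit_rf(x[:40], y[:40], seed=seed)
            pred = rf.predict(x[40:])
            ss_res = np.sum((y[40:] - pred) ** 2)
            ss_tot = np.sum((y[40:] - y[40:].mean()) ** 2)
            r2s.append(1 - ss_res / ss_tot)
        assert np.median(r2s) <= 0.3
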