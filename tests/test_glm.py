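"""Design construction, penalised likelihood, fitting and prediction."""

import numpy as np
import pytest

from whiskerglm import glm
from whiskerglm.glm import (
    DegenerateFitError,
    GLMConfig,
    GLMModel,
    build_design,
    fit,
    penalized_nll,
    predict,
    preferred_direction,
)


def make_design(rng, T=400, L_k=5, L_h=2, two_trials=False, quadratic=False):
    x = rng.normal(size=T)
    n = (rng.random(T) < 0.2).astype(int)
    bounds = [(0, T // 2), (T // 2, T)] if two_trials else [(0, T)]
    return build_design([x], n, bounds, GLMConfig(L_k=L_k, L_h=L_h, quadratic=quadratic)), x, n


class TestBuildDesign:
    def test_minimal_filter_gives_four_fit_parameters(self, rng):
        design, _, _ = make_design(rng, L_k=1, L_h=2)
        assert design.n_params == 4  # 1 stimulus + 2 history + bias

    def test_standard_filter_gives_eight_fit_parameters(self, rng):
        design, _, _ = make_design(rng, L_k=5, L_h=2)
        assert design.n_params == 8  # 5 stimulus + 2 history + bias

    def test_rows_match_brute_force_and_stay_within_trials(self, rng):
        L_k, L_h = 3, 2
        x = rng.normal(size=40)
        n = (rng.random(40) < 0.3).astype(int)
        bounds = [(0, 20), (20, 40)]
        design = build_design([x], n, bounds, GLMConfig(L_k=L_k, L_h=L_h))
        z = (x - design.zscore_mean[0]) / design.zscore_sd[0]
        margin = max(L_k, L_h)
        row = 0
        for start, stop in bounds:
            for t in range(start + margin, stop):
                stim = z[t - L_k + 1 : t + 1]          # includes bin t
                hist = n[t - L_h : t]                   # strictly before t
                np.testing.assert_allclose(design.X[row, :L_k], stim)
                np.testing.assert_allclose(design.X[row, L_k:], hist)
                assert t - L_k + 1 >= start and t - L_h >= start
                assert design.y[row] == n[t]
                row += 1
        assert row == design.X.shape[0]

    def test_quadratic_appends_squared_zscored_history(self, rng):
        design, x, _ = make_design(rng, quadratic=True)
        L_k = design.config.L_k
        np.testing.assert_allclose(design.X[:, L_k : 2 * L_k], design.X[:, :L_k] ** 2)

    def test_misaligned_lengths_raise(self, rng):
        with pytest.raises(ValueError):
            build_design([rng.normal(size=10)], np.zeros(11), [(0, 11)])

    def test_invalid_filter_lengths_raise(self):
        with pytest.raises(ValueError):
            GLMConfig(L_k=0)


class TestPenalizedNLL:
    def test_all_zero_parameters_give_T_ln2(self, rng):
        design, _, _ = make_design(rng)
        model = GLMModel(stimulus_filters=[np.zeros(5)], history_filter=np.zeros(2), bias=0.0)
        cost, _ = penalized_nll(model, design)
        assert cost == pytest.approx(design.y.size * np.log(2), rel=1e-12)

    def test_gradient_matches_central_finite_differences(self, rng):
        design, _, _ = make_design(rng, T=200)
        w = rng.normal(scale=0.3, size=design.n_params)
        cost, grad = glm._cost_grad(w, design, alpha=0.01)
        eps = 1e-6
        for j in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[j] += eps
            wm[j] -= eps
            fd = (glm._cost_grad(wp, design, 0.01)[0] - glm._cost_grad(wm, design, 0.01)[0]) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_penalty_is_linear_in_alpha(self, rng):
        design, _, _ = make_design(rng)
        w = rng.normal(size=design.n_params)
        c0 = glm._cost_grad(w, design, 0.0)[0]
        c1 = glm._cost_grad(w, design, 0.01)[0]
        c2 = glm._cost_grad(w, design, 0.02)[0]
        assert c2 - c0 == pytest.approx(2 * (c1 - c0), rel=1e-12)

    def test_penalty_touches_stimulus_filter_only(self, rng):
        design, _, _ = make_design(rng)
        # vary only history/bias coordinates: cost must not depend on alpha
        w = np.zeros(design.n_params)
        w[-3:] = rng.normal(size=3)
        assert glm._cost_grad(w, design, 0.0)[0] == pytest.approx(
            glm._cost_grad(w, design, 5.0)[0], rel=1e-12
        )


class TestFit:
    def test_bias_only_model_recovered(self, rng):
        T = 300_000
        b_true = -3.0  # ~47 spikes/s
        n = (rng.random(T) < 1 / (1 + np.exp(-b_true))).astype(int)
        design = build_design([rng.normal(size=T)], n, [(0, T)], GLMConfig())
        model = fit(design)
        assert model.bias == pytest.approx(b_true, abs=0.05)
        assert np.abs(model.stimulus_filters[0]).max() < 0.05

    def test_descent_property(self, rng):
        design, _, _ = make_design(rng, T=1000)
        model = fit(design)
        w0 = np.zeros(design.n_params)
        c0 = glm._cost_grad(w0, design, design.config.alpha)[0]
        cfit = penalized_nll(model, design)[0]
        assert cfit <= c0 + 1e-9

    def test_mean_fitted_probability_matches_training_rate(self, rng):
        design, _, _ = make_design(rng, T=5000)
        model = fit(design)
        w = glm._model_to_vector(model, design)
        from scipy.special import expit
        p = expit(design.X @ w[:-1] + w[-1])
        assert p.mean() == pytest.approx(design.y.mean(), rel=0.02)

    def test_convexity_random_restarts_reach_same_optimum(self, rng):
        design, _, _ = make_design(rng, T=2000)
        costs, biases = [], []
        for _ in range(4):
            init = rng.normal(scale=2.0, size=design.n_params)
            m = fit(design, init=init)
            costs.append(penalized_nll(m, design)[0])
            biases.append(m.bias)
        assert np.ptp(costs) < 1e-4 * abs(np.mean(costs))
        assert np.ptp(biases) < 1e-3

    def test_four_parameter_model_recovery(self, whitenoise_session, curvature_unit, curvature_spikes):
        s = whitenoise_session
        design = build_design(
            [s.curvature_change_invmm], curvature_spikes.counts, s.trial_bounds,
            GLMConfig(L_k=1, L_h=2),
        )
        model = fit(design)
        k_true = curvature_unit.stimulus_filters[0][0]
        k_fit = model.stimulus_filters[0][0]
        assert np.sign(k_fit) == np.sign(k_true)
        assert k_fit == pytest.approx(k_true, rel=0.15)

    def test_degenerate_response_raises(self, rng):
        x = rng.normal(size=500)
        with pytest.raises(DegenerateFitError):
            fit(build_design([x], np.zeros(500), [(0, 500)], GLMConfig()))


class TestPredict:
    def test_zero_parameters_fire_at_half_probability(self, rng):
        model = GLMModel(stimulus_filters=[np.zeros(1)], history_filter=np.zeros(2), bias=0.0)
        x = rng.normal(size=20_000)
        probs, spikes = predict(model, [x], [(0, 20_000)], seed=0)
        assert np.allclose(probs, 0.5)
        assert spikes.mean() == pytest.approx(0.5, abs=0.02)  # ~500 spikes/s at 1 kHz

    def test_saturated_negative_bias_is_silent(self, rng):
        model = GLMModel(stimulus_filters=[np.zeros(1)], history_filter=np.zeros(2), bias=-20.0)
        _, spikes = predict(model, [rng.normal(size=50_000)], [(0, 50_000)], seed=0)
        assert spikes.sum() == 0

    def test_no_history_makes_sampled_probs_equal_expected(self, rng):
        model = GLMModel(stimulus_filters=[np.array([0.4, -0.2])], history_filter=np.zeros(2), bias=-1.0)
        x = rng.normal(size=3000)
        bounds = [(0, 1500), (1500, 3000)]
        probs, _ = predict(model, [x], bounds, mode="sampled", seed=1)
        expected = predict(model, [x], bounds, mode="expected")
        np.testing.assert_allclose(probs, expected, rtol=1e-12)

    def test_fixed_seed_reproduces_sampled_train(self, rng):
        model = GLMModel(stimulus_filters=[np.array([1.0])], history_filter=np.array([-1.0, -1.0]), bias=-2.0)
        x = rng.normal(size=5000)
        _, s1 = predict(model, [x], [(0, 5000)], seed=42)
        _, s2 = predict(model, [x], [(0, 5000)], seed=42)
        np.testing.assert_array_equal(s1, s2)

    def test_negative_history_filter_is_refractory(self):
        # constant supra-threshold drive; strongly negative h suppresses the
        # two bins after each spike
        model = GLMModel(stimulus_filters=[np.zeros(1)], history_filter=np.array([-30.0, -30.0]), bias=2.0)
        x = np.zeros(5000)
        probs, spikes = predict(model, [x], [(0, 5000)], seed=3)
        spike_times = np.flatnonzero(spikes)
        gaps = np.diff(spike_times)
        assert gaps.min() >= 3  # absolute refractory period from the history filter
        after = spike_times[:-1] + 1
        assert probs[after].max() < 1e-10

    def test_trial_boundaries_reset_history(self):
        # with a hugely positive history filter, a spike would perpetuate
        # itself; fresh trials must start from silence
        model = GLMModel(stimulus_filters=[np.zeros(1)], history_filter=np.array([0.0, 40.0]), bias=-5.0)
        x = np.zeros(2000)
        probs, _ = predict(model, [x], [(0, 1000), (1000, 2000)], seed=0)
        from scipy.special import expit
        assert probs[1000] == pytest.approx(expit(-5.0), rel=1e-9)


class TestPreferredDirection:
    @pytest.mark.parametrize("k, label", [(0.3, "positive"), (-0.3, "negative"), (0.0, "undetermined")])
    def test_sign_maps_to_label(self, k, label):
        m = GLMModel(stimulus_filters=[np.array([k])], history_filter=np.zeros(2), bias=0.0)
        assert preferred_direction(m) == label

    def test_round_trip_recovery_of_positive_tuned_unit(self, whitenoise_session, curvature_unit, curvature_spikes):
        s = whitenoise_session
        design = build_design([s.curvature_change_invmm], curvature_spikes.counts,
                              s.trial_bounds, GLMConfig(L_k=1, L_h=2))
        assert preferred_direction(fit(design)) == "positive"

    def test_requires_single_tap_filter(self):
        m = GLMModel(stimulus_filters=[np.zeros(5)], history_filter=np.zeros(2), bias=0.0)
        with pytest.raises(ValueError):
            preferred_direction(m)


def test_model_json_round_trip(tmp_path):
    m = GLMModel(
        stimulus_filters=[np.array([0.1, -0.2, 0.3])], history_filter=np.array([-1.0, -0.5]),
        bias=-2.5, alpha=0.01, quadratic=True, quad_filters=[np.array([0.01, 0.02, 0.03])],
        zscore_mean=[1.0], zscore_sd=[2.0],
    )
    path = tmp_path / "model.json"
    m.save(path)
    m2 = GLMModel.load(path)
    np.testing.assert_allclose(m2.stimulus_filters[0], m.stimulus_filters[0])
    np.testing.assert_allclose(m2.quad_filters[0], m.quad_filters[0])
    assert m2.bias == m.bias and m2.quadratic and m2.zscore_sd == [2.0]
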