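"""Tests for the three per-participant estimators and their standard errors."""

import numpy as np
import pytest

from steinshrink.estimators import (
    MetabolicTrial,
    SteppingTrial,
    brockway,
    extract_gain,
    fit_jacobian,
    fit_steady_state,
    resting_mean,
)

from conftest import make_metabolic_trial, make_stepping_trial

J_TRUE = np.array([[0.05, 0.25, 0.0], [0.0, 0.0, 0.30]])


class TestBrockway:
    @pytest.mark.parametrize(
        "vo2, vco2, expected",
        [
            (0.0, 0.0, 0.0),
            (1.0, 0.0, 16.58),
            (0.0, 1.0, 4.51),
            (0.2, 0.18, 4.1278),
        ],
    )
    def test_values(self, vo2, vco2, expected):
        assert brockway(vo2, vco2) == pytest.approx(expected, abs=1e-12)

    def test_linear_over_series(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 1, (2, 30))
        np.testing.assert_allclose(
            brockway(a + b, a), brockway(a, np.zeros_like(a)) + brockway(b, a)
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            brockway(-0.1, 0.2)


class TestFitJacobian:
    def test_noiseless_exact_recovery(self):
        trial = make_stepping_trial(J_TRUE, n_steps=60, residual_sd=0.0, seed=1)
        jac = fit_jacobian(trial)
        np.testing.assert_allclose(jac.J, J_TRUE, atol=1e-10)
        assert jac.n_steps_used == 60

    def test_output_equal_to_first_predictor(self):
        """dS tracking the first pelvis coordinate exactly gives row [1,0,0]."""
        rng = np.random.default_rng(2)
        dP = rng.standard_normal((40, 3))
        P = dP + [0, 0, 1.3]
        trial = SteppingTrial(
            participant_id="P01",
            x_pelvis=P[:, 0],
            xdot_pelvis=P[:, 1],
            ydot_pelvis=P[:, 2],
            x_foot=dP[:, 0],
            y_foot=dP[:, 0],
        )
        jac = fit_jacobian(trial)
        np.testing.assert_allclose(jac.J, [[1, 0, 0], [1, 0, 0]], atol=1e-10)

    def test_truncation_uses_first_window(self):
        trial = make_stepping_trial(J_TRUE, n_steps=100, residual_sd=0.01, seed=3)
        j25 = fit_jacobian(trial, 25)
        j25b = fit_jacobian(
            SteppingTrial(
                participant_id="x",
                x_pelvis=trial.x_pelvis[:25],
                xdot_pelvis=trial.xdot_pelvis[:25],
                ydot_pelvis=trial.ydot_pelvis[:25],
                x_foot=trial.x_foot[:25],
                y_foot=trial.y_foot[:25],
            )
        )
        np.testing.assert_allclose(j25.J, j25b.J, atol=1e-14)

    def test_variance_shrinks_like_one_over_n(self):
        """Coefficient variance at 100 steps is ~1/4 of that at 25 steps."""
        rng = np.random.default_rng(4)
        v25, v100 = [], []
        for s in rng.integers(0, 2**31, size=300):
            trial = make_stepping_trial(J_TRUE, 100, residual_sd=0.01, seed=int(s))
            v25.append(extract_gain(fit_jacobian(trial, 25))[1])
            v100.append(extract_gain(fit_jacobian(trial, 100))[1])
        ratio = np.mean(v100) / np.mean(v25)
        assert 0.25 / 1.5 < ratio < 0.25 * 1.5
        assert np.mean(v100) < np.mean(v25)

    def test_rank_deficient_rejected(self):
        n = 20
        rng = np.random.default_rng(5)
        x = rng.standard_normal(n)
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            fit_jacobian(
                SteppingTrial("p", x, 2 * x, rng.standard_normal(n),
                              rng.standard_normal(n), rng.standard_normal(n))
            )

    def test_too_few_steps_rejected(self):
        trial = make_stepping_trial(J_TRUE, n_steps=20, seed=6)
        with pytest.raises(ValueError, match="at least"):
            fit_jacobian(trial, 5)
        with pytest.raises(ValueError, match="only"):
            fit_jacobian(trial, 50)


class TestExtractGain:
    def test_indexing_convention(self):
        trial = make_stepping_trial(J_TRUE, n_steps=80, residual_sd=0.0, seed=7)
        gain, var = extract_gain(fit_jacobian(trial))
        assert gain == pytest.approx(0.25, abs=1e-10)
        assert var == pytest.approx(0.0, abs=1e-18)


class TestFitSteadyState:
    def test_noiseless_recovery(self):
        t = np.linspace(0, 360, 54)
        e = 4.5 - 2.0 * np.exp(-t / 30.0)
        fit = fit_steady_state(make_metabolic_trial(e, t), 54, bootstrap_reps=0)
        assert fit.converged
        assert fit.a0 == pytest.approx(4.5, rel=1e-6)
        assert fit.a1 == pytest.approx(-2.0, rel=1e-6)
        assert fit.tau == pytest.approx(30.0, rel=1e-6)

    def test_constant_series(self):
        trial = make_metabolic_trial(np.full(20, 5.0))
        fit = fit_steady_state(trial, 20, bootstrap_reps=0)
        assert fit.converged
        assert fit.a0 == pytest.approx(5.0, abs=1e-8)
        assert fit.a1 == pytest.approx(0.0, abs=1e-8)

    def test_time_origin_shift_leaves_a0_unchanged(self):
        t = np.linspace(0, 300, 50)
        e = 4.5 - 2.0 * np.exp(-t / 30.0)
        f0 = fit_steady_state(make_metabolic_trial(e, t), 50, bootstrap_reps=0)
        f1 = fit_steady_state(make_metabolic_trial(e, t + 120.0), 50, bootstrap_reps=0)
        assert f1.a0 == pytest.approx(f0.a0, abs=1e-8)

    def test_bootstrap_se_positive_with_noise(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 360, 54))
        e = 4.5 - 2.0 * np.exp(-t / 30.0) + 0.3 * rng.standard_normal(54)
        fit = fit_steady_state(
            make_metabolic_trial(np.maximum(e, 0), t), 54,
            bootstrap_reps=100, seed=1,
        )
        assert fit.converged
        assert fit.se_a0 > 0

    def test_too_few_points_rejected(self):
        trial = make_metabolic_trial(np.full(20, 5.0))
        with pytest.raises(ValueError, match="at least"):
            fit_steady_state(trial, 4)
        with pytest.raises(ValueError, match="only"):
            fit_steady_state(trial, 30)


class TestRestingMean:
    def test_constant_series_exact_with_zero_se(self):
        trials = [
            make_metabolic_trial(np.full(40, 1.2), pid="a"),
            make_metabolic_trial(np.full(40, 1.4), pid="b"),
        ]
        ests = resting_mean(trials, 20, bootstrap_reps=500, seed=0)
        assert [e.mean_edot for e in ests] == pytest.approx([1.2, 1.4], rel=1e-12)
        assert all(e.se == 0.0 for e in ests)

    def test_pooled_se_matches_closed_form(self):
        """Deviations {-1,+1} per participant: SE of a 2-point mean is 1/sqrt(2)."""
        trials = [
            make_metabolic_trial(np.array([4.0, 6.0]), pid="a"),
            make_metabolic_trial(np.array([9.0, 11.0]), pid="b"),
        ]
        ests = resting_mean(trials, 2, bootstrap_reps=4000, seed=1)
        assert ests[0].se == ests[1].se
        assert ests[0].se == pytest.approx(1.0 / np.sqrt(2), abs=0.04)

    def test_short_trial_rejected(self):
        trials = [make_metabolic_trial(np.full(10, 1.2))]
        with pytest.raises(ValueError, match="fewer"):
            resting_mean(trials, 20)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty pool"):
            resting_mean([], 5)


class TestTrialValidation:
    def test_stepping_minimum_steps(self):
        with pytest.raises(ValueError, match="fewer than"):
            SteppingTrial("p", *(np.zeros(5) for _ in range(5)))

    def test_metabolic_monotone_time(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MetabolicTrial("p", [0.0, 2.0, 2.0], [0.1] * 3, [0.1] * 3)

    def test_metabolic_negative_flux(self):
        with pytest.raises(ValueError, match="non-negative"):
            MetabolicTrial("p", [0.0, 1.0], [0.1, -0.1], [0.1, 0.1])
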