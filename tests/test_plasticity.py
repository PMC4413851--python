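import numpy as np
import pytest

from sparsemotor.neural_coding import (
    ActivationSpec,
    CodingLayer,
    SensoryWeights,
    ThresholdSpec,
    compute_activity,
    sample_sensory_weights,
)
from sparsemotor.plasticity import (
    LearningParams,
    MuscleMap,
    UnsupportedConfigurationError,
    converged_error,
    masked_projection,
    muscle_activity,
    train,
    trial_cost,
    update_J,
    update_W,
)
from sparsemotor.task_model import default_geometry
from sparsemotor.validation import finite_difference_gradient


def random_unit_pair(rng):
    ang = rng.uniform(0, 2 * np.pi, 2)
    return (
        np.array([np.cos(ang[0]), np.sin(ang[0])]),
        np.array([np.cos(ang[1]), np.sin(ang[1])]),
    )


class TestMuscleActivity:
    def test_zero_weights(self):
        M, mask = muscle_activity(np.zeros((3, 4)), np.ones(4) / 2.0)
        np.testing.assert_array_equal(M, 0.0)
        assert not mask.any()

    def test_negative_drive_rectified(self):
        W = np.array([[-1.0, -1.0], [1.0, 1.0]])
        M, mask = muscle_activity(W, np.array([0.6, 0.8]))
        assert M[0] == 0.0 and not mask[0]
        assert M[1] > 0.0 and mask[1]

    def test_hand_case(self):
        W = np.array([[1.0, -1.0], [0.0, 2.0]])
        M, mask = muscle_activity(W, np.array([0.6, 0.8]))
        np.testing.assert_allclose(M, [0.0, 1.6])
        np.testing.assert_array_equal(mask, [False, True])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            muscle_activity(np.zeros((3, 4)), np.zeros(5))


class TestMaskedProjection:
    def test_all_active(self, rng):
        P = rng.standard_normal((2, 5))
        np.testing.assert_array_equal(masked_projection(P, np.ones(5, bool)), P)

    def test_none_active(self, rng):
        P = rng.standard_normal((2, 5))
        np.testing.assert_array_equal(masked_projection(P, np.zeros(5, bool)), 0.0)

    def test_single_active_column(self, rng):
        P = rng.standard_normal((2, 5))
        mask = np.zeros(5, bool)
        mask[2] = True
        out = masked_projection(P, mask)
        np.testing.assert_array_equal(out[:, 2], P[:, 2])
        assert np.all(out[:, [0, 1, 3, 4]] == 0.0)

    def test_bad_mask_length(self, rng):
        with pytest.raises(ValueError):
            masked_projection(rng.standard_normal((2, 5)), np.ones(4, bool))


class TestUpdateW:
    def test_no_change_when_error_zero(self, rng):
        W = rng.standard_normal((3, 6))
        A = rng.uniform(0, 1, 6)
        A /= np.linalg.norm(A)
        P_plus = rng.standard_normal((2, 3))
        out = update_W(W, np.zeros(2), A, P_plus, LearningParams())
        np.testing.assert_array_equal(out, W)

    def test_no_change_when_silent(self, rng):
        W = rng.standard_normal((3, 6))
        out = update_W(W, np.ones(2), np.zeros(6), rng.standard_normal((2, 3)), LearningParams())
        np.testing.assert_array_equal(out, W)

    def test_matches_finite_difference_gradient(self, rng):
        # kink-free random instances: analytic step vs central differences
        checked = 0
        while checked < 30:
            N, NM = 6, 4
            w = SensoryWeights(rng.standard_normal((N, 2)), rng.standard_normal((N, 2)))
            W = rng.standard_normal((NM, N))
            P = rng.standard_normal((2, NM))
            theta_vec = 0.5 * rng.standard_normal(N)
            v, p = random_unit_pair(rng)
            u = w.J_v @ v + w.J_p @ p - theta_vec
            if np.any(np.abs(u) < 1e-3) or not np.any(u > 0):
                continue
            act = ActivationSpec()
            A = compute_activity(v, p, w, theta_vec, act)
            M, mask = muscle_activity(W, A)
            if np.any(np.abs(W @ A.values) < 1e-3):
                continue
            lam = 0.2
            params = LearningParams(eta=0.9, lam=lam)
            x = P @ M
            e = v - x
            W2 = update_W(W, e, A, masked_projection(P, mask), params)
            analytic = -(W2 - W) / params.eta
            fd = finite_difference_gradient(
                lambda Wx: trial_cost(w.J_v, w.J_p, Wx, v, p, P, theta_vec, act, lam), W
            )
            np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-8)
            checked += 1

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            update_W(np.zeros((3, 6)), np.ones(2), np.ones(6), np.zeros((2, 4)), LearningParams())


class TestUpdateJ:
    def test_threshold_linear_unsupported(self, rng):
        w = sample_sensory_weights(4, 0)
        with pytest.raises(UnsupportedConfigurationError):
            update_J(
                w.J_v, w.J_p, np.zeros((2, 4)),
                np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                rng.standard_normal((2, 2)), np.zeros(4),
                ActivationSpec("threshold_linear"), LearningParams(),
            )

    def test_no_change_when_error_zero(self, rng):
        # choose the target equal to the executed movement so that e = 0
        N, NM = 5, 3
        act = ActivationSpec("tanh_rectified")
        w = SensoryWeights(rng.standard_normal((N, 2)), rng.standard_normal((N, 2)))
        W = rng.standard_normal((NM, N))
        P = rng.standard_normal((2, NM))
        theta_vec = np.zeros(N)
        v, p = random_unit_pair(rng)
        A = compute_activity(v, p, w, theta_vec, act)
        M, _ = muscle_activity(W, A)
        J_v2, J_p2 = update_J(w.J_v, w.J_p, W, P @ M, p, P, theta_vec, act, LearningParams())
        np.testing.assert_array_equal(J_v2, w.J_v)
        np.testing.assert_array_equal(J_p2, w.J_p)

    def test_matches_finite_difference_gradient(self, rng):
        checked = 0
        act = ActivationSpec("tanh_rectified", beta=1.3)
        while checked < 30:
            N, NM = 5, 3
            w = SensoryWeights(rng.standard_normal((N, 2)), rng.standard_normal((N, 2)))
            W = rng.standard_normal((NM, N))
            P = rng.standard_normal((2, NM))
            theta_vec = 0.5 * rng.standard_normal(N)
            v, p = random_unit_pair(rng)
            u = w.J_v @ v + w.J_p @ p - theta_vec
            if np.any(np.abs(u) < 1e-3) or not np.any(np.tanh(act.beta * u) > 0):
                continue
            A = compute_activity(v, p, w, theta_vec, act)
            if np.any(np.abs(W @ A.values) < 1e-3):
                continue
            lam = 0.1
            params = LearningParams(eta=0.5, lam=lam)
            J_v2, J_p2 = update_J(w.J_v, w.J_p, W, v, p, P, theta_vec, act, params)
            analytic_v = -(J_v2 - w.J_v) / params.eta
            analytic_p = -(J_p2 - w.J_p) / params.eta
            fd_v = finite_difference_gradient(
                lambda Jx: trial_cost(Jx, w.J_p, W, v, p, P, theta_vec, act, lam), w.J_v
            )
            fd_p = finite_difference_gradient(
                lambda Jx: trial_cost(w.J_v, Jx, W, v, p, P, theta_vec, act, lam), w.J_p
            )
            np.testing.assert_allclose(analytic_v, fd_v, rtol=1e-4, atol=1e-7)
            np.testing.assert_allclose(analytic_p, fd_p, rtol=1e-4, atol=1e-7)
            checked += 1

    def test_joint_adaptation_descends(self, full_geometry):
        # windowed error after 2,000 trials beats the first 100 trials
        N = 100
        rng = np.random.default_rng(6)
        weights = SensoryWeights(
            0.1 * rng.standard_normal((N, 2)), 0.1 * rng.standard_normal((N, 2))
        )
        coding = CodingLayer(weights, ThresholdSpec(0.0), ActivationSpec("tanh_rectified"))
        mm = MuscleMap.gaussian(full_geometry.muscles.n_muscles, N, 1 / np.sqrt(N), 3)
        params = LearningParams(n_trials=2000, adaptable=("J", "W"))
        result = train(full_geometry, coding, mm, params, seed=8)
        assert result.errors[-200:].mean() < 0.01 * result.errors[:100].mean()


class TestTrain:
    def test_zero_learning_rate_keeps_W_zero(self, tiny_geometry):
        coding = CodingLayer(sample_sensory_weights(10, 0), ThresholdSpec(-1.0))
        result = train(
            tiny_geometry, coding, params=LearningParams(eta=0.0, n_trials=200), seed=1
        )
        np.testing.assert_array_equal(result.W, 0.0)
        np.testing.assert_allclose(result.errors, 1.0)

    def test_silent_network_never_updates(self, tiny_geometry):
        coding = CodingLayer(sample_sensory_weights(10, 0), ThresholdSpec(1e6))
        result = train(tiny_geometry, coding, params=LearningParams(n_trials=100), seed=1)
        np.testing.assert_array_equal(result.W, 0.0)
        np.testing.assert_allclose(result.errors, 1.0)

    def test_same_seed_bit_identical(self, tiny_geometry):
        coding = CodingLayer(sample_sensory_weights(10, 4), ThresholdSpec(0.0))
        a = train(tiny_geometry, coding, params=LearningParams(n_trials=300), seed=5)
        b = train(tiny_geometry, coding, params=LearningParams(n_trials=300), seed=5)
        np.testing.assert_array_equal(a.errors, b.errors)
        np.testing.assert_array_equal(a.W, b.W)

    def test_error_bounded_by_no_learning_baseline(self, tiny_geometry):
        coding = CodingLayer(sample_sensory_weights(50, 7), ThresholdSpec(2.0))
        result = train(tiny_geometry, coding, params=LearningParams(n_trials=2000), seed=8)
        assert result.converged_error <= 1.0
        assert result.converged_error < 1e-6  # tiny sparse task is learnable

    def test_adaptable_J_requires_tanh(self, tiny_geometry):
        coding = CodingLayer(sample_sensory_weights(10, 0), ThresholdSpec(0.0))
        with pytest.raises(UnsupportedConfigurationError):
            train(
                tiny_geometry,
                coding,
                params=LearningParams(n_trials=10, adaptable=("J",)),
                seed=0,
            )

    def test_trace_length(self, tiny_geometry):
        coding = CodingLayer(sample_sensory_weights(10, 0), ThresholdSpec(0.0))
        result = train(tiny_geometry, coding, params=LearningParams(n_trials=123), seed=0)
        assert result.errors.shape == (123,)


class TestConvergedError:
    def test_constant_trace(self):
        errors = np.full(100, 0.25)
        assert converged_error(errors, (1, 100)) == 0.25

    def test_single_trial_window(self, rng):
        errors = rng.uniform(0, 1, 50)
        assert converged_error(errors, (7, 7)) == errors[6]

    def test_matches_direct_mean(self, rng):
        errors = rng.uniform(0, 1, 1000)
        direct = sum(errors[899:]) / 101
        assert abs(converged_error(errors, (900, 1000)) - direct) < 1e-12

    def test_invalid_window(self, rng):
        errors = rng.uniform(0, 1, 10)
        for window in [(0, 5), (5, 3), (1, 11)]:
            with pytest.raises(ValueError):
                converged_error(errors, window)

    def test_default_window_is_final_tenth(self):
        params = LearningParams(n_trials=20_000)
        assert params.window_for(20_000) == (18_001, 20_000)


def test_invalid_learning_params():
    with pytest.raises(ValueError):
        LearningParams(eta=-1.0)
    with pytest.raises(ValueError):
        LearningParams(adaptable=("Q",))
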