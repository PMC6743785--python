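"""Unscented Kalman Filter observer: sigma points, unscented-transform
exactness, gain behavior, and equivalence with the classic Kalman filter
on linear-Gaussian systems."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import speechsfc as s
from speechsfc.observer import (
    AugmentedUKF,
    ObserverState,
    _repair_psd,
    channel_mask,
    sigma_points,
)


def random_psd(rng, n, scale=1.0):
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T + n * np.eye(n))


class TestSigmaPoints:
    def test_count_is_2L_plus_1(self, rng):
        for L in (1, 3, 8):
            P = random_psd(rng, L)
            ss = sigma_points(np.zeros(L), P, lam=3.0 - L)
            assert ss.points.shape == (2 * L + 1, L)

    def test_scalar_closed_form(self):
        """1-dim, P = sigma^2, lambda = 2: points at mu, mu +- sigma sqrt(3)."""
        mu, sig = 1.5, 0.4
        ss = sigma_points(np.array([mu]), np.array([[sig**2]]), lam=2.0)
        np.testing.assert_allclose(
            np.sort(ss.points.ravel()), np.sort([mu, mu + sig * np.sqrt(3), mu - sig * np.sqrt(3)])
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), L=st.integers(1, 10))
    def test_reconstruction_property(self, seed, L):
        """Weighted mean and covariance of the sigma set reproduce the
        inputs to 1e-12 — the defining property of the construction."""
        rngl = np.random.default_rng(seed)
        mean = rngl.normal(size=L)
        P = random_psd(rngl, L)
        ss = sigma_points(mean, P, lam=3.0 - L)
        np.testing.assert_allclose(ss.mean(), mean, atol=1e-12 * max(1, np.abs(mean).max()))
        np.testing.assert_allclose(ss.covariance(), P, atol=1e-10)

    def test_non_psd_rejected_after_repair(self):
        P = np.array([[1.0, 0.0], [0.0, -0.5]])
        with pytest.raises(np.linalg.LinAlgError):
            sigma_points(np.zeros(2), P, lam=1.0)

    def test_roundoff_asymmetry_repaired(self, rng):
        P = random_psd(rng, 4)
        P[0, 1] += 1e-13  # break symmetry at round-off scale
        ss = sigma_points(np.zeros(4), P, lam=-1.0)
        assert np.all(np.isfinite(ss.points))


def _linear_ukf(A, C, Q, R, P0, covariance_update="filtered", alpha=1.0):
    """Augmented UKF on x' = A x + v, y = C x + n."""
    def process_fn(Xs, Xv, u):
        return Xs @ A.T + Xv

    def obs_fn(Xs, Xn):
        return Xs @ C.T + Xn

    return AugmentedUKF(process_fn, obs_fn, Q=Q, R=R, P0=P0,
                        alpha=alpha, covariance_update=covariance_update)


class TestUnscentedTransform:
    def test_linear_process_moments_exact(self, rng):
        """UT through a linear map reproduces the linear-Gaussian
        propagation A P A^T + Q exactly."""
        n = 3
        A = rng.normal(size=(n, n))
        Q = random_psd(rng, n, 0.1)
        R = np.eye(1)
        P = random_psd(rng, n)
        mean = rng.normal(size=n)
        ukf = _linear_ukf(A, np.ones((1, n)), Q, R, P)
        sig = ukf.augmented_sigma(mean, P)
        m_prop, P_prop, _ = ukf.ut_process(sig, None)
        np.testing.assert_allclose(m_prop, A @ mean, atol=1e-10)
        np.testing.assert_allclose(P_prop, A @ P @ A.T + Q, atol=1e-8)

    def test_scalar_quadratic_mean_exact(self):
        """For f(x) = x^2 and x ~ N(mu, sigma^2), the UT mean equals the
        analytic Gaussian moment mu^2 + sigma^2."""
        mu, var = 0.7, 0.3

        def process_fn(Xs, Xv, u):
            return Xs**2 + Xv

        ukf = AugmentedUKF(process_fn, lambda Xs, Xn: Xs + Xn,
                           Q=np.array([[0.0]]), R=np.array([[1.0]]),
                           P0=np.array([[var]]), alpha=1.0)
        sig = ukf.augmented_sigma(np.array([mu]), np.array([[var]]))
        m_prop, _, _ = ukf.ut_process(sig, None)
        assert m_prop[0] == pytest.approx(mu**2 + var, abs=1e-10)

    def test_zero_covariance_collapses_sigma_points(self, rng):
        n = 2
        A = np.eye(n)
        Q = 0.04 * np.eye(n)
        ukf = _linear_ukf(A, np.eye(n), Q, np.eye(n), np.zeros((n, n)))
        sig = ukf.augmented_sigma(np.ones(n), np.zeros((n, n)))
        m, P_prior, X = ukf.ut_process(sig, None)
        # all state sigma points coincide -> prior covariance = process noise only
        np.testing.assert_allclose(P_prior, Q, atol=1e-10)

    def test_identity_observation_covariance_analytic(self, rng):
        """Identity H: P_yy = propagated state covariance + R."""
        n = 2
        P = random_psd(rng, n)
        Q = 0.01 * np.eye(n)
        R = 0.5 * np.eye(n)
        ukf = _linear_ukf(np.eye(n), np.eye(n), Q, R, P)
        sig = ukf.augmented_sigma(np.zeros(n), P)
        _, P_prior, X = ukf.ut_process(sig, None)
        yhat, P_yy, P_ay = ukf.ut_observe(sig, X, np.ones(n, bool))
        np.testing.assert_allclose(P_yy, P_prior + R, atol=1e-8)
        np.testing.assert_allclose(P_ay, P_prior, atol=1e-8)

    def test_pyy_symmetric_psd_over_random_inputs(self, rng):
        n = 3
        A = rng.normal(size=(n, n)) * 0.5
        C = rng.normal(size=(2, n))
        ukf = _linear_ukf(A, C, 0.1 * np.eye(n), 0.2 * np.eye(2), np.eye(n))
        for _ in range(200):
            P = random_psd(rng, n)
            sig = ukf.augmented_sigma(rng.normal(size=n), P)
            _, _, X = ukf.ut_process(sig, None)
            _, P_yy, _ = ukf.ut_observe(sig, X, np.ones(2, bool))
            np.testing.assert_allclose(P_yy, P_yy.T, atol=1e-9)
            assert np.linalg.eigvalsh(P_yy).min() > -1e-9

    def test_channel_masking_removes_rows(self, rng):
        n = 2
        C = np.vstack([np.eye(n), np.ones((1, n))])
        ukf = _linear_ukf(np.eye(n), C, 0.01 * np.eye(n), np.eye(3), np.eye(n))
        sig = ukf.augmented_sigma(np.zeros(n), np.eye(n))
        _, _, X = ukf.ut_process(sig, None)
        mask = np.array([True, False, True])
        yhat, P_yy, P_ay = ukf.ut_observe(sig, X, mask)
        assert yhat.shape == (2,)
        assert P_yy.shape == (2, 2)
        assert P_ay.shape == (n, 2)


class TestGainAndCorrect:
    def test_zero_innovation_leaves_estimate(self, rng):
        n = 2
        P = random_psd(rng, n)
        P_yy = random_psd(rng, n)
        P_ay = rng.normal(size=(n, n)) * 0.1
        a = rng.normal(size=n)
        mean, _, _, _ = AugmentedUKF.gain_and_correct(a, P, P_ay, P_yy, np.zeros(n))
        np.testing.assert_array_equal(mean, a)

    def test_gain_vanishes_as_observation_noise_grows(self, rng):
        """R -> infinity drives K -> 0 and the correction disappears."""
        n = 2
        norms = []
        for r in (1e0, 1e4, 1e8):
            ukf = _linear_ukf(np.eye(n), np.eye(n), 0.01 * np.eye(n), r * np.eye(n), np.eye(n))
            state = ObserverState(np.zeros(n), np.eye(n))
            out = ukf.step(state, None, np.full(n, 5.0), np.ones(n, bool))
            norms.append(out.diagnostics["K_norm"])
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-6

    def test_monotone_auditory_gain_in_noise_estimate(self, trained_map, rng):
        """Scaling the auditory observation-noise estimate up strictly
        shrinks the auditory block of the Kalman gain, across random
        states."""
        prev_norms = None
        for aud_noise in (1e-3, 1e-1, 1e1):
            obs = s.ArticulatoryObserver(trained_map, dt=0.005, aud_noise=aud_noise)
            norms = []
            rngl = np.random.default_rng(5)
            for _ in range(20):
                x = np.concatenate([
                    rngl.uniform(s.kinematics.RANGE_LOW + 0.2, s.kinematics.RANGE_HIGH - 0.2),
                    rngl.normal(scale=0.1, size=10),
                ])
                state = obs.init_state(s.ArticulatoryState.from_vector(x))
                y = obs.ukf.obs_fn(x[None, :], np.zeros((1, 23)))[0]
                out = obs.step(state, np.zeros(10), y, channel_mask("both"))
                K = out.diagnostics["K"]
                norms.append(np.linalg.norm(K[:, 20:]))
            cur = float(np.mean(norms))
            if prev_norms is not None:
                assert cur < prev_norms
            prev_norms = cur


class TestKalmanEquivalence:
    def test_matches_classic_kalman_filter_on_linear_gaussian_system(self, rng):
        """Textbook Kalman filter oracle: on a 2-dim linear-Gaussian
        system the UKF state and covariance track the KF to < 1e-8 over
        500 steps."""
        n, m = 2, 2
        A = np.array([[1.0, 0.1], [0.0, 0.95]])
        C = np.array([[1.0, 0.0], [0.3, 1.0]])
        Q = 0.01 * np.eye(n)
        R = 0.25 * np.eye(m)
        P0 = np.eye(n)
        ukf = _linear_ukf(A, C, Q, R, P0, covariance_update="filtered", alpha=1.0)
        ukf_state = ObserverState(np.zeros(n), P0.copy())
        # oracle
        x_kf = np.zeros(n)
        P_kf = P0.copy()
        x_true = np.array([1.0, -0.5])
        max_diff = 0.0
        for _ in range(500):
            x_true = A @ x_true + rng.multivariate_normal(np.zeros(n), Q)
            y = C @ x_true + rng.multivariate_normal(np.zeros(m), R)
            # classic KF
            x_pred = A @ x_kf
            P_pred = A @ P_kf @ A.T + Q
            S = C @ P_pred @ C.T + R
            K = P_pred @ C.T @ np.linalg.inv(S)
            x_kf = x_pred + K @ (y - C @ x_pred)
            P_kf = P_pred - K @ S @ K.T
            # UKF
            ukf_state = ukf.step(ukf_state, None, y, np.ones(m, bool))
            max_diff = max(max_diff, np.abs(ukf_state.mean - x_kf).max())
            np.testing.assert_allclose(ukf_state.P, P_kf, atol=1e-8)
        assert max_diff < 1e-8

    def test_covariance_stays_psd_over_many_steps(self, rng):
        n = 2
        ukf = _linear_ukf(np.array([[1.0, 0.1], [0.0, 0.9]]), np.eye(n),
                          0.01 * np.eye(n), 0.1 * np.eye(n), np.eye(n),
                          covariance_update="filtered", alpha=1.0)
        state = ObserverState(np.zeros(n), np.eye(n))
        for k in range(10_000):
            y = rng.normal(size=n)
            state = ukf.step(state, None, y, np.ones(n, bool))
            if k % 500 == 0:
                evals = np.linalg.eigvalsh(state.P)
                assert evals.min() > -1e-12
        assert np.all(np.isfinite(state.mean))


class TestSpeechObserver:
    def test_dead_reckoning_with_no_feedback(self, trained_map):
        """An all-false mask reduces the observer to pure efference-copy
        integration."""
        from speechsfc.forward import predict_state
        from speechsfc.kinematics import ArticulatoryState, MotorCommand

        obs = s.ArticulatoryObserver(trained_map, dt=0.005)
        state = obs.init_state(ArticulatoryState.neutral())
        rngl = np.random.default_rng(2)
        est = ArticulatoryState.neutral()
        for _ in range(20):
            u = rngl.normal(scale=3.0, size=10)
            state = obs.step(state, u, None, channel_mask("none"))
            est = predict_state(est, MotorCommand(u), dt=0.005)
        np.testing.assert_allclose(state.mean, est.as_vector(), atol=1e-9)

    def test_mask_shapes_validated(self, trained_map):
        obs = s.ArticulatoryObserver(trained_map, dt=0.005)
        state = obs.init_state(s.ArticulatoryState.neutral())
        with pytest.raises(ValueError):
            obs.step(state, np.zeros(10), np.zeros(23), np.ones(5, bool))
        with pytest.raises(ValueError):
            obs.step(state, np.zeros(10), np.zeros(7), channel_mask("both"))

    def test_f1_shift_moves_estimate_toward_higher_predicted_f1(self, trained_map):
        """A +100 Hz perceived-F1 shift corrects the tongue estimate in
        the direction that raises its predicted F1 (probed at a
        mid-vowel posture where the map carries F1 information)."""
        from speechsfc.kinematics import DEFAULT_GEOMETRY as geom

        obs = s.ArticulatoryObserver(trained_map, dt=0.005)
        a = s.NEUTRAL.copy()
        a[1] = 0.60   # CA: theta = 0.75
        a[2] = geom.outline_radius(0.75) - geom.rt - 0.30  # TBCD = 0.30
        x = s.ArticulatoryState(a, np.zeros(10))
        state = obs.init_state(x)
        y = obs.ukf.obs_fn(x.as_vector()[None, :], np.zeros((1, 23)))[0]
        y_shift = y.copy()
        y_shift[20] += 100.0
        out = obs.step(state, np.zeros(10), y_shift, channel_mask("both"))
        f1_before = trained_map.predict(x.a)[0]
        f1_after = trained_map.predict(out.mean[:10])[0]
        assert f1_after > f1_before

    def test_feedback_condition_masks(self):
        assert channel_mask("both").sum() == 23
        assert channel_mask("somat").sum() == 20
        assert channel_mask("aud").sum() == 3
        assert channel_mask("none").sum() == 0
        with pytest.raises(ValueError):
            channel_mask("banana")

    def test_psd_repair_rejects_badly_indefinite(self):
        with pytest.raises(np.linalg.LinAlgError):
            _repair_psd(np.diag([1.0, -1.0]))
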