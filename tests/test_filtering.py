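import numpy as np
import pytest
from scipy.linalg import expm

from biohekf import (
    FilterConfig,
    InputError,
    LinearConstraintSet,
    MeasurementSeries,
    constrain_estimate,
    extend_state,
    final_estimate,
    kalman_gain,
    linear_output,
    measurement_update,
    run_hekf,
    simulate_measurements,
    time_update,
)
from biohekf.errors import FilterDivergenceError
from biohekf.filtering import FilterStep, FilterTrajectory, default_P0
from biohekf.models import ODEModel

from conftest import make_linear_model


def _cfg(x0, P0, R, **kw):
    kw.setdefault("rtol", 1e-10)
    kw.setdefault("atol", 1e-12)
    kw.setdefault("cov_rtol", 1e-10)
    kw.setdefault("cov_atol", 1e-12)
    return FilterConfig(x0_ext=x0, P0=P0, R=R, **kw)


class TestTimeUpdate:
    def test_constant_dynamics_adds_q_delta(self):
        model = make_linear_model(np.zeros((2, 2)))
        q = 0.3
        ext = extend_state(model, (), {}, linear_output(np.eye(2)), Q=np.full(2, q))
        x0 = np.array([1.0, -2.0])
        P0 = np.diag([2.0, 5.0])
        cfg = _cfg(x0, P0, np.ones(2))
        x1, P1 = time_update(x0, P0, ext, 0.0, 0.7, cfg)
        np.testing.assert_allclose(x1, x0, atol=1e-10)
        np.testing.assert_allclose(P1, P0 + q * 0.7 * np.eye(2), atol=1e-8)

    def test_scalar_closed_form_lyapunov(self):
        # P(t) = e^{2aD} P0 + q (e^{2aD} - 1) / (2a)
        a, D, P0s, q = -1.0, 0.5, 1.0, 0.2
        model = make_linear_model(np.array([[a]]))
        ext = extend_state(model, (), {}, linear_output(np.eye(1)), Q=np.array([q]))
        cfg = _cfg(np.array([1.0]), np.array([[P0s]]), np.ones(1))
        _, P1 = time_update(np.array([1.0]), np.array([[P0s]]), ext, 0.0, D, cfg)
        expected = np.exp(2 * a * D) * P0s + q * (np.exp(2 * a * D) - 1) / (2 * a)
        assert P1[0, 0] == pytest.approx(expected, abs=1e-8)

    def test_zero_q_matches_matrix_exponential(self):
        A = np.array([[-0.2, 0.5], [-0.1, -0.9]])
        model = make_linear_model(A)
        ext = extend_state(model, (), {}, linear_output(np.eye(2)), Q=np.zeros(2))
        P0 = np.array([[2.0, 0.3], [0.3, 1.0]])
        x0 = np.array([1.0, 1.0])
        cfg = _cfg(x0, P0, np.ones(2))
        _, P1 = time_update(x0, P0, ext, 0.0, 0.8, cfg)
        Phi = expm(A * 0.8)
        np.testing.assert_allclose(P1, Phi @ P0 @ Phi.T, atol=1e-8)

    def test_requires_forward_time(self, lti_2d):
        cfg = _cfg(np.zeros(2), np.eye(2), np.ones(2))
        with pytest.raises(InputError):
            time_update(np.zeros(2), np.eye(2), lti_2d["ext"], 1.0, 1.0, cfg)


class TestKalmanGain:
    def test_scalar_half(self):
        K = kalman_gain(np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]]))
        assert K[0, 0] == pytest.approx(0.5)

    def test_distrusted_measurements_zero_gain(self):
        K = kalman_gain(np.array([[1.0]]), np.array([[1.0]]), np.array([[1e12]]))
        assert np.linalg.norm(K) < 1e-10

    def test_defining_identity_random_spd(self, rng):
        M = rng.normal(size=(5, 5))
        P = M @ M.T + 5 * np.eye(5)
        H = rng.normal(size=(2, 5))
        R = np.diag(rng.uniform(0.5, 2.0, size=2))
        K = kalman_gain(P, H, R)
        np.testing.assert_allclose(K @ (H @ P @ H.T + R), P @ H.T, atol=1e-10)

    def test_singular_innovation_raises(self):
        with pytest.raises(FilterDivergenceError):
            kalman_gain(np.zeros((1, 1)), np.array([[1.0]]), np.array([[0.0]]))


class TestMeasurementUpdate:
    def test_zero_innovation_keeps_prior(self, lti_2d):
        cfg = _cfg(np.zeros(2), np.eye(2), np.ones(2))
        x = np.array([1.5, -0.5])
        P = np.eye(2)
        y = x.copy()  # identity output
        x_post, P_post, K, innov = measurement_update(x, P, y, lti_2d["ext"], 0, cfg)
        np.testing.assert_allclose(innov, 0.0, atol=1e-14)
        np.testing.assert_allclose(x_post, x, atol=1e-14)

    def test_scalar_arithmetic(self):
        model = make_linear_model(np.array([[0.0]]))
        ext = extend_state(model, (), {}, linear_output(np.eye(1)), Q=np.zeros(1))
        cfg = _cfg(np.zeros(1), np.eye(1), np.ones(1))
        x_post, P_post, K, innov = measurement_update(
            np.array([0.0]), np.array([[1.0]]), np.array([2.0]), ext, 0, cfg
        )
        assert K[0, 0] == pytest.approx(0.5)
        assert x_post[0] == pytest.approx(1.0)
        assert P_post[0, 0] == pytest.approx(0.5)

    def test_joint_update_matches_conjugate_gaussian_oracle(self, rng):
        # Bayesian linear-Gaussian posterior: precision form
        n = 4
        M = rng.normal(size=(n, n))
        P = M @ M.T + 3 * np.eye(n)
        H = rng.normal(size=(2, n))
        Rd = rng.uniform(0.5, 1.5, size=2)
        x_prior = rng.normal(size=n)
        y = rng.normal(size=2)

        model = make_linear_model(np.zeros((n, n)))
        ext = extend_state(model, (), {}, linear_output(H), Q=np.zeros(n))
        cfg = _cfg(np.zeros(n), np.eye(n), Rd)
        x_post, P_post, _, _ = measurement_update(x_prior, P, y, ext, 0, cfg)

        prec = np.linalg.inv(P) + H.T @ np.diag(1.0 / Rd) @ H
        cov = np.linalg.inv(prec)
        mean = cov @ (np.linalg.inv(P) @ x_prior + H.T @ np.diag(1.0 / Rd) @ y)
        np.testing.assert_allclose(x_post, mean, atol=1e-8)
        np.testing.assert_allclose(P_post, cov, atol=1e-8)

    def test_sequential_masked_differs_from_joint(self, rng):
        n = 3
        P = np.diag([2.0, 1.0, 0.5]) + 0.2
        H = np.array([[1.0, 0.5, 0.0], [0.0, 1.0, 1.0]])
        Rd = np.array([1.0, 0.8])
        x = np.array([0.5, -1.0, 0.2])
        y = np.array([1.0, 0.3])
        model = make_linear_model(np.zeros((n, n)))

        def masked(active):
            out = linear_output(H, mask=lambda k: np.asarray(active, bool))
            return extend_state(model, (), {}, out, Q=np.zeros(n))

        cfg = _cfg(np.zeros(n), np.eye(n), Rd)
        # joint
        xj, _, _, _ = measurement_update(x, P, y, masked([True, True]), 0, cfg)
        # channel 1 only then channel 2 only, both from the same prior
        x1, _, _, _ = measurement_update(x, P, y[:1], masked([True, False]), 0, cfg)
        x2, _, _, _ = measurement_update(x1, P, y[1:], masked([False, True]), 0, cfg)
        assert not np.allclose(xj, x2, atol=1e-6)

    def test_posterior_covariance_not_larger(self, rng):
        n = 4
        M = rng.normal(size=(n, n))
        P = M @ M.T + np.eye(n)
        H = rng.normal(size=(2, n))
        model = make_linear_model(np.zeros((n, n)))
        ext = extend_state(model, (), {}, linear_output(H), Q=np.zeros(n))
        cfg = _cfg(np.zeros(n), np.eye(n), np.ones(2))
        _, P_post, _, _ = measurement_update(
            rng.normal(size=n), P, rng.normal(size=2), ext, 0, cfg
        )
        eigs = np.linalg.eigvalsh(P - P_post)
        assert eigs.min() >= -1e-10


class TestConstrainEstimate:
    def test_feasible_returned_bitwise(self):
        cs = LinearConstraintSet(np.eye(2), np.zeros(2), ">=")
        x = np.array([1.0, 2.0])
        assert constrain_estimate(x, np.eye(2), cs) is x

    def test_scalar_projection_onto_halfline(self):
        cs = LinearConstraintSet(np.eye(1), np.zeros(1), ">=")
        x_c = constrain_estimate(np.array([-1.0]), np.eye(1), cs)
        assert x_c[0] == pytest.approx(0.0, abs=1e-9)

    def test_2d_qp_matches_grid_oracle(self):
        P = np.array([[2.0, 0.5], [0.5, 1.0]])
        x_post = np.array([-1.0, 2.0])
        cs = LinearConstraintSet(np.eye(2), np.zeros(2), ">=")
        x_c = constrain_estimate(x_post, P, cs)
        # brute force over the feasible quadrant
        Pinv = np.linalg.inv(P)
        g1 = np.arange(0.0, 1.0, 1e-3)
        g2 = np.arange(1.0, 3.0, 1e-3)
        X1, X2 = np.meshgrid(g1, g2, indexing="ij")
        D1, D2 = X1 - x_post[0], X2 - x_post[1]
        vals = Pinv[0, 0] * D1**2 + 2 * Pinv[0, 1] * D1 * D2 + Pinv[1, 1] * D2**2
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        np.testing.assert_allclose(x_c, [g1[i], g2[j]], atol=2e-3)

    def test_no_constraints_passthrough(self):
        x = np.array([-5.0, 3.0])
        assert constrain_estimate(x, np.eye(2), None) is x


def _series(times, values, R):
    return MeasurementSeries(times=times, values=values, R=R)


class TestRunHekf:
    def test_linear_gaussian_equivalence_with_discrete_kf(self, rng):
        """HEKF on an LTI system == textbook discrete KF (Van Loan discretization)."""
        A = np.array([[-0.5, 0.2], [0.0, -0.3]])
        qd = np.array([0.04, 0.09])
        model = make_linear_model(A)
        H = np.array([[1.0, 0.0]])
        output = linear_output(H)
        ext = extend_state(model, (), {}, output, Q=qd)
        R = np.array([0.25])
        times = np.array([0.4, 0.9, 1.3, 2.0, 2.6])
        x_true = np.array([2.0, -1.0])
        vals = np.array([[2.1], [0.8], [0.9], [0.2], [0.35]])
        data = _series(times, vals, R)
        x0 = np.array([1.0, 0.0])
        P0 = np.diag([1.0, 2.0])
        cfg = _cfg(x0, P0, R, averaging_window=1)
        traj = run_hekf(ext, data, cfg)

        # independent oracle: exact discretization per interval (Van Loan)
        def discretize(dt):
            n = 2
            Qc = np.diag(qd)
            M = np.zeros((2 * n, 2 * n))
            M[:n, :n] = -A
            M[:n, n:] = Qc
            M[n:, n:] = A.T
            E = expm(M * dt)
            Phi = E[n:, n:].T
            Qd = Phi @ E[:n, n:]
            return Phi, Qd

        x, P = x0.copy(), P0.copy()
        t_prev = 0.0
        for k, t in enumerate(times):
            Phi, Qd = discretize(t - t_prev)
            x = Phi @ x
            P = Phi @ P @ Phi.T + Qd
            S = H @ P @ H.T + np.diag(R)
            K = P @ H.T @ np.linalg.inv(S)
            x = x + (K @ (vals[k] - H @ x))
            P = (np.eye(2) - K @ H) @ P
            step = traj.steps[k]
            np.testing.assert_allclose(step.x_post, x, atol=1e-8)
            np.testing.assert_allclose(step.P_post, P, atol=1e-8)
            t_prev = t

    def test_noise_free_linear_system_recovers_state(self):
        A = np.array([[-0.3, 0.1], [0.05, -0.6]])
        model = make_linear_model(A)
        output = linear_output(np.eye(2))
        ext = extend_state(model, (), {}, output, Q=np.zeros(2))
        from biohekf import uniform_schedule

        x_true = np.array([3.0, 1.0])
        data = simulate_measurements(
            model, x_true, uniform_schedule(25, 8.0, t_start=0.3), output,
            R=np.zeros(2), seed=0, params=np.empty(0),
        )
        data = MeasurementSeries(
            times=data.times, values=data.values, R=np.full(2, 1e-10)
        )
        cfg = _cfg(np.array([1.0, -1.0]), np.eye(2), np.full(2, 1e-10))
        traj = run_hekf(ext, data, cfg)
        x_end = traj.steps[-1].x_constrained
        expected = expm(A * data.times[-1]) @ x_true
        np.testing.assert_allclose(x_end, expected, atol=1e-3)

    def test_noise_free_self_consistency_innovations_small(self, heat_shock_setup):
        s = heat_shock_setup
        data = simulate_measurements(
            s["model"], s["x0"], s["schedule"], s["output"],
            R=np.zeros(2), seed=0,
        )
        data = MeasurementSeries(times=data.times, values=data.values, R=s["R"])
        x0_ext = np.concatenate([s["x0"], [3.0, 3.0]])  # truth
        ext = s["ext"]
        cfg = FilterConfig(
            x0_ext=x0_ext, P0=np.diag(np.full(5, 1e-8)), R=s["R"],
            rtol=1e-8, atol=1e-10, cov_rtol=1e-8, cov_atol=1e-10,
        )
        traj = run_hekf(ext, data, cfg)
        for step in traj.steps:
            assert np.all(np.abs(step.innovation) < 1e-3)

    def test_heat_shock_two_parameter_recovery_single_seed(self, heat_shock_setup, heat_shock_data):
        s = heat_shock_setup
        traj = run_hekf(s["ext"], heat_shock_data, s["cfg"])
        assert not traj.diverged
        np.testing.assert_allclose(traj.final_params, [3.0, 3.0], rtol=0.10)

    def test_covariance_order_and_constraints_every_step(self, heat_shock_setup, heat_shock_data):
        s = heat_shock_setup
        traj = run_hekf(s["ext"], heat_shock_data, s["cfg"])
        for step in traj.steps:
            eigs = np.linalg.eigvalsh(step.P_prior - step.P_post)
            assert eigs.min() >= -1e-10 * max(1.0, abs(eigs.max()))
            assert np.all(step.x_constrained >= -1e-9)

    def test_without_constraints_bitwise_passthrough(self, lti_2d):
        data = _series(
            np.array([0.5, 1.0]), np.array([[0.4, 0.1], [0.2, 0.05]]), np.ones(2)
        )
        cfg = _cfg(np.array([1.0, 1.0]), np.eye(2), np.ones(2), averaging_window=1)
        traj = run_hekf(lti_2d["ext"], data, cfg)
        for step in traj.steps:
            assert step.x_constrained is step.x_post

    def test_non_monotone_times_raise(self, lti_2d):
        with pytest.raises(InputError):
            _series(np.array([1.0, 1.0]), np.ones((2, 2)), np.ones(2))

    def test_window_larger_than_series_raises(self, lti_2d):
        data = _series(np.array([0.5]), np.array([[0.4, 0.1]]), np.ones(2))
        cfg = _cfg(np.ones(2), np.eye(2), np.ones(2), averaging_window=10)
        with pytest.raises(InputError):
            run_hekf(lti_2d["ext"], data, cfg)

    def test_divergence_flagged_with_partial_trajectory(self):
        model = ODEModel(
            n_states=1,
            rhs=lambda x, u, t, p: np.array([x[0] ** 2]),
            param_names=(),
            default_params={},
        )
        ext = extend_state(model, (), {}, linear_output(np.eye(1)), Q=np.zeros(1))
        data = _series(
            np.array([0.5, 5.0, 6.0]), np.array([[2.0], [1.0], [1.0]]), np.ones(1)
        )
        cfg = _cfg(np.array([1.0]), np.eye(1), np.ones(1), averaging_window=1)
        traj = run_hekf(ext, data, cfg)
        assert traj.diverged
        assert len(traj.steps) == 1
        assert "step" in traj.divergence_message


class TestFinalEstimate:
    def _traj(self, track):
        steps = [
            FilterStep(
                k=i, t=float(i), x_prior=np.zeros(1), x_post=np.zeros(1),
                x_constrained=np.array([0.0, v]), P_prior=np.eye(2), P_post=np.eye(2),
            )
            for i, v in enumerate(track)
        ]
        return FilterTrajectory(steps=steps, final_params=None, n_states=1)

    def test_constant_track(self):
        assert final_estimate(self._traj([4.2] * 12), 10)[0] == pytest.approx(4.2)

    def test_arithmetic_sequence(self):
        assert final_estimate(self._traj(range(1, 21)), 10)[0] == pytest.approx(15.5)

    def test_window_equals_length(self):
        assert final_estimate(self._traj(range(1, 21)), 20)[0] == pytest.approx(10.5)

    @pytest.mark.parametrize("window", [0, 21])
    def test_invalid_window_raises(self, window):
        with pytest.raises(InputError):
            final_estimate(self._traj(range(1, 21)), window)


class TestFilterConfigValidation:
    def test_asymmetric_p0_raises(self):
        with pytest.raises(Exception):
            FilterConfig(
                x0_ext=np.zeros(2),
                P0=np.array([[1.0, 0.5], [0.0, 1.0]]),
                R=np.ones(1),
            )

    def test_nonpositive_r_raises(self):
        with pytest.raises(Exception):
            FilterConfig(x0_ext=np.zeros(2), P0=np.eye(2), R=np.array([1.0, 0.0]))

    def test_default_p0(self):
        P0 = default_P0(np.array([0.1, -5.0]))
        np.testing.assert_allclose(np.diag(P0), [1.0, 25.0])
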