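"""Cyclic state-space model and unscented Kalman filter/smoother."""

import numpy as np
import pytest
from scipy.stats import chi2

from cardiofuse import dynamics as dyn
from cardiofuse.dynamics import (CyclicState, ModelSpec, build_process_noise,
                                 init_state, measure, propagate,
                                 transition_block, ukf_filter, uks_smooth)


def blkdiag_F(omega, T):
    F = np.zeros((10, 10))
    Fb = transition_block(omega, T)
    for a in range(3):
        F[3 * a:3 * a + 3, 3 * a:3 * a + 3] = Fb
    F[9, 9] = 1.0
    return F


class TestTransitionBlock:
    def test_full_period_is_identity(self):
        F = transition_block(2 * np.pi, 1.0)
        assert np.allclose(F, np.eye(3), atol=1e-12)

    def test_zero_frequency_constant_velocity_limit(self):
        T = 0.04
        F0 = transition_block(0.0, T)
        assert np.allclose(F0, [[1, 0, 0], [0, 1, T], [0, 0, 1]])
        # approach of the limit for small but nonzero frequency
        Feps = transition_block(1e-6, T)
        assert np.allclose(Feps, F0, atol=1e-6)

    def test_half_period_reflects_about_mean(self):
        F = transition_block(np.pi, 1.0)
        assert np.allclose(F, [[1, 0, 0], [2, -1, 0], [0, 0, -1]], atol=1e-12)

    @pytest.mark.parametrize("omega,T", [(7.5, 0.04), (2.0, 0.3), (0.3, 1.0)])
    def test_unit_determinant_and_rotation_eigenvalues(self, omega, T):
        F = transition_block(omega, T)
        assert abs(abs(np.linalg.det(F)) - 1.0) < 1e-9
        ev = np.sort_complex(np.linalg.eigvals(F))
        expected = np.sort_complex(np.array(
            [1.0, np.exp(1j * omega * T), np.exp(-1j * omega * T)]))
        assert np.allclose(ev, expected, atol=1e-9)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            transition_block(1.0, 0.0)


class TestPropagate:
    def test_equilibrium_is_fixed_point(self):
        s = np.array([1, 1, 0, -2, -2, 0, 5, 5, 0, 3.0])
        assert np.allclose(propagate(s, 0.1), s, atol=1e-12)

    def test_periodicity_of_pure_oscillator(self):
        omega = 2 * np.pi
        n, T = 16, 1.0 / 16
        s = np.array([0, 2.5, 0, 0, 0, 0, 0, 0, 0, omega])
        for _ in range(n):
            s = propagate(s, T)
        assert np.allclose(s[:3], [0, 2.5, 0], atol=1e-9)

    def test_matches_direct_formula(self, rng):
        s = rng.normal(size=10)
        s[9] = 5.0
        assert np.allclose(propagate(s, 0.07), blkdiag_F(5.0, 0.07) @ s,
                           atol=1e-12)

    def test_oscillator_invariant_conserved(self):
        # omega^2 (x - x_mean)^2 + x_dot^2 is constant under the dynamics
        omega, T = 7.54, 0.013
        s = np.array([1.0, 4.0, -6.0, 0, 1, 2, -3, 0, 5, omega])
        inv0 = omega ** 2 * (s[1] - s[0]) ** 2 + s[2] ** 2
        for _ in range(1000):
            s = propagate(s, T)
        inv1 = omega ** 2 * (s[1] - s[0]) ** 2 + s[2] ** 2
        assert abs(inv1 - inv0) < 1e-9 * inv0


class TestMeasure:
    def test_position_selector(self):
        s = np.array([0, 1, 2, 0, 3, 4, 0, 5, 6, 1.0])
        assert np.allclose(measure(s), [1, 3, 5])

    def test_commutes_at_equilibrium(self):
        s = np.array([1, 1, 0, 2, 2, 0, 3, 3, 0, 2.0])
        assert np.allclose(measure(propagate(s, 0.1)), measure(s))

    def test_random_state_indexing(self, rng):
        s = rng.normal(size=10)
        s[9] = 1.0
        assert np.allclose(measure(s), s[[1, 4, 7]])


def _linear_kf_rts(Z, F, Q, R, m0, P0):
    """Classical Kalman filter + RTS smoother oracle (frozen transition)."""
    H = dyn.H
    I = np.eye(10)

    def upd(m, P, z):
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        return m + K @ (z - H @ m), (I - K @ H) @ P @ (I - K @ H).T + K @ R @ K.T

    m, P = upd(m0, P0, Z[0])
    filt, preds = [(m, P)], []
    for k in range(1, len(Z)):
        mp, Pp = F @ m, F @ P @ F.T + Q
        preds.append((mp, Pp))
        m, P = upd(mp, Pp, Z[k])
        filt.append((m, P))
    sm = [None] * len(Z)
    sm[-1] = filt[-1]
    for k in range(len(Z) - 2, -1, -1):
        mf, Pf = filt[k]
        mp, Pp = preds[k]
        G = Pf @ F.T @ np.linalg.pinv(Pp)
        sm[k] = (mf + G @ (sm[k + 1][0] - mp),
                 Pf + G @ (sm[k + 1][1] - Pp) @ G.T)
    return filt, sm


def _frozen_omega_setup(seed=3, K=25):
    rng = np.random.default_rng(seed)
    omega, T = 2 * np.pi * 1.2, 0.05
    F = blkdiag_F(omega, T)
    Q = build_process_noise(T)
    Q[9, 9] = 0.0
    R = np.eye(3) * 0.25
    s0 = np.array([0, 3, 0, 0, 0, 5, 10, 10, 0, omega])
    truth = [s0]
    for _ in range(K - 1):
        truth.append(F @ truth[-1])
    Z = np.array([measure(s) + rng.normal(0, 0.5, 3) for s in truth])
    P0 = np.diag([4, 4, 100.0] * 3 + [0.0])
    init = CyclicState(s=s0 + np.r_[rng.normal(0, 0.5, 9), 0.0], P=P0)
    model = ModelSpec(T=T, Q=Q, R=R)
    return Z, F, model, init, np.array(truth)


class TestUnscentedFilter:
    def test_linear_kf_oracle_frozen_omega(self):
        # UT is exact for linear models: with zero omega variance the UKF
        # must coincide with a classical Kalman filter
        Z, F, model, init, _ = _frozen_omega_setup()
        filt = ukf_filter(Z, model, init)
        oracle, _ = _linear_kf_rts(Z, F, model.Q, model.R, init.s, init.P)
        for k in range(len(Z)):
            assert np.allclose(filt[k].s, oracle[k][0], atol=1e-6)
            assert np.allclose(filt[k].P, oracle[k][1], atol=1e-6)

    def test_noise_free_self_consistency(self):
        omega, T, K = 6.0, 0.05, 12
        s0 = np.array([0, 3, 0, 1, 1, 2, -2, 0, 4, omega])
        s, truth = s0.copy(), [s0]
        for _ in range(K - 1):
            s = propagate(s, T)
            truth.append(s)
        truth = np.array(truth)
        Z = truth[:, [1, 4, 7]]
        eps = 1e-9
        model = ModelSpec(T=T, Q=np.eye(10) * eps, R=np.eye(3) * eps)
        init = CyclicState(s=s0, P=np.eye(10) * 1e-6)
        filt = ukf_filter(Z, model, init)
        for k in range(3, K):
            assert np.allclose(filt[k].position, Z[k], atol=1e-3)

    def test_stationary_observation_converges_to_equilibrium(self):
        T = 0.05
        z = np.array([4.0, -2.0, 7.0])
        Z = np.tile(z, (40, 1))
        model = ModelSpec.default(T, r=0.01)
        s0 = np.zeros(10)
        s0[9] = 6.0
        init = CyclicState(s=s0, P=np.diag([25.0] * 9 + [1.0]))
        filt = ukf_filter(Z, model, init)
        last = filt[-1]
        assert np.allclose(last.position, z, atol=0.05)
        assert np.all(np.abs(last.s[[2, 5, 8]]) < 0.5)

    def test_covariances_symmetric_psd(self):
        Z, _, model, init, _ = _frozen_omega_setup(seed=9)
        for st in ukf_filter(Z, model, init):
            assert np.allclose(st.P, st.P.T)
            assert np.linalg.eigvalsh(st.P).min() > -1e-9 * np.trace(st.P)


class TestUnscentedSmoother:
    def test_linear_rts_oracle_frozen_omega(self):
        Z, F, model, init, _ = _frozen_omega_setup()
        sm = uks_smooth(Z, model, init)
        _, oracle = _linear_kf_rts(Z, F, model.Q, model.R, init.s, init.P)
        for k in range(len(Z)):
            assert np.allclose(sm[k].s, oracle[k][0], atol=1e-6)
            assert np.allclose(sm[k].P, oracle[k][1], atol=1e-6)

    def test_omega_recovery_noise_free(self):
        from cardiofuse.phantom import PhantomSpec, make_motion
        spec = PhantomSpec(K=20)
        gt = make_motion(spec)
        obs = gt.positions[10]
        init, T = init_state(obs, spec.heart_rate_bpm)
        # start from a misspecified frequency: the data must pull it back
        s = init.s.copy()
        s[9] = 1.15 * gt.omega
        sm = uks_smooth(obs, ModelSpec.default(T, r=0.25),
                        CyclicState(s=s, P=init.P))
        w_est = np.mean([st.omega for st in sm])
        assert abs(w_est - gt.omega) / gt.omega < 0.05

    def test_constant_track_velocities_vanish(self):
        T, K = 0.05, 20
        Z = np.tile([3.0, -1.0, 2.0], (K, 1))
        init, _ = init_state(Z, heart_rate_bpm=60.0)
        model = ModelSpec(T=T, Q=np.zeros((10, 10)), R=np.eye(3) * 1e-12)
        sm = uks_smooth(Z, model, init)
        for st in sm:
            assert np.all(np.abs(st.s[[2, 5, 8]]) < 1e-6)

    def test_smoothing_never_inflates_covariance(self):
        Z, _, model, init, _ = _frozen_omega_setup(seed=5)
        filt = ukf_filter(Z, model, init)
        sm = uks_smooth(Z, model, init)
        for k in range(len(Z)):
            assert np.trace(sm[k].P) <= np.trace(filt[k].P) + 1e-9

    def test_position_nees_calibrated(self):
        # 200 Monte-Carlo tracks generated by the model itself: the pooled
        # normalized estimation error squared of the three positions at the
        # middle frame must lie in the 95% chi-square band
        rng = np.random.default_rng(7)
        T, K, n_runs = 0.05, 20, 200
        Q = build_process_noise(T, q_pos=1.0, q_omega=1e-2)
        R = np.eye(3) * 0.25
        P0 = np.diag([4, 1, 25.0] * 3 + [0.1])
        m0 = np.array([0, 2, 0, 0, 0, 10, 5, 5, 0, 7.5])
        model = ModelSpec(T=T, Q=Q, R=R)
        Lq = np.linalg.cholesky(Q + 1e-12 * np.eye(10))
        L0 = np.linalg.cholesky(P0)
        pos = [1, 4, 7]
        nees = []
        for _ in range(n_runs):
            s = m0 + L0 @ rng.normal(size=10)
            s[9] = abs(s[9])
            xs = [s.copy()]
            for _ in range(K - 1):
                s = propagate(s, T) + Lq @ rng.normal(size=10)
                s[9] = abs(s[9])
                xs.append(s.copy())
            Z = np.array([measure(x) + rng.normal(0, 0.5, 3) for x in xs])
            sm = uks_smooth(Z, model, CyclicState(s=m0, P=P0))
            k = K // 2
            e = sm[k].s[pos] - xs[k][pos]
            nees.append(e @ np.linalg.solve(sm[k].P[np.ix_(pos, pos)], e))
        total = float(np.sum(nees))
        df = 3 * n_runs
        assert chi2.ppf(0.025, df) < total < chi2.ppf(0.975, df)


class TestInitState:
    def test_interval_and_frequency_arithmetic(self):
        traj = np.zeros((20, 3))
        traj[:, 0] = np.linspace(0, 1, 20)
        st, T = init_state(traj, heart_rate_bpm=60.0)
        assert T == pytest.approx(0.05)
        assert st.omega == pytest.approx(2 * np.pi)

    def test_constant_trajectory(self):
        traj = np.tile([1.0, 2.0, 3.0], (10, 1))
        st, T = init_state(traj, heart_rate_bpm=75.0)
        assert np.allclose(st.mean_position, [1, 2, 3])
        assert np.allclose(st.position, [1, 2, 3])
        assert np.allclose(st.s[[2, 5, 8]], 0.0)

    def test_sinusoid_mean_within_quadrature_error(self):
        K, A = 25, 3.0
        t = np.arange(K) / K
        traj = np.zeros((K, 3))
        traj[:, 1] = 5.0 + A * np.cos(2 * np.pi * t)
        st, _ = init_state(traj, heart_rate_bpm=60.0)
        assert abs(st.s[3] - 5.0) <= A / K

    def test_invalid_heart_rate(self):
        with pytest.raises(ValueError):
            init_state(np.zeros((5, 3)), heart_rate_bpm=0.0)
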