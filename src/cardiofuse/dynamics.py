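"""Cyclic-motion state-space model and unscented Kalman filtering/smoothing.

Each myocardial point is modelled as three independent harmonic oscillators
(one per patient axis) sharing a single, slowly varying angular frequency.
The 10-dimensional state is

    s = [x_bar, x, x_dot, y_bar, y, y_dot, z_bar, z, z_dot, omega]

with per-axis mean position (mm), instantaneous position (mm) and velocity
(mm/s), plus the angular frequency omega (rad/s).  Over one frame interval
``T`` an oscillator with frequency ``omega`` advances by the block

    F = [[1,               0,              0             ],
         [1 - cos(wT),     cos(wT),        sin(wT)/w     ],
         [w sin(wT),      -w sin(wT),      cos(wT)       ]]

acting on (mean, position, velocity); the full transition is
blkdiag(F, F, F, 1).  Because ``F`` depends on the state's own omega the
model is nonlinear, and the unscented Kalman filter (UKF) plus its
fixed-interval Rauch-Tung-Striebel smoother (UKS) are used for estimation.
Only the three positions are observed, with isotropic noise by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.linalg import cholesky, solve

__all__ = [
    "CyclicState",
    "ModelSpec",
    "Observation",
    "transition_block",
    "build_process_noise",
    "propagate",
    "measure",
    "ukf_filter",
    "uks_smooth",
    "init_state",
    "NumericalFailure",
]

STATE_DIM = 10
POS_IDX = np.array([1, 4, 7])  # observed components (x, y, z)
H = np.zeros((3, STATE_DIM))
H[np.arange(3), POS_IDX] = 1.0


class NumericalFailure(RuntimeError):
    """Covariance lost positive-definiteness beyond jitter repair."""


@dataclass
class CyclicState:
    """State mean ``s`` (10,) and covariance ``P`` (10, 10)."""

    s: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.s.shape != (STATE_DIM,) or self.P.shape != (STATE_DIM, STATE_DIM):
            raise ValueError("state must be 10-vector with 10x10 covariance")
        if not np.allclose(self.P, self.P.T, atol=1e-8 * (1 + abs(np.trace(self.P)))):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(0.5 * (self.P + self.P.T))
        if w.min() < -1e-9 * max(np.trace(self.P), 1.0):
            raise ValueError("covariance must be positive semi-definite")
        if self.s[9] <= 0:
            raise ValueError("angular frequency must be positive")

    @property
    def position(self) -> np.ndarray:
        return self.s[POS_IDX]

    @property
    def mean_position(self) -> np.ndarray:
        """Per-axis mean positions over the beat (elements 0, 3, 6): the
        anatomical location of the tissue point."""
        return self.s[POS_IDX - 1]

    @property
    def omega(self) -> float:
        return float(self.s[9])


@dataclass
class ModelSpec:
    """Frame interval, noise covariances and sigma-point parameters.

    ``Q`` is the 10x10 process-noise covariance and ``R`` the 3x3
    measurement-noise covariance (isotropic ``diag([r, r, r])`` by default;
    a full 3x3 matrix may be supplied, e.g. to inflate the through-plane
    direction of a single view).
    """

    T: float
    Q: np.ndarray
    R: np.ndarray
    sigma_params: tuple[float, float, float] = (0.1, 2.0, 0.0)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("frame interval T must be positive")
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.Q.shape != (STATE_DIM, STATE_DIM) or self.R.shape != (3, 3):
            raise ValueError("Q must be 10x10 and R 3x3")

    @classmethod
    def default(cls, T: float, *, r: float | None = None,
                pixel_spacing_mm: float = 1.5, q_pos: float = 1.0,
                q_mean_scale: float = 1e-4, q_omega: float = 1e-2,
                sigma_params=(0.1, 2.0, 0.0)) -> "ModelSpec":
        """Build a spec with the white-noise-jerk process noise structure.

        Per axis the (position, velocity) pair receives the continuous
        white-noise-acceleration block scaled by ``q_pos`` (mm^2/s^3), the
        mean position a small random-walk variance ``q_mean_scale * q_pos``,
        and omega a random walk of intensity ``q_omega`` (rad^2/s^3).  The
        default measurement variance is half a pixel of tracking noise,
        ``r = (0.5 * pixel_spacing_mm)**2``.
        """
        Q = build_process_noise(T, q_pos=q_pos, q_mean_scale=q_mean_scale,
                                q_omega=q_omega)
        if r is None:
            r = (0.5 * pixel_spacing_mm) ** 2
        return cls(T=T, Q=Q, R=np.eye(3) * r, sigma_params=sigma_params)


def build_process_noise(T: float, q_pos: float = 1.0,
                        q_mean_scale: float = 1e-4,
                        q_omega: float = 1e-2) -> np.ndarray:
    """10x10 process noise: white-noise acceleration per axis + omega walk."""
    blk = np.array([
        [q_mean_scale * q_pos * T, 0.0, 0.0],
        [0.0, q_pos * T ** 3 / 3.0, q_pos * T ** 2 / 2.0],
        [0.0, q_pos * T ** 2 / 2.0, q_pos * T],
    ])
    Q = np.zeros((STATE_DIM, STATE_DIM))
    for a in range(3):
        Q[3 * a:3 * a + 3, 3 * a:3 * a + 3] = blk
    Q[9, 9] = q_omega * T
    return Q


@dataclass(frozen=True)
class Observation:
    """A 3D position measurement (mm) at frame ``k`` (zero-based)."""

    z: np.ndarray
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        if self.z.shape != (3,) or not np.all(np.isfinite(self.z)):
            raise ValueError("observation must be a finite 3-vector")


# ---------------------------------------------------------------------------
# Transition / measurement models

def transition_block(omega: float, T: float) -> np.ndarray:
    """Per-axis 3x3 transition over interval ``T`` for frequency ``omega``.

    Acts on (mean, position, velocity).  For ``omega*T`` below 1e-8 the
    constant-velocity limit ``[[1,0,0],[0,1,T],[0,0,1]]`` is returned.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    wT = omega * T
    if wT < 1e-8:
        return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, T], [0.0, 0.0, 1.0]])
    c, s = np.cos(wT), np.sin(wT)
    return np.array([
        [1.0, 0.0, 0.0],
        [1.0 - c, c, s / omega],
        [omega * s, -omega * s, c],
    ])


def propagate(s: np.ndarray, T: float) -> np.ndarray:
    """Advance a 10-vector one frame: blkdiag(F, F, F, 1) with F = F(s[9])."""
    s = np.asarray(s, dtype=float)
    F = transition_block(abs(float(s[9])), T)
    out = np.empty_like(s)
    for a in range(3):
        out[3 * a:3 * a + 3] = F @ s[3 * a:3 * a + 3]
    out[9] = s[9]
    return out


def measure(s: np.ndarray) -> np.ndarray:
    """Observed quantities: the three positions (elements 1, 4, 7)."""
    return np.asarray(s, dtype=float)[POS_IDX]


# ---------------------------------------------------------------------------
# Unscented transform machinery

def _ut_weights(n: int, alpha: float, beta: float, kappa: float):
    lam = alpha ** 2 * (n + kappa) - n
    c = n + lam
    wm = np.full(2 * n + 1, 1.0 / (2.0 * c))
    wc = wm.copy()
    wm[0] = lam / c
    wc[0] = lam / c + (1.0 - alpha ** 2 + beta)
    return wm, wc, np.sqrt(c)


def _safe_cholesky(P: np.ndarray, where: str) -> np.ndarray:
    """Matrix square root L with L L^T = P, tolerant of semi-definiteness.

    Cholesky when positive definite; an eigendecomposition square root when
    merely PSD (e.g. a state component deliberately frozen to zero
    variance); symmetrize-and-jitter repair, at most 3 attempts, when
    slightly indefinite from roundoff.
    """
    P = 0.5 * (P + P.T)
    tol = 1e-9 * max(np.trace(P), 1.0)
    try:
        return cholesky(P)
    except np.linalg.LinAlgError:
        pass
    w, V = np.linalg.eigh(P)
    if w.min() >= -tol:
        return V * np.sqrt(np.clip(w, 0.0, None))
    jitter = tol
    for _ in range(3):
        P = P + jitter * np.eye(P.shape[0])
        try:
            return cholesky(P)
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalFailure(f"covariance not positive definite at {where}")


def _sigma_points(m: np.ndarray, P: np.ndarray, scale: float,
                  where: str) -> np.ndarray:
    L = _safe_cholesky(P, where)
    pts = np.empty((2 * STATE_DIM + 1, STATE_DIM))
    pts[0] = m
    pts[1:STATE_DIM + 1] = m + scale * L.T
    pts[STATE_DIM + 1:] = m - scale * L.T
    # frequency sign is unidentifiable: reflect negative omega about zero
    pts[:, 9] = np.abs(pts[:, 9])
    return pts


def _predict(m, P, model: ModelSpec, where: str):
    """UT prediction through the transition; returns pred mean/cov and the
    filtered-to-predicted cross-covariance needed by the RTS pass."""
    alpha, beta, kappa = model.sigma_params
    wm, wc, scale = _ut_weights(STATE_DIM, alpha, beta, kappa)
    chi = _sigma_points(m, P, scale, where)
    chi_prop = np.array([propagate(x, model.T) for x in chi])
    m_pred = wm @ chi_prop
    d_prop = chi_prop - m_pred
    d_prev = chi - m
    P_pred = (wc[:, None] * d_prop).T @ d_prop + model.Q
    P_pred = 0.5 * (P_pred + P_pred.T)
    C = (wc[:, None] * d_prev).T @ d_prop  # Cov(s_k, s_{k+1})
    return m_pred, P_pred, C


def _update(m_pred, P_pred, z, R):
    """Linear Kalman update (the measurement model is exactly linear)."""
    S = H @ P_pred @ H.T + R
    K = solve(S.T, (P_pred @ H.T).T).T
    m = m_pred + K @ (z - H @ m_pred)
    IKH = np.eye(STATE_DIM) - K @ H
    P = IKH @ P_pred @ IKH.T + K @ R @ K.T  # Joseph form
    return m, 0.5 * (P + P.T)


def _as_obs_array(observations) -> np.ndarray:
    if isinstance(observations, np.ndarray):
        Z = np.asarray(observations, dtype=float)
    else:
        obs = list(observations)
        if obs and isinstance(obs[0], Observation):
            order = np.argsort([o.k for o in obs])
            Z = np.array([obs[i].z for i in order], dtype=float)
        else:
            Z = np.asarray(obs, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 3:
        raise ValueError("observations must be K x 3")
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return Z


def ukf_filter(observations, model: ModelSpec, init: CyclicState,
               _return_internals: bool = False):
    """Forward unscented Kalman filter.

    ``observations`` is a K x 3 array (or list of :class:`Observation`)
    of 3D positions, time-ordered and uniformly spaced by ``model.T``.
    The first observation is assimilated into the initial state directly.
    Returns a list of K filtered :class:`CyclicState`.
    """
    Z = _as_obs_array(observations)
    K_frames = Z.shape[0]
    m, P = init.s.copy(), init.P.copy()
    m, P = _update(m, P, Z[0], model.R)
    filtered = [(m, P)]
    preds, crosses = [], []
    for k in range(1, K_frames):
        m_pred, P_pred, C = _predict(m, P, model, where=f"frame {k}")
        preds.append((m_pred, P_pred))
        crosses.append(C)
        m, P = _update(m_pred, P_pred, Z[k], model.R)
        filtered.append((m, P))
    states = []
    for mm, PP in filtered:
        mm = mm.copy()
        mm[9] = abs(mm[9])
        states.append(CyclicState(s=mm, P=PP))
    if _return_internals:
        return states, preds, crosses
    return states


def uks_smooth(observations, model: ModelSpec, init: CyclicState):
    """Fixed-interval unscented Rauch-Tung-Striebel smoother.

    Runs :func:`ukf_filter` forward then recurses backward

        G_k = C_k P_pred(k+1)^{-1}
        s_k <- s_k + G_k (s_{k+1}^smooth - s_pred(k+1))
        P_k <- P_k + G_k (P_{k+1}^smooth - P_pred(k+1)) G_k^T

    so every state uses the full observation record.  Smoothing never
    increases the covariance trace relative to the filter.
    """
    filtered, preds, crosses = ukf_filter(observations, model, init,
                                          _return_internals=True)
    K_frames = len(filtered)
    sm = [None] * K_frames
    sm[-1] = (filtered[-1].s.copy(), filtered[-1].P.copy())
    for k in range(K_frames - 2, -1, -1):
        m_f, P_f = filtered[k].s, filtered[k].P
        m_pred, P_pred = preds[k]
        G = solve(P_pred.T, crosses[k].T).T
        m_next, P_next = sm[k + 1]
        m_s = m_f + G @ (m_next - m_pred)
        P_s = P_f + G @ (P_next - P_pred) @ G.T
        sm[k] = (m_s, 0.5 * (P_s + P_s.T))
    out = []
    for m_s, P_s in sm:
        m_s = m_s.copy()
        m_s[9] = abs(m_s[9])
        out.append(CyclicState(s=m_s, P=P_s))
    return out


def init_state(trajectory_3d, heart_rate_bpm: float, K: int | None = None, *,
               p_mean: float = 4.0, p_pos: float = 4.0, p_vel: float = 100.0,
               omega_rel_sd: float = 0.2) -> tuple[CyclicState, float]:
    """Initial state and frame interval from a raw 3D trajectory.

    Mean positions are the temporal means of the trajectory (the full record
    is available retrospectively), positions the first-frame values,
    velocities the first forward difference divided by ``T``, and the
    frequency prior is one oscillation per beat, ``omega0 = 2*pi*HR/60``.
    ``T`` is the beat duration divided by the frame count,
    ``T = (60/heart_rate_bpm)/K``.

    The initial covariance is diagonal: ``p_mean``/``p_pos`` mm^2 on mean
    and instantaneous positions, ``p_vel`` (mm/s)^2 on velocities and a
    relative standard deviation ``omega_rel_sd`` on omega.

    Returns ``(state, T)``.
    """
    traj = np.asarray(trajectory_3d, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3 or traj.shape[0] < 3:
        raise ValueError("trajectory must be K x 3 with K >= 3")
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be positive")
    K = traj.shape[0] if K is None else int(K)
    T = (60.0 / heart_rate_bpm) / K
    omega0 = 2.0 * np.pi * heart_rate_bpm / 60.0
    mean = traj.mean(axis=0)
    vel = (traj[1] - traj[0]) / T
    s = np.empty(STATE_DIM)
    for a in range(3):
        s[3 * a:3 * a + 3] = (mean[a], traj[0, a], vel[a])
    s[9] = omega0
    P = np.diag([p_mean, p_pos, p_vel] * 3 + [(omega_rel_sd * omega0) ** 2])
    return CyclicState(s=s, P=P), T
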