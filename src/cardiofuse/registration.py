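"""Diffeomorphic moving-mesh registration between adjacent cine frames.

The transformation between two frames is parameterized by a *monitor
function* ``mu`` (the prescribed Jacobian determinant of the map, a
positive field of mean 1) and the curl ``gamma`` of an end velocity field.
Given (mu, gamma) the map is constructed in three steps:

1. solve the div-curl system  div rho = mu - 1,  curl rho = gamma,
   rho = 0 on the domain boundary;
2. form the time-dependent velocity  nu_t(x) = rho(x) / (t + (1-t) mu(x));
3. integrate  d psi/dt = nu_t(psi),  psi(x, 0) = x  over t in [0, 1]
   and set  phi = psi(., 1).

By construction the Jacobian determinant of ``phi`` equals ``mu``; keeping
``mu`` positive (clamped to [0.5, 2] here) therefore guarantees a
diffeomorphism — the property that makes the moving-mesh approach suitable
for tracking tissue, where folding is non-physical.  Registration minimizes
the L2 image dissimilarity over (mu, gamma) by gradient descent with step
halving on a coarse-to-fine pyramid; accepted iterates never increase the
energy.

Conventions: images are (H, W) arrays indexed [row, col] = [j, i]; point
and vector-field components are ordered (x, y) = (col, row), matching the
(i, j) pixel convention of the geometry module.  Fields are stored as
(2, H, W) arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter, map_coordinates, zoom
from scipy.sparse.linalg import splu

logger = logging.getLogger(__name__)

__all__ = [
    "MonitorField",
    "DeformationField",
    "FramePair",
    "RegistrationOptions",
    "solve_div_curl",
    "velocity_at",
    "integrate_flow",
    "register_pair",
    "track_points",
    "divergence",
    "curl",
]


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class MonitorField:
    """Monitor function ``mu`` (> 0, mean 1) and end-velocity curl ``gamma``."""

    mu: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.mu.shape != self.gamma.shape:
            raise ValueError("mu and gamma must share a grid")
        if np.any(self.mu <= 0):
            raise ValueError("mu must be strictly positive")
        if abs(self.mu.mean() - 1.0) > 1e-6:
            raise ValueError("mu must have mean 1 (discrete area constraint)")


@dataclass
class DeformationField:
    """Dense map phi: Omega -> Omega stored as per-pixel target coordinates.

    ``phi[0]``/``phi[1]`` hold the x (column) and y (row) target coordinate
    of each source pixel; ``jacobian_det`` the determinant of its spatial
    gradient.  Positive determinant everywhere certifies a diffeomorphism.
    """

    phi: np.ndarray
    jacobian_det: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 3 or self.phi.shape[0] != 2:
            raise ValueError("phi must be (2, H, W)")
        if self.jacobian_det is None:
            self.jacobian_det = jacobian_determinant(self.phi)
        self.jacobian_det = np.asarray(self.jacobian_det, dtype=float)

    @classmethod
    def identity(cls, shape) -> "DeformationField":
        H, W = shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        return cls(phi=np.stack([xx, yy]), jacobian_det=np.ones((H, W)))

    @property
    def shape(self):
        return self.phi.shape[1:]

    def warp_points(self, pts) -> np.ndarray:
        """Advance points (N, 2) in (i, j) = (col, row) through the map,
        sampling the field with bilinear sub-pixel interpolation."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        coords = [pts[:, 1], pts[:, 0]]  # map_coordinates wants [row, col]
        x = map_coordinates(self.phi[0], coords, order=1, mode="nearest")
        y = map_coordinates(self.phi[1], coords, order=1, mode="nearest")
        return np.column_stack([x, y])

    def warp_image(self, img) -> np.ndarray:
        """Sample ``img`` at the target coordinates: returns img(phi(x))."""
        return map_coordinates(np.asarray(img, float),
                               [self.phi[1], self.phi[0]],
                               order=1, mode="nearest")


@dataclass
class FramePair:
    """Two intensity images on a common grid, registered k -> k+1."""

    T_k: np.ndarray
    T_k1: np.ndarray

    def __post_init__(self) -> None:
        self.T_k = np.asarray(self.T_k, dtype=float)
        self.T_k1 = np.asarray(self.T_k1, dtype=float)
        if self.T_k.shape != self.T_k1.shape:
            raise ValueError("frames must have equal shapes")
        if not (np.all(np.isfinite(self.T_k)) and np.all(np.isfinite(self.T_k1))):
            raise ValueError("frames must be finite")


@dataclass
class RegistrationOptions:
    n_levels: int = 3
    n_steps: int = 10          # RK4 steps for the flow integration
    max_iter: int = 200        # gradient iterations per pyramid level
    rel_tol: float = 1e-4      # relative energy change stopping criterion
    mu_bounds: tuple[float, float] = (0.5, 2.0)
    gamma_free: bool = True    # optimize gamma as well as mu
    max_halvings: int = 10     # line-search step halvings before giving up
    pyramid_sigma: float = 1.0


# ---------------------------------------------------------------------------
# Discrete differential operators (centered differences, interior nodes)

def divergence(f: np.ndarray) -> np.ndarray:
    """Centered-difference divergence of a (2, H, W) field on interior nodes;
    one-sided at the boundary."""
    dfx = np.gradient(f[0], axis=1)
    dfy = np.gradient(f[1], axis=0)
    return dfx + dfy


def curl(f: np.ndarray) -> np.ndarray:
    """Scalar 2D curl d(f_y)/dx - d(f_x)/dy, centered in the interior."""
    return np.gradient(f[1], axis=1) - np.gradient(f[0], axis=0)


def jacobian_determinant(phi: np.ndarray) -> np.ndarray:
    dxx = np.gradient(phi[0], axis=1)
    dxy = np.gradient(phi[0], axis=0)
    dyx = np.gradient(phi[1], axis=1)
    dyy = np.gradient(phi[1], axis=0)
    return dxx * dyy - dxy * dyx


# ---------------------------------------------------------------------------
# div-curl solver
#
# Unknowns: rho_x, rho_y on the full grid.  Equations: centered-difference
# div and curl at every interior node, rho = 0 on the boundary.  The system
# is solved in the least-squares sense through the (pre-factorized) normal
# equations; for compatible smooth data (mean(mu) = 1) the residual is at
# machine level in the interior, while the Dirichlet boundary condition is
# honored approximately, as the continuous problem (which prescribes both
# components on the whole boundary) is formally overdetermined.

class _DivCurlSolver:
    def __init__(self, shape):
        H, W = shape
        if H < 4 or W < 4:
            raise ValueError("grid too small for the div-curl stencil")
        self.shape = (H, W)
        N = H * W

        def ux(j, i):
            return j * W + i

        def uy(j, i):
            return N + j * W + i

        jj, ii = np.mgrid[1:H - 1, 1:W - 1]
        jj = jj.ravel()
        ii = ii.ravel()
        m = jj.size
        self.interior = (jj, ii)

        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        r_div = np.arange(m)
        # div: (rho_x[j,i+1] - rho_x[j,i-1])/2 + (rho_y[j+1,i] - rho_y[j-1,i])/2
        add(r_div, ux(jj, ii + 1), np.full(m, 0.5))
        add(r_div, ux(jj, ii - 1), np.full(m, -0.5))
        add(r_div, uy(jj + 1, ii), np.full(m, 0.5))
        add(r_div, uy(jj - 1, ii), np.full(m, -0.5))
        r_curl = np.arange(m) + m
        # curl: (rho_y[j,i+1] - rho_y[j,i-1])/2 - (rho_x[j+1,i] - rho_x[j-1,i])/2
        add(r_curl, uy(jj, ii + 1), np.full(m, 0.5))
        add(r_curl, uy(jj, ii - 1), np.full(m, -0.5))
        add(r_curl, ux(jj + 1, ii), np.full(m, -0.5))
        add(r_curl, ux(jj - 1, ii), np.full(m, 0.5))

        bmask = np.ones((H, W), dtype=bool)
        bmask[1:H - 1, 1:W - 1] = False
        bj, bi = np.nonzero(bmask)
        nb = bj.size
        r0 = 2 * m
        add(np.arange(nb) + r0, ux(bj, bi), np.ones(nb))
        add(np.arange(nb) + r0 + nb, uy(bj, bi), np.ones(nb))

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        A = sparse.coo_matrix((vals, (rows, cols)),
                              shape=(2 * m + 2 * nb, 2 * N)).tocsc()
        self.A = A
        self.m = m
        AtA = (A.T @ A).tocsc()
        # tiny Tikhonov term guards against checkerboard near-null modes
        AtA = AtA + sparse.identity(2 * N, format="csc") * 1e-12
        self._lu = splu(AtA)

    def solve(self, mu_minus_1: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        H, W = self.shape
        jj, ii = self.interior
        b = np.zeros(self.A.shape[0])
        b[:self.m] = mu_minus_1[jj, ii]
        b[self.m:2 * self.m] = gamma[jj, ii]
        x = self._lu.solve(self.A.T @ b)
        return x.reshape(2, H, W)

    def adjoint(self, force: np.ndarray):
        """Gradient of a functional wrt (mu - 1, gamma) given its gradient
        ``force`` wrt rho (small-deformation chain rule through the solve)."""
        H, W = self.shape
        jj, ii = self.interior
        y = self._lu.solve(force.reshape(-1))
        g = self.A @ y
        g_mu = np.zeros((H, W))
        g_gamma = np.zeros((H, W))
        g_mu[jj, ii] = g[:self.m]
        g_gamma[jj, ii] = g[self.m:2 * self.m]
        return g_mu, g_gamma


_SOLVER_CACHE: dict[tuple[int, int], _DivCurlSolver] = {}


def _get_solver(shape) -> _DivCurlSolver:
    key = tuple(int(v) for v in shape)
    if key not in _SOLVER_CACHE:
        _SOLVER_CACHE[key] = _DivCurlSolver(key)
    return _SOLVER_CACHE[key]


def solve_div_curl(mu: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Solve div rho = mu - 1, curl rho = gamma, rho ~ 0 on the boundary.

    ``mu`` must have mean 1 (the divergence data must integrate to zero for
    compatibility with a vanishing boundary field).  Returns rho as a
    (2, H, W) array.
    """
    mu = np.asarray(mu, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if mu.shape != gamma.shape:
        raise ValueError("mu and gamma must share a grid")
    if abs(mu.mean() - 1.0) > 1e-6:
        raise ValueError("mean(mu) must equal 1 (incompatible divergence data)")
    return _get_solver(mu.shape).solve(mu - 1.0, gamma)


def velocity_at(rho: np.ndarray, mu: np.ndarray, t: float) -> np.ndarray:
    """Velocity nu_t(x) = rho(x) / (t + (1 - t) mu(x)), pointwise."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    return np.asarray(rho, float) / (t + (1.0 - t) * mu)


def _sample_field(field2, mu, pts_x, pts_y, t):
    """nu_t at off-grid positions, bilinear in rho and mu."""
    coords = [pts_y, pts_x]
    rx = map_coordinates(field2[0], coords, order=1, mode="nearest")
    ry = map_coordinates(field2[1], coords, order=1, mode="nearest")
    mu_p = map_coordinates(mu, coords, order=1, mode="nearest")
    denom = t + (1.0 - t) * mu_p
    return rx / denom, ry / denom


def integrate_flow(rho: np.ndarray, mu: np.ndarray,
                   n_steps: int = 10) -> DeformationField:
    """Integrate d psi/dt = nu_t(psi) from the identity with RK4.

    Returns the end map phi = psi(., 1) with its Jacobian determinant
    (centered finite differences).  Trajectories are clamped to the domain;
    the field vanishes on the boundary by construction so clamping is a
    numerical safeguard only.
    """
    mu = np.asarray(mu, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    H, W = mu.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    px, py = xx.ravel(), yy.ravel()
    h = 1.0 / n_steps
    worst_exit = 0.0
    for step in range(n_steps):
        t = step * h
        k1x, k1y = _sample_field(rho, mu, px, py, t)
        k2x, k2y = _sample_field(rho, mu, px + 0.5 * h * k1x,
                                 py + 0.5 * h * k1y, t + 0.5 * h)
        k3x, k3y = _sample_field(rho, mu, px + 0.5 * h * k2x,
                                 py + 0.5 * h * k2y, t + 0.5 * h)
        k4x, k4y = _sample_field(rho, mu, px + h * k3x, py + h * k3y, t + h)
        px = px + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        py = py + (h / 6.0) * (k1y + 2 * k2y + 2 * k3y + k4y)
        worst_exit = max(worst_exit, -px.min(), px.max() - (W - 1),
                         -py.min(), py.max() - (H - 1))
        np.clip(px, 0, W - 1, out=px)
        np.clip(py, 0, H - 1, out=py)
    if worst_exit > 0.1:
        # the field vanishes on the boundary only approximately; sub-pixel
        # exits are routine and silently clamped
        logger.warning("flow trajectories exited the domain by %.2f px "
                       "and were clamped", worst_exit)
    phi = np.stack([px.reshape(H, W), py.reshape(H, W)])
    return DeformationField(phi=phi, jacobian_det=jacobian_determinant(phi))


# ---------------------------------------------------------------------------
# Pairwise registration

def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _pyramid(img: np.ndarray, n_levels: int, sigma: float):
    """Coarse-to-fine list of images, coarsest first."""
    levels = [img]
    for _ in range(n_levels - 1):
        prev = levels[0]
        if min(prev.shape) < 16:
            break
        sm = gaussian_filter(prev, sigma)
        levels.insert(0, sm[::2, ::2])
    return levels


def _project_mu(mu: np.ndarray, bounds) -> np.ndarray:
    mu = np.clip(mu, bounds[0], bounds[1])
    return mu / mu.mean()


def _energy_and_warp(m_field, gamma, fixed, moving, n_steps):
    mu = 1.0 + m_field
    rho = _get_solver(mu.shape).solve(m_field, gamma)
    warp = integrate_flow(rho, mu, n_steps=n_steps)
    moved = warp.warp_image(moving)
    resid = moved - fixed
    return float(np.sum(resid ** 2)), warp, moved, resid


def register_pair(pair, opts: RegistrationOptions | None = None) -> DeformationField:
    """Estimate the diffeomorphism warping frame k onto frame k+1.

    The map phi sends frame-k coordinates to frame-(k+1) coordinates so
    trajectories advance forward in time; the dissimilarity minimized is
    ``sum (T_{k+1}(phi(x)) - T_k(x))^2`` over the grid.  Gradient descent on
    (mu, gamma) with step halving; after every step mu is clamped to
    ``opts.mu_bounds`` and rescaled to mean 1, which maintains the
    diffeomorphism margin.  Returns the full-resolution field; ``info``
    carries the energy ratio and convergence flags.
    """
    if opts is None:
        opts = RegistrationOptions()
    if not isinstance(pair, FramePair):
        pair = FramePair(*pair)
    fixed_full = _normalize(pair.T_k)
    moving_full = _normalize(pair.T_k1)

    fixed_pyr = _pyramid(fixed_full, opts.n_levels, opts.pyramid_sigma)
    moving_pyr = _pyramid(moving_full, opts.n_levels, opts.pyramid_sigma)

    m_field = np.zeros_like(fixed_pyr[0])
    gamma = np.zeros_like(fixed_pyr[0])
    warning = False
    e0_full = float(np.sum((moving_full - fixed_full) ** 2))

    for level, (fixed, moving) in enumerate(zip(fixed_pyr, moving_pyr)):
        if m_field.shape != fixed.shape:
            zf = (fixed.shape[0] / m_field.shape[0],
                  fixed.shape[1] / m_field.shape[1])
            m_field = zoom(m_field, zf, order=1)
            gamma = zoom(gamma, zf, order=1)
            m_field = _project_mu(1.0 + m_field, opts.mu_bounds) - 1.0
        solver = _get_solver(fixed.shape)
        gx = np.gradient(moving, axis=1)
        gy = np.gradient(moving, axis=0)
        E, warp, moved, resid = _energy_and_warp(m_field, gamma, fixed,
                                                 moving, opts.n_steps)
        if np.allclose(fixed, moving, atol=1e-12) and np.allclose(m_field, 0):
            continue  # identical frames: identity is already optimal
        eta = None
        for it in range(opts.max_iter):
            # force dE/drho at the warped positions (small-deformation adjoint)
            coords = [warp.phi[1], warp.phi[0]]
            gxp = map_coordinates(gx, coords, order=1, mode="nearest")
            gyp = map_coordinates(gy, coords, order=1, mode="nearest")
            force = np.stack([2.0 * resid * gxp, 2.0 * resid * gyp])
            g_mu, g_gamma = solver.adjoint(force)
            if not opts.gamma_free:
                g_gamma = np.zeros_like(g_gamma)
            gmax = max(np.abs(g_mu).max(), np.abs(g_gamma).max())
            if gmax < 1e-14:
                break
            if eta is None:
                eta = 0.02 / gmax
            accepted = False
            for _ in range(opts.max_halvings):
                m_try = _project_mu(1.0 + m_field - eta * g_mu,
                                    opts.mu_bounds) - 1.0
                g_try = gamma - eta * g_gamma
                E_try, warp_try, moved_try, resid_try = _energy_and_warp(
                    m_try, g_try, fixed, moving, opts.n_steps)
                if E_try < E:
                    accepted = True
                    break
                eta *= 0.5
            if not accepted:
                break
            rel = (E - E_try) / max(E, 1e-30)
            m_field, gamma = m_try, g_try
            E, warp, moved, resid = E_try, warp_try, moved_try, resid_try
            eta *= 1.3
            if rel < opts.rel_tol:
                break

    # final field at full resolution
    if m_field.shape != fixed_full.shape:
        zf = (fixed_full.shape[0] / m_field.shape[0],
              fixed_full.shape[1] / m_field.shape[1])
        m_field = zoom(m_field, zf, order=1)
        gamma = zoom(gamma, zf, order=1)
        m_field = _project_mu(1.0 + m_field, opts.mu_bounds) - 1.0
    mu = 1.0 + m_field
    rho = _get_solver(mu.shape).solve(m_field, gamma)
    out = integrate_flow(rho, mu, n_steps=opts.n_steps)
    e_final = float(np.sum((out.warp_image(moving_full) - fixed_full) ** 2))
    if e_final > e0_full:
        warning = True
        logger.warning("registration did not reduce the energy; "
                       "returning best-effort field")
    out.info = {
        "energy_initial": e0_full,
        "energy_final": e_final,
        "energy_ratio": e_final / e0_full if e0_full > 0 else 1.0,
        "warning": warning,
        "mu": mu,
        "gamma": gamma,
    }
    return out


def track_points(sequence, seeds, opts: RegistrationOptions | None = None):
    """Track seed points through a cine sequence by composing the K - 1
    adjacent-frame registrations.

    ``sequence`` is a (K, H, W) stack or list of frames; ``seeds`` an
    (N, 2) array of (i, j) pixel positions on frame 1 (inside the grid).
    Returns an (N, K, 2) trajectory array; positions advance through each
    deformation field with bilinear sub-pixel interpolation.
    """
    frames = [np.asarray(f, dtype=float) for f in sequence]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    H, W = frames[0].shape
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if (seeds[:, 0].min() < 0 or seeds[:, 0].max() > W - 1 or
            seeds[:, 1].min() < 0 or seeds[:, 1].max() > H - 1):
        raise ValueError("seeds must lie inside the image grid")
    K = len(frames)
    traj = np.empty((seeds.shape[0], K, 2))
    traj[:, 0] = seeds
    pts = seeds.copy()
    for k in range(K - 1):
        warp = register_pair(FramePair(frames[k], frames[k + 1]), opts)
        pts = warp.warp_points(pts)
        traj[:, k + 1] = pts
    return traj
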