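"""Synthetic left-ventricular phantom: cyclic 3D motion with ground truth.

The phantom places myocardial points on rings of a prolate ellipsoid (the
time-mean endocardial surface) and moves each point as a single-harmonic
oscillation about its mean position,

    p(t) = p_mean + A(p_mean) * cos(omega * t),

where the amplitude vector ``A`` composes three motion components:

* radial contraction — in-plane displacement ``c * (x, y)`` (peak radial
  excursion is the contraction fraction times the local radius);
* longitudinal shortening — axial displacement ``l * (z + z_apex_dist)``:
  the apex (z = -c) is stationary and every point oscillates along the long
  axis in proportion to its distance from the apex, so the base descends
  toward the apex in systole (the mitral-plane excursion of real hearts);
* twist — tangential displacement ``theta(z) * r`` with the rotation angle
  varying linearly from zero at the base (z = +c) to the full twist
  amplitude at the apex.

Every short-axis slice therefore carries through-plane (longitudinal)
motion and every long-axis plane through-plane (tangential) motion, which
is the situation multi-view fusion addresses.

Because every axis oscillates as a single harmonic about its mean, the
motion lies exactly in the model class of the cyclic state-space dynamics,
so frequency and position recovery by the smoother is well-posed.  A
two-harmonic "misspecified" mode exists for robustness experiments only.

The phantom also synthesizes the acquisition geometry (a short-axis stack
plus 2-/3-/4-chamber-like long-axis planes), noisy per-view measurements,
textured image sequences warped by the known in-plane motion, and a
multi-subject cohort with a hypokinetic sector for classification studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import PlaneGeometry, image_to_patient, patient_to_image
from .registration import DeformationField, jacobian_determinant

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "ViewSample",
    "make_motion",
    "default_geometries",
    "sample_views",
    "render_images",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the synthetic phantom.

    Defaults describe a healthy adult left ventricle imaged by a routine
    cine protocol: endocardial semi-axes 25 x 25 x 45 mm, 15% radial
    contraction, a longitudinal shortening fraction of 0.06 of the
    apex-to-point distance (about 11 mm of basal peak-to-peak excursion,
    the mitral-plane descent of healthy hearts), 10 degrees of apical
    twist, 72 bpm (one oscillation per beat), 20 frames per cycle, and
    0.5 mm of tracking noise.  Ring levels follow the 10 mm short-axis
    slice spacing of clinical acquisitions.
    """

    semi_axes: tuple[float, float, float] = (25.0, 25.0, 45.0)
    radial_contraction: float = 0.15
    longitudinal_shortening: float = 0.06
    twist_deg: float = 10.0
    heart_rate_bpm: float = 72.0
    omega_true: float | None = None   # default: 2*pi*HR/60
    K: int = 20
    noise_sd: float = 0.5             # mm, in-plane measurement noise
    seed: int = 0
    ring_z_levels: tuple[float, ...] = (-10.0, 0.0, 10.0)
    points_per_ring: int = 48
    hypo_sector_deg: tuple[float, float] | None = None
    hypo_factor: float = 0.3
    second_harmonic: float = 0.0      # misspecification amplitude fraction

    def __post_init__(self) -> None:
        if not (0.0 <= self.radial_contraction <= 0.5
                and 0.0 <= self.longitudinal_shortening <= 0.5):
            raise ValueError("motion fractions must lie in [0, 0.5]")
        if self.K < 8:
            raise ValueError("need at least 8 frames per cycle")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def omega(self) -> float:
        if self.omega_true is not None:
            return float(self.omega_true)
        return 2.0 * np.pi * self.heart_rate_bpm / 60.0

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def frame_interval_s(self) -> float:
        return self.cycle_s / self.K


@dataclass
class GroundTruth:
    """Analytic truth: per-point mean positions, amplitudes and trajectories."""

    means: np.ndarray        # (P, 3) mm
    amplitudes: np.ndarray   # (P, 3) mm
    omega: float             # rad/s
    times: np.ndarray        # (K,) s
    positions: np.ndarray    # (P, K, 3) mm
    amp_scale: np.ndarray    # (P,) hypokinesia scaling applied per point
    azimuth: np.ndarray      # (P,) rad
    ring_z: np.ndarray       # (P,) mm, mean-surface ring level of each point
    spec: PhantomSpec | None = None

    def positions_at(self, t) -> np.ndarray:
        """Analytic positions at arbitrary times (P, len(t), 3)."""
        t = np.atleast_1d(np.asarray(t, float))
        osc = np.cos(self.omega * t)[None, :, None]
        out = self.means[:, None, :] + self.amplitudes[:, None, :] * osc
        if self.spec is not None and self.spec.second_harmonic > 0:
            osc2 = np.cos(2.0 * self.omega * t)[None, :, None]
            out = out + (self.spec.second_harmonic
                         * self.amplitudes[:, None, :] * osc2)
        return out


def make_motion(spec: PhantomSpec) -> GroundTruth:
    """Build the analytic point motion for ``spec`` (deterministic)."""
    a, b, c = spec.semi_axes
    pts, azim, ringz = [], [], []
    for z in spec.ring_z_levels:
        frac = 1.0 - (z / c) ** 2
        if frac <= 0:
            raise ValueError(f"ring level z={z} lies outside the ellipsoid")
        alpha = 2.0 * np.pi * np.arange(spec.points_per_ring) / spec.points_per_ring
        r_x = a * np.sqrt(frac)
        r_y = b * np.sqrt(frac)
        ring = np.column_stack([r_x * np.cos(alpha), r_y * np.sin(alpha),
                                np.full_like(alpha, z)])
        pts.append(ring)
        azim.append(alpha)
        ringz.append(np.full_like(alpha, z))
    means = np.vstack(pts)
    azim = np.concatenate(azim)
    ringz = np.concatenate(ringz)

    twist_rad = np.deg2rad(spec.twist_deg)
    A = np.empty_like(means)
    # radial: peak displacement = contraction fraction x local radius
    A[:, 0] = spec.radial_contraction * means[:, 0]
    A[:, 1] = spec.radial_contraction * means[:, 1]
    # twist: tangential, zero at the base (z = +c), maximal at the apex
    theta = twist_rad * (c - means[:, 2]) / (2.0 * c)
    A[:, 0] += -theta * means[:, 1]
    A[:, 1] += theta * means[:, 0]
    # longitudinal: apex stationary, excursion grows with apex distance
    A[:, 2] = spec.longitudinal_shortening * (means[:, 2] + c)

    scale = np.ones(len(means))
    if spec.hypo_sector_deg is not None:
        lo, hi = np.deg2rad(spec.hypo_sector_deg)
        ang = np.mod(azim - lo, 2.0 * np.pi)
        width = np.mod(hi - lo, 2.0 * np.pi)
        scale[ang < width] = spec.hypo_factor
    A = A * scale[:, None]

    times = np.arange(spec.K) * spec.frame_interval_s
    gt = GroundTruth(means=means, amplitudes=A, omega=spec.omega,
                     times=times, positions=np.empty(0), amp_scale=scale,
                     azimuth=azim, ring_z=ringz, spec=spec)
    gt.positions = gt.positions_at(times)
    return gt


def default_geometries(spec: PhantomSpec, *, extent_mm: float = 48.0,
                       spacing_mm: float = 1.0,
                       la_angles_deg=(0.0, 60.0, 120.0)) -> list[PlaneGeometry]:
    """Default acquisition: one short-axis plane per ring level plus three
    long-axis planes rotated about the long axis (2-/3-/4-chamber-like)."""
    n = int(round(2 * extent_mm / spacing_mm))
    geoms = []
    for z in spec.ring_z_levels:
        geoms.append(PlaneGeometry(
            origin=np.array([-extent_mm, -extent_mm, z]),
            row_cosine=np.array([1.0, 0.0, 0.0]),
            col_cosine=np.array([0.0, 1.0, 0.0]),
            spacing=np.array([spacing_mm, spacing_mm]),
            n_rows=n, n_cols=n,
            heart_rate_bpm=spec.heart_rate_bpm, n_frames=spec.K,
            view_id=f"SA_z{z:+.0f}"))
    for ang in la_angles_deg:
        u = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang)), 0.0])
        geoms.append(PlaneGeometry(
            origin=-extent_mm * u + np.array([0.0, 0.0, -extent_mm]),
            row_cosine=u,
            col_cosine=np.array([0.0, 0.0, 1.0]),
            spacing=np.array([spacing_mm, spacing_mm]),
            n_rows=n, n_cols=n,
            heart_rate_bpm=spec.heart_rate_bpm, n_frames=spec.K,
            view_id=f"LA_{ang:.0f}"))
    return geoms


@dataclass
class ViewSample:
    """Per-view sampling of the phantom: pixel trajectories and 3D mappings."""

    geometry: PlaneGeometry
    point_ids: np.ndarray      # indices into the GroundTruth point set
    pixel_true: np.ndarray     # (P_v, K, 2) noise-free projections
    pixel_noisy: np.ndarray    # (P_v, K, 2)
    obs_3d: np.ndarray         # (P_v, K, 3) noisy pixels mapped to mm
    seeds: np.ndarray          # (P_v, 2) frame-1 true pixel positions


def sample_views(gt: GroundTruth, geometries, noise_sd: float, seed: int,
                 slice_tol_mm: float = 1.0) -> list[ViewSample]:
    """Project the true motion onto each plane and add measurement noise.

    A point belongs to a view when its *mean* position lies within
    ``slice_tol_mm`` of the plane (the anatomical slice selection).  Noise
    is i.i.d. Gaussian with SD ``noise_sd`` mm on each in-plane pixel axis,
    i.e. ``noise_sd / spacing`` pixels.  The noisy pixels are mapped back to
    mm with the plane geometry; the out-of-plane coordinate of these 3D
    observations is frozen at the plane, which is exactly the through-plane
    blindness of single-view 2D tracking.
    """
    rng = np.random.default_rng(seed)
    out = []
    P, K, _ = gt.positions.shape
    for g in geometries:
        _, d_mean = patient_to_image(g, gt.means)
        keep = np.flatnonzero(np.abs(d_mean) <= slice_tol_mm)
        if keep.size == 0:
            import warnings
            warnings.warn(f"no phantom points intersect view {g.view_id}")
            out.append(ViewSample(g, keep, np.empty((0, K, 2)),
                                  np.empty((0, K, 2)), np.empty((0, K, 3)),
                                  np.empty((0, 2))))
            continue
        flat = gt.positions[keep].reshape(-1, 3)
        pix, _ = patient_to_image(g, flat)
        pix = pix.reshape(len(keep), K, 2)
        noise = rng.normal(0.0, 1.0, size=pix.shape) * (noise_sd / g.spacing)
        noisy = pix + noise
        obs3d = image_to_patient(g, noisy.reshape(-1, 2)).reshape(len(keep), K, 3)
        out.append(ViewSample(geometry=g, point_ids=keep, pixel_true=pix,
                              pixel_noisy=noisy, obs_3d=obs3d,
                              seeds=pix[:, 0, :].copy()))
    return out


# ---------------------------------------------------------------------------
# Image rendering (registration fixture)

def _inplane_motion_matrix(gt: GroundTruth, g: PlaneGeometry, t: float):
    """In-plane material map at time t about the plane's LV-axis point, in
    pixel units: p(t) = c + B(t) (p_mean - c) + off(t)."""
    spec = gt.spec
    c_semi = spec.semi_axes[2]
    c_osc = float(np.cos(gt.omega * t))
    if abs(float(g.normal[2])) > 0.9:  # short-axis plane
        z = float((image_to_patient(g, (0.0, 0.0)))[2])
        rc = spec.radial_contraction
        theta = np.deg2rad(spec.twist_deg) * (c_semi - z) / (2.0 * c_semi)
        B = np.array([[1.0 + rc * c_osc, -theta * c_osc],
                      [theta * c_osc, 1.0 + rc * c_osc]])
        off = np.zeros(2)
    else:  # long-axis plane: radial along u, apex-referenced shortening in z
        ls = spec.longitudinal_shortening
        B = np.array([[1.0 + spec.radial_contraction * c_osc, 0.0],
                      [0.0, 1.0 + ls * c_osc]])
        off = np.array([0.0, ls * c_semi * c_osc / g.spacing[1]])
    return B, off


def _plane_center_px(g: PlaneGeometry) -> np.ndarray:
    """Pixel coordinates of the LV long axis (x = y = 0) in this plane."""
    if abs(float(g.normal[2])) > 0.9:
        c3 = np.array([0.0, 0.0, image_to_patient(g, (0.0, 0.0))[2]])
    else:
        c3 = np.array([0.0, 0.0, 0.0])
        # project axis point onto plane
        p, _ = patient_to_image(g, c3)
        return np.asarray(p, float)
    p, _ = patient_to_image(g, c3)
    return np.asarray(p, float)


@dataclass
class RenderedSequence:
    images: np.ndarray                    # (K, H, W) in [0, 1]
    true_fields: list[DeformationField]   # adjacent-frame maps, length K-1
    maps: list[np.ndarray]                # (K, 2, 3) affine [B | b] per frame
    geometry: PlaneGeometry

    def apply_map(self, k: int, pts: np.ndarray) -> np.ndarray:
        """Material positions at frame k of points given at frame 0."""
        A0 = self.maps[0]
        Ak = self.maps[k]
        B0, b0 = A0[:, :2], A0[:, 2]
        pts = np.atleast_2d(pts)
        mean_cfg = np.linalg.solve(B0, (pts - b0).T).T
        return mean_cfg @ Ak[:, :2].T + Ak[:, 2]


def render_images(gt: GroundTruth, geometry: PlaneGeometry, texture_seed: int,
                  shape: tuple[int, int] = (64, 64),
                  wall_mm: float = 8.0) -> RenderedSequence:
    """Textured image sequence of this plane warped by the analytic motion.

    Frame 1 shows a smooth random-blob texture masked to the myocardial
    annulus (endocardial surface to endocardium + ``wall_mm``); subsequent
    frames are warps of the same material texture under the in-plane
    component of the phantom motion.  The true adjacent-frame deformation
    fields are returned for scoring a registration.
    """
    H, W = shape
    spec = gt.spec
    # render geometry: same plane pose, resampled to the requested grid
    scale = np.array([geometry.spacing[0] * geometry.n_cols / W,
                      geometry.spacing[1] * geometry.n_rows / H])
    g = PlaneGeometry(origin=geometry.origin, row_cosine=geometry.row_cosine,
                      col_cosine=geometry.col_cosine, spacing=scale,
                      n_rows=H, n_cols=W,
                      heart_rate_bpm=geometry.heart_rate_bpm,
                      n_frames=geometry.n_frames, view_id=geometry.view_id)

    rng = np.random.default_rng(texture_seed)
    tex = gaussian_filter(rng.normal(size=(H, W)), 2.0)
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
    tex = 0.15 + 0.8 * tex

    # annulus mask in the mean configuration
    jj, ii = np.mgrid[0:H, 0:W].astype(float)
    q = image_to_patient(g, np.column_stack([ii.ravel(), jj.ravel()]))
    a, b, c = spec.semi_axes
    f_endo = (q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2 + (q[:, 2] / c) ** 2
    a2, b2, c2 = a + wall_mm, b + wall_mm, c + wall_mm
    f_epi = (q[:, 0] / a2) ** 2 + (q[:, 1] / b2) ** 2 + (q[:, 2] / c2) ** 2
    mask = (1.0 / (1.0 + np.exp(-(f_endo - 1.0) * 8.0))
            * 1.0 / (1.0 + np.exp((f_epi - 1.0) * 8.0)))
    base = (tex * mask.reshape(H, W)).clip(0.0, 1.0)

    center = _plane_center_px(g)
    maps = []
    for t in gt.times:
        B, off = _inplane_motion_matrix(gt, g, float(t))
        bvec = center - B @ center + off
        maps.append(np.column_stack([B, bvec]))

    images = np.empty((len(gt.times), H, W))
    for k, A in enumerate(maps):
        B, bvec = A[:, :2], A[:, 2]
        Binv = np.linalg.inv(B)
        # I_k(y) = base(B^{-1}(y - b)) : pull back to the mean configuration
        pts = np.column_stack([ii.ravel(), jj.ravel()])
        src = (pts - bvec) @ Binv.T
        images[k] = map_coordinates(base, [src[:, 1], src[:, 0]], order=1,
                                    mode="constant", cval=0.0).reshape(H, W)

    fields = []
    for k in range(len(maps) - 1):
        Bk, bk = maps[k][:, :2], maps[k][:, 2]
        Bn, bn = maps[k + 1][:, :2], maps[k + 1][:, 2]
        M = Bn @ np.linalg.inv(Bk)
        off = bn - M @ bk
        pts = np.column_stack([ii.ravel(), jj.ravel()])
        tgt = pts @ M.T + off
        phi = np.stack([tgt[:, 0].reshape(H, W), tgt[:, 1].reshape(H, W)])
        fields.append(DeformationField(phi=phi,
                                       jacobian_det=jacobian_determinant(phi)))
    return RenderedSequence(images=images, true_fields=fields, maps=maps,
                            geometry=g)


# ---------------------------------------------------------------------------
# Classification cohort

def make_cohort(n_subjects: int = 20, n_abnormal: int = 7, seed: int = 0,
                K: int = 20, noise_sd: float = 0.5):
    """Synthetic cohort for regional-function classification.

    Normal subjects contract fully; abnormal subjects carry one hypokinetic
    sector (90 degrees wide, amplitude scaled to 30%).  Subject anatomy and
    function vary mildly around the defaults.  Returns a pandas DataFrame of
    per-segment feature samples (subject, level, segment, sde_radial,
    sde_area, label) ready for leave-one-subject-out evaluation.
    """
    import pandas as pd

    from .regional import LEVEL_SEGMENTS, partition_contour, radial_feature, \
        area_feature

    rng = np.random.default_rng(seed)
    levels = ["apical", "mid", "basal"]
    rows = []
    for subj in range(n_subjects):
        abnormal = subj < n_abnormal
        contraction = float(np.clip(rng.normal(0.15, 0.02), 0.08, 0.25))
        shortening = float(np.clip(rng.normal(0.12, 0.015), 0.05, 0.2))
        twist = float(np.clip(rng.normal(8.0, 1.0), 4.0, 12.0))
        ab = float(np.clip(rng.normal(25.0, 1.5), 20.0, 30.0))
        cc = float(np.clip(rng.normal(45.0, 2.0), 38.0, 52.0))
        hr = float(np.clip(rng.normal(68.0, 7.0), 50.0, 90.0))
        sector = None
        if abnormal:
            start = float(rng.uniform(0.0, 360.0))
            sector = (start, start + 90.0)
        spec = PhantomSpec(semi_axes=(ab, ab, cc),
                           radial_contraction=contraction,
                           longitudinal_shortening=shortening,
                           twist_deg=twist, heart_rate_bpm=hr, K=K,
                           noise_sd=noise_sd,
                           seed=int(rng.integers(0, 2 ** 31 - 1)),
                           hypo_sector_deg=sector)
        gt = make_motion(spec)
        for level, z in zip(levels, spec.ring_z_levels):
            on_ring = np.flatnonzero(gt.ring_z == z)
            traj = gt.positions[on_ring][:, :, :2]  # in-plane (x, y), (N,K,2)
            traj = traj + rng.normal(0.0, noise_sd, size=traj.shape)
            contours = np.transpose(traj, (1, 0, 2))  # (K, N, 2)
            # septal insertion landmark: fixed anatomical azimuth
            landmark_idx = int(np.argmin(np.abs(
                np.mod(gt.azimuth[on_ring] - np.deg2rad(120.0),
                       2 * np.pi))))
            seg = partition_contour(contours[0],
                                    contours[0][landmark_idx], level)
            for s in range(LEVEL_SEGMENTS[level]):
                sel = seg.labels == s
                if not np.any(sel):
                    continue
                sde_r = radial_feature(contours[:, sel, :],
                                       centroids=contours.mean(axis=1))
                sde_a = area_feature(contours[:, sel, :],
                                     centroids=contours.mean(axis=1))
                frac_hypo = float(np.mean(gt.amp_scale[on_ring][sel] < 0.65))
                rows.append({"subject": subj, "level": level, "segment": s,
                             "sde_radial": sde_r, "sde_area": sde_a,
                             "label": int(frac_hypo >= 0.5)})
    return pd.DataFrame(rows)
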