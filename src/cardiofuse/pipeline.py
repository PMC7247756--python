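"""End-to-end orchestration: track -> smooth -> fuse -> evaluate.

The pipeline turns per-view 2D pixel trajectories into 3D state estimates
and fuses them:

1. per view, pixel trajectories come either from the diffeomorphic
   registration tracker (image mode) or directly from the phantom sampler
   (observation mode);
2. pixel positions are mapped to patient coordinates with the view's plane
   geometry; the out-of-plane coordinate of these measurements is frozen at
   the plane, so the per-view measurement covariance is inflated along the
   plane normal;
3. each 3D trajectory is smoothed by the cyclic-dynamics unscented Kalman
   smoother, yielding per-frame means and covariances;
4. corresponding tracks from different views are fused frame-wise by
   maximum likelihood.

Evaluation helpers implement the RMSE of 2D projections, mid-wall
comparison points and the first-half-cycle truncation used when scoring
against reference estimates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, fusion, phantom, registration
from .dynamics import CyclicState, ModelSpec, init_state, uks_smooth
from .fusion import FusedTrack, ViewTrack, build_correspondences, fuse_tracks
from .geometry import PlaneGeometry, image_to_patient, patient_to_image

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicsConfig",
    "RunConfig",
    "view_measurement_covariance",
    "smooth_view",
    "run_pipeline",
    "rmse_2d",
    "rmse_3d",
    "midwall_points",
    "half_cycle_filter",
    "save_tracks_csv",
    "load_tracks_csv",
]


@dataclass
class DynamicsConfig:
    """Tunable dynamics/noise parameters (units in mm, s, rad)."""

    q_pos: float = 1.0          # mm^2/s^3 white-noise acceleration intensity
    q_mean_scale: float = 1e-4  # mean-position drift relative to q_pos
    q_omega: float = 1e-2       # rad^2/s^3 frequency random walk
    r: float | None = None      # mm^2; default (0.5 * max spacing)^2
    through_plane_factor: float = 1e4  # variance inflation along the normal
    alpha: float = 0.1
    beta: float = 2.0
    kappa: float = 0.0


@dataclass
class RunConfig:
    """Configuration of a full phantom-driven run."""

    phantom: phantom.PhantomSpec = field(default_factory=phantom.PhantomSpec)
    mode: str = "observations"       # "observations" or "images"
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    fusion_tol_mm: float = 3.0
    slice_tol_mm: float = 1.0
    half_cycle: bool = False
    seed: int = 0
    outdir: str | None = None
    image_shape: tuple[int, int] = (64, 64)
    registration_opts: registration.RegistrationOptions = field(
        default_factory=registration.RegistrationOptions)


def view_measurement_covariance(g: PlaneGeometry, r: float,
                                through_plane_factor: float) -> np.ndarray:
    """3x3 measurement covariance of a view in patient coordinates:
    isotropic ``r`` in-plane, ``through_plane_factor * r`` along the
    normal (the through-plane coordinate of a 2D view carries almost no
    information)."""
    u, v, n = g.row_cosine, g.col_cosine, g.normal
    return (r * (np.outer(u, u) + np.outer(v, v))
            + through_plane_factor * r * np.outer(n, n))


def smooth_view(obs_3d: np.ndarray, g: PlaneGeometry, heart_rate_bpm: float,
                cfg: DynamicsConfig | None = None,
                point_ids=None) -> list[ViewTrack]:
    """Smooth each point's 3D measurement trajectory of one view.

    ``obs_3d`` is (P, K, 3) in mm.  Returns one :class:`ViewTrack` per
    point with the view's anisotropic measurement covariance.
    """
    if cfg is None:
        cfg = DynamicsConfig()
    P, K, _ = obs_3d.shape
    r = cfg.r if cfg.r is not None else (0.5 * float(g.spacing.max())) ** 2
    R = view_measurement_covariance(g, r, cfg.through_plane_factor)
    tracks = []
    for p in range(P):
        init, T = init_state(obs_3d[p], heart_rate_bpm)
        Q = dynamics.build_process_noise(T, q_pos=cfg.q_pos,
                                         q_mean_scale=cfg.q_mean_scale,
                                         q_omega=cfg.q_omega)
        model = ModelSpec(T=T, Q=Q, R=R,
                          sigma_params=(cfg.alpha, cfg.beta, cfg.kappa))
        states = uks_smooth(obs_3d[p], model, init)
        pid = int(point_ids[p]) if point_ids is not None else p
        tracks.append(ViewTrack(states=states, view_id=g.view_id,
                                geometry=g, point_id=pid))
    return tracks


# ---------------------------------------------------------------------------
# Evaluation operators

def rmse_2d(estimates, references) -> float:
    """RMSE over N matched 2D points:
    sqrt((1/N) sum_i (xi_i - xi_ref_i)^2 + (eta_i - eta_ref_i)^2)."""
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    ref = np.atleast_2d(np.asarray(references, dtype=float))
    if est.shape != ref.shape:
        raise ValueError("estimate and reference point sets must match")
    if est.shape[0] < 1:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean(np.sum((est - ref) ** 2, axis=-1))))


def rmse_3d(estimates, references) -> float:
    """RMSE of 3D position error (mm) over points and frames."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("shapes must match")
    return float(np.sqrt(np.mean(np.sum((est - ref) ** 2, axis=-1))))


def midwall_points(endo, epi) -> np.ndarray:
    """Mid-wall comparison points: pointwise midpoints of index-aligned
    endocardial and epicardial samples."""
    endo = np.asarray(endo, dtype=float)
    epi = np.asarray(epi, dtype=float)
    if endo.shape != epi.shape:
        raise ValueError("endo and epi contours must be index-aligned")
    return 0.5 * (endo + epi)


def half_cycle_filter(track, K: int | None = None):
    """First ``ceil(K/2)`` frames of a track (evaluation-path truncation)."""
    if isinstance(track, (ViewTrack, FusedTrack)):
        K_eff = len(track) if K is None else K
        n = int(np.ceil(K_eff / 2.0))
        return dataclasses.replace(track, states=track.states[:n])
    arr = np.asarray(track)
    K_eff = arr.shape[0] if K is None else K
    if K_eff < 2:
        raise ValueError("need at least 2 frames")
    n = int(np.ceil(K_eff / 2.0))
    return arr[:min(n, arr.shape[0])]


# ---------------------------------------------------------------------------
# Orchestration

def _track_views_from_images(gt, geoms, cfg: RunConfig):
    """Image-mode tracking: render each view, register adjacent frames and
    advance the seeds, then map pixel trajectories to 3D."""
    views = phantom.sample_views(gt, geoms, noise_sd=0.0, seed=cfg.seed,
                                 slice_tol_mm=cfg.slice_tol_mm)
    out = []
    for vi, vs in enumerate(views):
        if len(vs.point_ids) == 0:
            continue
        rend = phantom.render_images(gt, vs.geometry, texture_seed=cfg.seed + vi,
                                     shape=cfg.image_shape)
        g = rend.geometry
        seeds, _ = patient_to_image(g, gt.positions[vs.point_ids, 0, :])
        traj_px = registration.track_points(rend.images, seeds,
                                            cfg.registration_opts)
        P, K, _ = traj_px.shape
        obs3d = image_to_patient(g, traj_px.reshape(-1, 2)).reshape(P, K, 3)
        out.append((g, vs.point_ids, obs3d))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full phantom pipeline and evaluate against ground truth.

    Returns a dict with the per-view tracks, fused tracks, per-view and
    fused 3D RMSE (over the points contributing to >= 2 views), and writes
    CSV/JSON outputs when ``cfg.outdir`` is set.  Deterministic given
    ``cfg.seed``.
    """
    spec = dataclasses.replace(cfg.phantom, seed=cfg.seed)
    gt = phantom.make_motion(spec)
    geoms = phantom.default_geometries(spec)

    if cfg.mode == "observations":
        views = phantom.sample_views(gt, geoms, noise_sd=spec.noise_sd,
                                     seed=cfg.seed,
                                     slice_tol_mm=cfg.slice_tol_mm)
        per_view = [(vs.geometry, vs.point_ids, vs.obs_3d) for vs in views
                    if len(vs.point_ids)]
    elif cfg.mode == "images":
        per_view = _track_views_from_images(gt, geoms, cfg)
    else:
        raise ValueError("mode must be 'observations' or 'images'")

    view_tracks: list[ViewTrack] = []
    for g, pids, obs3d in per_view:
        try:
            view_tracks.extend(smooth_view(obs3d, g, spec.heart_rate_bpm,
                                           cfg.dynamics, point_ids=pids))
        except Exception as e:
            raise RuntimeError(f"stage=smooth view={g.view_id}: {e}") from e

    correspondence = build_correspondences(view_tracks,
                                           tol_mm=cfg.fusion_tol_mm)
    fused = fuse_tracks(view_tracks, correspondence)

    # evaluation over multi-view (fused) points
    multi = [ft for ft in fused if len(ft.view_ids) >= 2]
    report: dict = {"n_view_tracks": len(view_tracks),
                    "n_fused": len(fused),
                    "n_multiview": len(multi)}
    if multi:
        fused_err = []
        view_err: dict[str, list] = {}
        fused_err_by_view: dict[str, list] = {}
        for ft, grp in zip(fused, correspondence):
            if len(ft.view_ids) < 2:
                continue
            ref = gt.positions[ft.point_id]
            est = ft.positions()
            if cfg.half_cycle:
                est = half_cycle_filter(est)
                ref = half_cycle_filter(ref)
            fe = np.sum((est - ref[:est.shape[0]]) ** 2, axis=-1)
            fused_err.append(fe)
            for idx in grp:
                vt = view_tracks[idx]
                refv = gt.positions[vt.point_id]
                estv = vt.positions()
                if cfg.half_cycle:
                    estv = half_cycle_filter(estv)
                    refv = half_cycle_filter(refv)
                view_err.setdefault(vt.view_id, []).append(
                    np.sum((estv - refv[:estv.shape[0]]) ** 2, axis=-1))
                fused_err_by_view.setdefault(vt.view_id, []).append(fe)
        report["fused_rmse_mm"] = float(np.sqrt(np.mean(
            np.concatenate(fused_err))))
        # per view, single-view RMSE and fused RMSE over the SAME points
        report["view_rmse_mm"] = {
            v: float(np.sqrt(np.mean(np.concatenate(errs))))
            for v, errs in view_err.items()}
        report["fused_rmse_by_view_mm"] = {
            v: float(np.sqrt(np.mean(np.concatenate(errs))))
            for v, errs in fused_err_by_view.items()}
        report["fusion_helps"] = bool(all(
            report["fused_rmse_by_view_mm"][v] < report["view_rmse_mm"][v]
            for v in report["view_rmse_mm"]))

    result = {"ground_truth": gt, "view_tracks": view_tracks,
              "fused_tracks": fused, "correspondence": correspondence,
              "report": report}
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_tracks_csv(view_tracks, outdir / "view_tracks.csv")
        save_tracks_csv(fused, outdir / "fused_tracks.csv")
        with open(outdir / "report.json", "w") as f:
            json.dump(report, f, indent=1)
    return result


# ---------------------------------------------------------------------------
# Track I/O

_STATE_COLS = ["x_mean", "x", "x_dot", "y_mean", "y", "y_dot",
               "z_mean", "z", "z_dot", "omega"]


def save_tracks_csv(tracks, path, covariances: str | Path | None = None):
    """Write tracks as CSV (point_id, view, frame, 10 state columns);
    optionally store the per-frame covariances in a compressed archive."""
    rows = []
    covs = {}
    for t in tracks:
        view = t.view_id if isinstance(t, ViewTrack) else "+".join(t.view_ids)
        for k, st in enumerate(t.states):
            rows.append([t.point_id, view, k, *st.s.tolist()])
        covs[f"{t.point_id}_{view}"] = np.array([st.P for st in t.states])
    df = pd.DataFrame(rows, columns=["point_id", "view", "frame", *_STATE_COLS])
    df.to_csv(path, index=False)
    if covariances is not None:
        np.savez_compressed(covariances, **covs)
    return df


def load_tracks_csv(path, covariances: str | Path | None = None):
    """Read tracks written by :func:`save_tracks_csv`; covariances default
    to identity when no archive is given."""
    df = pd.read_csv(path)
    archive = np.load(covariances) if covariances is not None else None
    tracks = []
    for (pid, view), grp in df.groupby(["point_id", "view"], sort=False):
        grp = grp.sort_values("frame")
        S = grp[_STATE_COLS].to_numpy(dtype=float)
        key = f"{pid}_{view}"
        if archive is not None and key in archive:
            P = archive[key]
        else:
            P = np.repeat(np.eye(10)[None], len(S), axis=0)
        states = [CyclicState(s=S[k], P=P[k]) for k in range(len(S))]
        tracks.append(ViewTrack(states=states, view_id=str(view),
                                point_id=int(pid)))
    return tracks
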