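"""Maximum-likelihood track-to-track fusion of per-view state estimates.

Two views of the same myocardial point yield two smoothed state estimates
(s_a, P_a) and (s_b, P_b).  Treating them as independent Gaussian estimates
of one underlying state (zero cross-covariance between views), the
maximum-likelihood combination is

    s_ML = P_b (P_a + P_b)^{-1} s_a + P_a (P_a + P_b)^{-1} s_b
    P_ML = (P_a^{-1} + P_b^{-1})^{-1}

i.e. inverse-covariance (information) weighting.  The fused covariance is
never larger than either input in the Loewner order, which is how fusing a
short-axis track (weak through-plane information) with a long-axis track
recovers full 3D motion.  A general form retaining the cross-covariance
term is kept as a secondary path for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve

from .dynamics import CyclicState, NumericalFailure
from .geometry import PlaneGeometry, patient_to_image

__all__ = [
    "ViewTrack",
    "FusedTrack",
    "fuse_pair",
    "fuse_pair_correlated",
    "fuse_many",
    "fuse_tracks",
    "build_correspondences",
    "resample_track",
]


@dataclass
class ViewTrack:
    """Smoothed states of one myocardial point in one view."""

    states: list[CyclicState]
    view_id: str
    geometry: PlaneGeometry | None = None
    point_id: int = -1

    def __len__(self) -> int:
        return len(self.states)

    def positions(self) -> np.ndarray:
        return np.array([st.position for st in self.states])


@dataclass
class FusedTrack:
    """ML combination of two or more :class:`ViewTrack` of the same point."""

    states: list[CyclicState]
    view_ids: list[str]
    point_id: int = -1

    def __len__(self) -> int:
        return len(self.states)

    def positions(self) -> np.ndarray:
        return np.array([st.position for st in self.states])


def _solve_sum(P_sum: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        return solve(P_sum, B, assume_a="pos")
    except np.linalg.LinAlgError as e:
        raise NumericalFailure(f"singular covariance sum in fusion: {e}")


def fuse_pair(s_a, P_a, s_b, P_b):
    """Fuse two independent Gaussian state estimates (zero cross-covariance).

    Returns ``(s, P)`` with the ML mean and the information-weighted
    covariance; implemented with linear solves against ``P_a + P_b``.
    """
    s_a = np.asarray(s_a, float)
    s_b = np.asarray(s_b, float)
    P_a = np.asarray(P_a, float)
    P_b = np.asarray(P_b, float)
    P_sum = P_a + P_b
    # mean = P_b (P_a+P_b)^-1 s_a + P_a (P_a+P_b)^-1 s_b
    s = P_b @ _solve_sum(P_sum, s_a) + P_a @ _solve_sum(P_sum, s_b)
    # covariance = (P_a^-1 + P_b^-1)^-1 = P_a (P_a+P_b)^-1 P_b
    P = P_a @ _solve_sum(P_sum, P_b)
    return s, 0.5 * (P + P.T)


def fuse_pair_correlated(s_a, P_a, s_b, P_b, P_ab):
    """General two-track fusion retaining the cross-covariance ``P_ab``.

    Reduces to :func:`fuse_pair` when ``P_ab = 0``.  Used as a verification
    path; the production pipeline assumes independent views.
    """
    s_a = np.asarray(s_a, float)
    s_b = np.asarray(s_b, float)
    P_a = np.asarray(P_a, float)
    P_b = np.asarray(P_b, float)
    P_ab = np.asarray(P_ab, float)
    D = P_a + P_b - P_ab - P_ab.T
    try:
        Dinv_sa = np.linalg.solve(D, s_a)
        Dinv_sb = np.linalg.solve(D, s_b)
    except np.linalg.LinAlgError as e:
        raise NumericalFailure(f"singular denominator in correlated fusion: {e}")
    s = (P_b - P_ab.T) @ Dinv_sa + (P_a - P_ab) @ Dinv_sb
    return s


def fuse_many(tracks):
    """Inverse-covariance fusion of M >= 1 estimates ``[(s_i, P_i), ...]``.

    ``P = (sum_i P_i^{-1})^{-1}``, ``s = P sum_i P_i^{-1} s_i``.  For M = 2
    this equals :func:`fuse_pair` algebraically.
    """
    tracks = list(tracks)
    if len(tracks) == 0:
        raise ValueError("need at least one estimate")
    if len(tracks) == 1:
        s, P = tracks[0]
        return np.asarray(s, float).copy(), np.asarray(P, float).copy()
    n = np.asarray(tracks[0][0], float).shape[0]
    info = np.zeros((n, n))
    info_mean = np.zeros(n)
    for s_i, P_i in tracks:
        s_i = np.asarray(s_i, float)
        P_i = np.asarray(P_i, float)
        try:
            c = cho_factor(0.5 * (P_i + P_i.T))
        except np.linalg.LinAlgError as e:
            raise NumericalFailure(f"non-PD input covariance in fusion: {e}")
        info += cho_solve(c, np.eye(n))
        info_mean += cho_solve(c, s_i)
    try:
        c = cho_factor(0.5 * (info + info.T))
    except np.linalg.LinAlgError as e:
        raise NumericalFailure(f"singular information sum in fusion: {e}")
    P = cho_solve(c, np.eye(n))
    s = cho_solve(c, info_mean)
    return s, 0.5 * (P + P.T)


# ---------------------------------------------------------------------------
# Track-level fusion

def resample_track(track: ViewTrack, K_common: int) -> ViewTrack:
    """Linearly resample state means and covariances onto a common
    normalized cardiac-phase grid of ``K_common`` frames."""
    K = len(track)
    if K == K_common:
        return track
    phase_in = np.linspace(0.0, 1.0, K, endpoint=False)
    phase_out = np.linspace(0.0, 1.0, K_common, endpoint=False)
    S = np.array([st.s for st in track.states])
    P = np.array([st.P for st in track.states])
    states = []
    for ph in phase_out:
        idx = np.searchsorted(phase_in, ph, side="right") - 1
        idx = min(max(idx, 0), K - 2)
        w = (ph - phase_in[idx]) / (phase_in[idx + 1] - phase_in[idx])
        s = (1 - w) * S[idx] + w * S[idx + 1]
        Pm = (1 - w) * P[idx] + w * P[idx + 1]
        states.append(CyclicState(s=s, P=Pm))
    return ViewTrack(states=states, view_id=track.view_id,
                     geometry=track.geometry, point_id=track.point_id)


def build_correspondences(view_tracks: list[ViewTrack],
                          tol_mm: float = 3.0) -> list[list[int]]:
    """Group tracks (indices into ``view_tracks``) believed to follow the
    same tissue point.

    Two tracks from different views correspond when their smoothed mean
    (anatomical) positions are within ``tol_mm`` and each lies within
    ``tol_mm`` of the other view's image plane; candidate pairs are
    accepted greedily by increasing distance, one-to-one per view pair,
    then merged into groups.  Matching on the beat-mean position rather
    than a single frame makes the association insensitive to the cardiac
    phase and to through-plane excursions within the beat.  Tracks matching
    nothing form singleton groups.
    """
    n = len(view_tracks)
    first_pos = np.array([t.states[0].mean_position for t in view_tracks])
    pairs = []
    for a in range(n):
        for b in range(a + 1, n):
            ta, tb = view_tracks[a], view_tracks[b]
            if ta.view_id == tb.view_id:
                continue
            d = float(np.linalg.norm(first_pos[a] - first_pos[b]))
            if d > tol_mm:
                continue
            ok = True
            if tb.geometry is not None:
                _, dd = patient_to_image(tb.geometry, first_pos[a])
                ok &= abs(dd) <= tol_mm
            if ta.geometry is not None:
                _, dd = patient_to_image(ta.geometry, first_pos[b])
                ok &= abs(dd) <= tol_mm
            if ok:
                pairs.append((d, a, b))
    pairs.sort()
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    matched_with = {i: set() for i in range(n)}
    for d, a, b in pairs:
        va, vb = view_tracks[a].view_id, view_tracks[b].view_id
        if vb in matched_with[a] or va in matched_with[b]:
            continue  # greedy one-to-one per view pair
        matched_with[a].add(vb)
        matched_with[b].add(va)
        parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())


def fuse_tracks(view_tracks: list[ViewTrack],
                correspondence: list[list[int]] | None = None,
                tol_mm: float = 3.0) -> list[FusedTrack]:
    """Frame-wise ML fusion of corresponding tracks.

    ``correspondence`` is a list of groups of indices into ``view_tracks``;
    when omitted it is built with :func:`build_correspondences`.  Tracks of
    unequal length are first resampled to the longest length in the group.
    A singleton group passes through unchanged.
    """
    if not view_tracks:
        raise ValueError("no tracks to fuse")
    if correspondence is None:
        correspondence = build_correspondences(view_tracks, tol_mm=tol_mm)
    if not correspondence:
        raise ValueError("empty correspondence")
    fused = []
    for group in correspondence:
        tracks = [view_tracks[i] for i in group]
        K_common = max(len(t) for t in tracks)
        tracks = [resample_track(t, K_common) for t in tracks]
        states = []
        for k in range(K_common):
            s, P = fuse_many([(t.states[k].s, t.states[k].P) for t in tracks])
            s = s.copy()
            s[9] = abs(s[9])
            states.append(CyclicState(s=s, P=P))
        fused.append(FusedTrack(states=states,
                                view_ids=[t.view_id for t in tracks],
                                point_id=tracks[0].point_id))
    return fused
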