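"""Regional wall-motion analysis: AHA segments, entropy features, classifier.

Endocardial contours of apical, mid-cavity and basal short-axis slices are
partitioned into 4, 6 and 6 equal-angle segments (the slice portions of the
AHA 17-segment model; the apex cap is not represented on these slices).
Per segment and frame two normalized quantities are tracked over the cardiac
cycle — mean radial distance to the cavity centroid and the sector polygon
area, each normalized by its first-frame (end-diastolic) value — and their
temporal variability is summarized by Shannon differential entropy (SDE).
A vigorous segment sweeps a wide range of normalized radius/area (high
entropy); a hypokinetic one barely moves (low entropy).  Normal/abnormal
classification uses a Gaussian naive Bayes on the two SDE features, fitted
separately per slice level, evaluated leave-one-subject-out, and the
separability of the feature distributions is measured by the Bhattacharyya
metric  B = sqrt(1 - sum_r sqrt(f_N(r) f_A(r))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB

__all__ = [
    "LEVEL_SEGMENTS",
    "RegionalSegments",
    "FeatureSample",
    "partition_contour",
    "shannon_differential_entropy",
    "radial_feature",
    "area_feature",
    "bhattacharyya",
    "fit_classifier",
    "evaluate_loso",
]

# slice portions of the AHA 17-segment model: 4 apical, 6 mid, 6 basal
LEVEL_SEGMENTS = {"apical": 4, "mid": 6, "basal": 6}

SDE_FLOOR = -10.0  # nats; reported for degenerate (point-mass) distributions


@dataclass
class RegionalSegments:
    """Assignment of contour points to equal-angle regional segments."""

    labels: np.ndarray
    level: str
    landmark: np.ndarray
    centroid: np.ndarray

    @property
    def n_segments(self) -> int:
        return LEVEL_SEGMENTS[self.level]


@dataclass(frozen=True)
class FeatureSample:
    sde_radial: float
    sde_area: float
    label: int
    subject: int = -1
    level: str = ""
    segment: int = -1


def _as_2d_contour(contour) -> np.ndarray:
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] not in (2, 3):
        raise ValueError("contour must be (N, 2) or (N, 3)")
    if c.shape[1] == 3:
        if np.ptp(c[:, 2]) > 1e-6:
            raise ValueError("3D contour points must be coplanar (equal z)")
        c = c[:, :2]
    return c


def partition_contour(contour, landmark, level: str) -> RegionalSegments:
    """Assign contour points to equal-angle sectors about the cavity centroid.

    Sectors start at the (anterior) septal insertion ``landmark`` and run
    counterclockwise; apical slices get 4 sectors, mid-cavity and basal 6.
    """
    if level not in LEVEL_SEGMENTS:
        raise ValueError(f"level must be one of {sorted(LEVEL_SEGMENTS)}")
    c = _as_2d_contour(contour)
    lm = np.asarray(landmark, dtype=float)
    if lm.shape[-1] == 3:
        full = np.asarray(contour, dtype=float)
        if full.shape[1] == 3 and abs(lm[2] - full[0, 2]) > 1e-6:
            raise ValueError("landmark does not lie on the contour plane")
        lm = lm[:2]
    centroid = c.mean(axis=0)
    n_seg = LEVEL_SEGMENTS[level]
    theta0 = np.arctan2(lm[1] - centroid[1], lm[0] - centroid[0])
    ang = np.arctan2(c[:, 1] - centroid[1], c[:, 0] - centroid[0])
    rel = np.mod(ang - theta0, 2.0 * np.pi)
    labels = np.minimum((rel / (2.0 * np.pi / n_seg)).astype(int), n_seg - 1)
    return RegionalSegments(labels=labels, level=level, landmark=lm,
                            centroid=centroid)


# ---------------------------------------------------------------------------
# Shannon differential entropy estimation

def shannon_differential_entropy(values, method: str = "hist",
                                 floor: float = SDE_FLOOR) -> float:
    """SDE (nats) of a sample, histogram estimator with Freedman-Diaconis
    bins; degenerate (point-mass) samples report the ``floor`` value.

    ``method="kde"`` switches to a Gaussian-KDE plug-in estimate.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite values")
    rng_x = float(np.ptp(x))
    if rng_x <= 0:
        return floor
    if method == "kde":
        from scipy.stats import gaussian_kde
        try:
            kde = gaussian_kde(x)
        except np.linalg.LinAlgError:
            return floor
        return max(float(-np.mean(np.log(np.maximum(kde(x), 1e-300)))), floor)
    if method != "hist":
        raise ValueError("method must be 'hist' or 'kde'")
    q75, q25 = np.percentile(x, [75, 25])
    h = 2.0 * (q75 - q25) * x.size ** (-1.0 / 3.0)
    if h <= 0:
        h = rng_x / max(int(np.sqrt(x.size)), 1)
    nbins = max(int(np.ceil(rng_x / h)), 1)
    counts, edges = np.histogram(x, bins=nbins)
    p = counts / counts.sum()
    w = edges[1] - edges[0]
    nz = p > 0
    ent = float(-(p[nz] * np.log(p[nz])).sum() + np.log(w))
    return max(ent, floor)


def _normalized_series(values: np.ndarray, what: str) -> np.ndarray:
    if abs(values[0]) < 1e-12:
        raise ValueError(f"degenerate {what}: first-frame value is zero")
    return values / values[0]


def radial_feature(segment_traj, centroids, method: str = "hist") -> float:
    """SDE of the normalized mean radial distance of a segment over time.

    ``segment_traj`` is (K, M, 2): the segment's M contour points over K
    frames; ``centroids`` (K, 2) the cavity centroid per frame.  Per frame
    the mean point-to-centroid distance is computed and normalized by its
    frame-1 value; the SDE of the K normalized values is returned.
    """
    traj = np.asarray(segment_traj, dtype=float)
    cen = np.asarray(centroids, dtype=float)
    if traj.ndim != 3 or traj.shape[0] < 8:
        raise ValueError("segment trajectory must be (K >= 8, M, 2)")
    radii = np.linalg.norm(traj - cen[:, None, :], axis=2).mean(axis=1)
    if np.any(radii <= 0):
        raise ValueError("degenerate contour: zero radius")
    return shannon_differential_entropy(
        _normalized_series(radii, "radius"), method=method)


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _arc_order(points: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Order indices of a contiguous contour arc by angle about the
    centroid, cutting the cyclic ordering at the largest angular gap so
    that arcs crossing the +-pi seam stay contiguous."""
    ang = np.arctan2(points[:, 1] - centroid[1], points[:, 0] - centroid[0])
    order = np.argsort(ang)
    gaps = np.diff(ang[order], append=ang[order[0]] + 2.0 * np.pi)
    start = (int(np.argmax(gaps)) + 1) % len(order)
    return np.roll(order, -start)


def area_feature(segment_traj, centroids, method: str = "hist") -> float:
    """SDE of the normalized sector area of a segment over time.

    The per-frame sector polygon is the segment's contour points closed
    through the cavity centroid; its shoelace area is normalized by the
    frame-1 value and the SDE of the K values returned.  Points are put in
    arc order (by frame-1 angle about the centroid) so the polygon cannot
    self-intersect.
    """
    traj = np.asarray(segment_traj, dtype=float)
    cen = np.asarray(centroids, dtype=float)
    if traj.ndim != 3 or traj.shape[0] < 8:
        raise ValueError("segment trajectory must be (K >= 8, M, 2)")
    traj = traj[:, _arc_order(traj[0], cen[0]), :]
    areas = np.array([
        _shoelace(np.vstack([cen[k][None, :], traj[k]]))
        for k in range(traj.shape[0])
    ])
    if np.any(areas <= 0):
        raise ValueError("degenerate segment: zero area")
    return shannon_differential_entropy(
        _normalized_series(areas, "area"), method=method)


def bhattacharyya(f_N, f_A) -> float:
    """Bhattacharyya separability of two discrete distributions on shared
    bins: ``B = sqrt(1 - sum_r sqrt(f_N(r) f_A(r)))``; 0 for identical
    distributions, 1 for disjoint supports."""
    f_N = np.asarray(f_N, dtype=float)
    f_A = np.asarray(f_A, dtype=float)
    if f_N.shape != f_A.shape:
        raise ValueError("distributions must share bins")
    if np.any(f_N < 0) or np.any(f_A < 0):
        raise ValueError("negative probability mass")
    if abs(f_N.sum() - 1.0) > 1e-6 or abs(f_A.sum() - 1.0) > 1e-6:
        raise ValueError("distributions must be normalized to sum 1")
    bc = float(np.sqrt(f_N * f_A).sum())
    return float(np.sqrt(max(1.0 - bc, 0.0)))


# ---------------------------------------------------------------------------
# Classification

_FEATURES = ["sde_radial", "sde_area"]


class NaiveBayesScorer:
    """Gaussian naive Bayes on the two SDE features; scores are the
    posterior probability of the abnormal class."""

    def __init__(self, nb: GaussianNB):
        self._nb = nb

    def score(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = self._nb.predict_proba(X)
        col = list(self._nb.classes_).index(1)
        return proba[:, col]

    def predict(self, X) -> np.ndarray:
        return (self.score(X) >= 0.5).astype(int)


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return pd.DataFrame([s.__dict__ if not isinstance(s, dict) else s
                         for s in samples])


def fit_classifier(samples, level: str | None = None) -> NaiveBayesScorer:
    """Fit the per-level naive Bayes classifier on SDE feature samples.

    ``samples`` is a DataFrame (or list of :class:`FeatureSample`) with
    columns sde_radial, sde_area, label; when ``level`` is given only that
    slice level's rows are used (decision boundaries are level-specific).
    """
    df = _as_frame(samples)
    if level is not None:
        df = df[df["level"] == level]
    y = df["label"].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    nb = GaussianNB()
    nb.fit(df[_FEATURES].to_numpy(dtype=float), y)
    return NaiveBayesScorer(nb)


def evaluate_loso(samples) -> dict:
    """Leave-one-subject-out evaluation of the regional classifier.

    Per held-out subject the per-level classifiers are fitted on the other
    subjects and applied to the held-out segments; predictions are pooled.
    Abnormal (label 1) is the positive class.  Returns accuracy,
    sensitivity, specificity, ROC points (threshold sweep on the posterior
    scores) and the trapezoid AUC.
    """
    df = _as_frame(samples)
    subjects = df["subject"].unique()
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    y_all, s_all = [], []
    for subj in subjects:
        train = df[df["subject"] != subj]
        test = df[df["subject"] == subj]
        scorers = {}
        for level in test["level"].unique():
            sub = train[train["level"] == level]
            if sub["label"].nunique() < 2 or sub["label"].value_counts().min() < 2:
                sub = train  # fall back to pooled levels
            scorers[level] = fit_classifier(sub)
        for level, grp in test.groupby("level"):
            y_all.append(grp["label"].to_numpy(dtype=int))
            s_all.append(scorers[level].score(grp[_FEATURES].to_numpy(float)))
    y = np.concatenate(y_all)
    scores = np.concatenate(s_all)
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    fpr, tpr, thr = roc_curve(y, scores)
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "auc": float(_trapezoid_auc(fpr, tpr)),
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "n_segments": int(len(y)),
        "labels": y,
        "scores": scores,
    }
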