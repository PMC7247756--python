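"""Image-plane geometry: mapping 2D pixel coordinates to the patient 3D frame.

Every cine view is a 2D plane positioned in the scanner's patient-based
coordinate system by the DICOM attributes Image Position (Patient),
Image Orientation (Patient) and Pixel Spacing.  A pixel index ``(i, j)``
(``i`` = column, ``j`` = row, zero-based) maps to millimetres as

    q = S + i * d_i * X + j * d_j * Y

where ``S`` is the plane origin, ``X``/``Y`` the row/column direction
cosines and ``(d_i, d_j)`` the pixel spacing.  This is the 3x3 homogeneous
matrix product used throughout multi-view CMR processing; the inverse map
(orthogonal projection onto the plane plus a signed out-of-plane distance)
is what re-projects 3D estimates onto any target view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PlaneGeometry",
    "image_to_patient",
    "patient_to_image",
    "plane_intersection_points",
    "load_sidecar",
    "save_sidecar",
    "read_dicom_series_geometry",
]

_ORTHO_WARN_TOL = 1e-4
_ORTHO_FAIL_TOL = 1e-2


@dataclass(frozen=True)
class PlaneGeometry:
    """Pose of a 2D image plane in the patient 3D reference frame.

    Parameters
    ----------
    origin : (3,) array
        Image Position (Patient): 3D location of pixel (0, 0), mm.
    row_cosine : (3,) array
        Unit vector along which the column index ``i`` increases.
    col_cosine : (3,) array
        Unit vector along which the row index ``j`` increases.
    spacing : (2,) array
        Pixel spacing ``(d_i, d_j)`` in mm along ``row_cosine`` and
        ``col_cosine`` respectively.
    n_rows, n_cols : int
        Image grid shape.

    Direction cosines from real headers carry rounding; deviations from
    orthonormality up to 1e-4 are silently re-orthogonalized by one
    Gram-Schmidt step, beyond 1e-2 the geometry is rejected.
    """

    origin: np.ndarray
    row_cosine: np.ndarray
    col_cosine: np.ndarray
    spacing: np.ndarray
    n_rows: int = 0
    n_cols: int = 0
    heart_rate_bpm: float | None = None
    n_frames: int | None = None
    view_id: str = ""
    normal: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("origin", "row_cosine", "col_cosine", "spacing"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
        if self.origin.shape != (3,) or self.spacing.shape != (2,):
            raise ValueError("origin must be 3-vector, spacing 2-vector")
        if np.any(self.spacing <= 0):
            raise ValueError("pixel spacing must be strictly positive")

        r, c = self.row_cosine, self.col_cosine
        err = max(abs(np.linalg.norm(r) - 1.0), abs(np.linalg.norm(c) - 1.0),
                  abs(float(r @ c)))
        if err > _ORTHO_FAIL_TOL:
            raise ValueError(
                f"direction cosines not orthonormal (deviation {err:.2e})")
        if err > 0:
            # one Gram-Schmidt step absorbs header rounding
            r = r / np.linalg.norm(r)
            c = c - (c @ r) * r
            c = c / np.linalg.norm(c)
            object.__setattr__(self, "row_cosine", r)
            object.__setattr__(self, "col_cosine", c)
        object.__setattr__(self, "normal",
                           np.cross(self.row_cosine, self.col_cosine))

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 matrix mapping homogeneous pixel coords (i, j, 1) to mm."""
        return np.column_stack([
            self.row_cosine * self.spacing[0],
            self.col_cosine * self.spacing[1],
            self.origin,
        ])


def image_to_patient(g: PlaneGeometry, p) -> np.ndarray:
    """Map pixel coordinates ``(i, j)`` (column, row; zero-based) to mm.

    Sub-pixel coordinates are allowed and points need not lie inside the
    image bounds.  Accepts a single (2,) point or an (N, 2) array.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pixel coordinates must be finite")
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    if pts.shape[-1] != 2:
        raise ValueError("expected (i, j) pixel coordinates")
    hom = np.column_stack([pts, np.ones(len(pts))])
    q = hom @ g.matrix.T
    return q[0] if single else q


def patient_to_image(g: PlaneGeometry, q):
    """Project 3D point(s) onto the plane; return pixel coords and distance.

    Returns ``(p, d)`` where ``p`` is the orthogonal in-plane projection
    expressed in ``(i, j)`` pixel coordinates and ``d`` the signed distance
    (mm) along the plane normal ``row_cosine x col_cosine``.  Round-tripping
    an in-plane point through :func:`image_to_patient` is exact to 1e-9 mm.
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("patient coordinates must be finite")
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    rel = pts - g.origin
    i = rel @ g.row_cosine / g.spacing[0]
    j = rel @ g.col_cosine / g.spacing[1]
    d = rel @ g.normal
    p = np.column_stack([i, j])
    if single:
        return p[0], float(d[0])
    return p, d


def plane_intersection_points(g1: PlaneGeometry, g2: PlaneGeometry,
                              contour, tol_mm: float) -> np.ndarray:
    """Indices of ``contour`` points (pixels in ``g1``) within ``tol_mm`` of plane ``g2``.

    Used to decide which tracked points of one view are shared with another
    view (and may therefore be fused): a point participates when it lies
    close to the second plane, i.e. near the two planes' intersection line.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.size == 0:
        raise ValueError("contour must be non-empty")
    q = image_to_patient(g1, contour)
    _, d = patient_to_image(g2, q)
    return np.flatnonzero(np.abs(np.atleast_1d(d)) <= tol_mm)


# ---------------------------------------------------------------------------
# I/O: JSON sidecar and DICOM series

def load_sidecar(path) -> PlaneGeometry:
    """Read a JSON sidecar carrying plane geometry for non-DICOM fixtures.

    Schema: ``{origin, row_cosine, col_cosine, spacing, shape,
    heart_rate_bpm, n_frames}`` with shape = [n_rows, n_cols].
    """
    with open(path) as f:
        d = json.load(f)
    shape = d.get("shape", [0, 0])
    return PlaneGeometry(
        origin=np.asarray(d["origin"], float),
        row_cosine=np.asarray(d["row_cosine"], float),
        col_cosine=np.asarray(d["col_cosine"], float),
        spacing=np.asarray(d["spacing"], float),
        n_rows=int(shape[0]),
        n_cols=int(shape[1]),
        heart_rate_bpm=d.get("heart_rate_bpm"),
        n_frames=d.get("n_frames"),
        view_id=d.get("view_id", Path(path).stem),
    )


def save_sidecar(g: PlaneGeometry, path) -> None:
    d = {
        "origin": g.origin.tolist(),
        "row_cosine": g.row_cosine.tolist(),
        "col_cosine": g.col_cosine.tolist(),
        "spacing": g.spacing.tolist(),
        "shape": [g.n_rows, g.n_cols],
        "heart_rate_bpm": g.heart_rate_bpm,
        "n_frames": g.n_frames,
        "view_id": g.view_id,
    }
    with open(path, "w") as f:
        json.dump(d, f, indent=1)


def read_dicom_series_geometry(paths) -> PlaneGeometry:
    """Extract plane geometry, heart rate and frame count from a cine series.

    All files must share one image plane (a single-slice cine).  Heart rate
    is read from (0018,1088) when present.
    """
    import pydicom

    paths = sorted(Path(p) for p in np.atleast_1d(paths))
    ds = pydicom.dcmread(str(paths[0]), stop_before_pixels=True)
    iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
    return PlaneGeometry(
        origin=np.asarray([float(v) for v in ds.ImagePositionPatient]),
        row_cosine=iop[:3],
        col_cosine=iop[3:],
        # DICOM Pixel Spacing is (row spacing, column spacing) =
        # (between-rows d_j, between-columns d_i); reorder to (d_i, d_j)
        spacing=np.asarray([float(ds.PixelSpacing[1]),
                            float(ds.PixelSpacing[0])]),
        n_rows=int(ds.Rows),
        n_cols=int(ds.Columns),
        heart_rate_bpm=float(ds.HeartRate) if "HeartRate" in ds else None,
        n_frames=len(paths),
        view_id=getattr(ds, "SeriesDescription", ""),
    )
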