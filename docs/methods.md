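# Methods

`cardiofuse` estimates the 3D motion of left-ventricular (LV) myocardial
points from several routine 2D cine CMR sequences — a short-axis (SA) stack
and 2-/3-/4-chamber long-axis (LA) views — none of which sees the full 3D
motion on its own.  The processing chain is: per-view 2D tracking by
diffeomorphic moving-mesh registration, mapping of pixel trajectories into
the patient 3D frame via the DICOM plane geometry, temporal smoothing with a
cyclic-dynamics unscented Kalman smoother (UKS), and maximum-likelihood (ML)
track-to-track fusion of per-view state estimates of the same tissue point.
Regional wall-motion classification is built on the fused tracks.

## Plane geometry

A view's pose is given by Image Position (Patient) `S`, the row/column
direction cosines `X`, `Y` and the pixel spacing `(d_i, d_j)`.  Pixel
`(i, j)` (column, row; zero-based) maps to millimetres as
`q = S + i d_i X + j d_j Y`.  The inverse map returns the orthogonal
in-plane projection plus a signed out-of-plane distance along `X x Y`.
Direction cosines from real headers are rounded: deviations from
orthonormality up to 1e-4 are repaired by one Gram–Schmidt step, beyond
1e-2 the geometry is rejected.  A JSON sidecar mirrors the DICOM attributes
for non-DICOM fixtures.

## Moving-mesh registration

The transformation between adjacent frames is parameterized by the monitor
function `mu > 0` (mean 1 over the grid) and the curl `gamma` of an end
velocity field.  Given `(mu, gamma)`:
a vector field `rho` solves `div rho = mu - 1`, `curl rho = gamma` with
`rho = 0` on the boundary; the velocity `nu_t = rho / (t + (1-t) mu)` is
integrated from the identity over `t in [0, 1]` (RK4, 10 steps, bilinear
field sampling) to give the map `phi`, whose Jacobian determinant equals
`mu` by construction.  Clamping `mu` to `[0.5, 2]` and rescaling to mean 1
therefore guarantees a fold-free (diffeomorphic) map at every iterate.

Numerics worth knowing:

* **div–curl solve.**  Centered-difference divergence and curl at interior
  nodes plus the Dirichlet rows form a square sparse system solved through
  pre-factorized normal equations (one LU per grid shape, reused across
  iterations; a 1e-12 Tikhonov term guards near-null checkerboard modes).
  For compatible smooth data the interior residuals are at machine level
  and the recovered field converges at second order; the boundary condition
  is honored approximately (least squares), as the continuous problem
  prescribing both components on the whole boundary is formally
  overdetermined.
* **Optimization.**  The L2 dissimilarity `sum (T_{k+1}(phi(x)) - T_k(x))^2`
  is minimized by gradient descent on `(mu, gamma)` with step halving and a
  3-level coarse-to-fine pyramid (Gaussian sigma 1 px per level; `mu`,
  `gamma` are resolution-invariant and are simply upsampled).  The gradient
  uses the small-deformation adjoint (`phi ~ x + rho`), which is only
  approximate for large `|mu - 1|`; correctness does not depend on it
  because the line search evaluates the true energy through the full flow,
  so accepted iterates never increase the energy.  Convergence: relative
  energy change < 1e-4 or 200 iterations per level.  Constant images yield
  a zero gradient and return the identity immediately.
* **Direction convention.**  `phi` maps frame-k coordinates to frame-(k+1)
  coordinates, so trajectories advance forward in time by composing
  adjacent-frame maps with bilinear sub-pixel sampling.  `gamma` is a free
  optimization variable by default (it can be pinned to zero).

## Cyclic dynamics and unscented smoothing

Each tracked point follows three per-axis harmonic oscillators about their
mean positions with a shared, slowly varying angular frequency `omega`:
state `s = [x_bar, x, x_dot, y_bar, y, y_dot, z_bar, z, z_dot, omega]`.
The per-axis transition over a frame interval `T` is

    F = [[1, 0, 0],
         [1 - cos(wT),  cos(wT),  sin(wT)/w],
         [w sin(wT),   -w sin(wT), cos(wT)]]

(the `w -> 0` limit is the constant-velocity block), the full transition
`blkdiag(F, F, F, 1)`.  `F` has eigenvalues `{1, e^{+-iwT}}` and conserves
the oscillator invariant `w^2 (x - x_bar)^2 + x_dot^2`.  Only the three
positions are observed.  The measurement-model block structure nominally
carries a fourth row for `omega`, but the measurement noise covariance is
3x3, so the self-consistent 3-row (positions-only) reading is implemented.

Because `F` depends on the state's own `omega`, estimation uses the UKF and
its fixed-interval Rauch–Tung–Striebel smoother with the scaled unscented
transform (defaults `alpha = 0.1`, `beta = 2`, `kappa = 0`; the transform
is exact for the linear frozen-`omega` case regardless of `alpha`).  The
measurement update is performed in closed form (the model is linear in the
observed positions), in Joseph form.  Covariance square roots fall back
from Cholesky to an eigendecomposition when a component is deliberately
frozen to zero variance, and to jitter (`1e-9 trace I`, at most 3 attempts)
only for roundoff-indefinite matrices.  Negative-`omega` sigma points are
reflected (`|omega|`): the frequency's sign is unidentifiable.

Noise defaults: per-axis white-noise-acceleration blocks of intensity
`q_pos = 1 mm^2/s^3`, mean-position drift `1e-4 q_pos`, frequency random
walk `q_omega = 1e-2 rad^2/s^3`; measurement variance
`r = (0.5 max pixel spacing)^2` (half-pixel tracking noise).  Frames are
assumed uniformly spaced: `T = (60/HR)/K` from the DICOM heart rate and
frame count; the frequency prior is one oscillation per beat,
`omega_0 = 2 pi HR / 60`, with 20% relative prior SD.  Initial means are
the temporal trajectory means (the full record is available
retrospectively), positions the frame-1 values, velocities the first
forward difference.

In the multi-view pipeline each view's 3D measurements are back-projections
of 2D pixel positions, so they carry no through-plane information; the
view's 3x3 measurement covariance is accordingly anisotropic — `r` in-plane
and `1e4 r` along the plane normal.  Calibration was checked by Monte
Carlo: on model-generated tracks the pooled normalized estimation error
squared of the smoothed positions sits inside the 95% chi-square band.

## Track-to-track fusion

Two smoothed estimates `(s_a, P_a)`, `(s_b, P_b)` of the same point are
combined as `s = P_b (P_a + P_b)^{-1} s_a + P_a (P_a + P_b)^{-1} s_b`,
the ML solution under independent Gaussian errors (zero cross-covariance
between views).  The fused covariance is the corresponding Fisher
information, `(P_a^{-1} + P_b^{-1})^{-1}`; it is never larger than either
input in the Loewner order.  M-track fusion uses the same
inverse-covariance weighting; a general two-track form retaining the
cross-covariance exists as a verification path only.  All 10 state
components are fused, `omega` included — it sits in the state vector and
its per-view estimates are legitimately combinable.

Correspondence between views is geometric: tracks are paired when their
smoothed *mean* (anatomical) positions agree within 3 mm and each lies
within 3 mm of the other view's plane, greedily by distance, one-to-one per
view pair, then merged into groups.  Matching on the beat-mean position
rather than a single frame makes the association insensitive to cardiac
phase and to through-plane excursion within the beat (frame-1 positions of
the same point can disagree by several millimetres between views, because a
view's 3D back-projection pins the out-of-plane coordinate at the plane).
Tracks of unequal length are linearly resampled (means and covariances) to
a common normalized-phase grid before frame-wise fusion.

## Synthetic phantom

The phantom is the package's test bed and defines its study conditions.
Myocardial points sit on rings of a prolate ellipsoid (semi-axes
25 x 25 x 45 mm) at the SA slice levels -10/0/+10 mm (10 mm slice spacing,
as in clinical stacks) and move as one harmonic per axis,
`p(t) = p_mean + A cos(omega t)`, composing:

* radial contraction, default fraction 0.15 of the local radius;
* apex-referenced longitudinal shortening, default 0.06 of the
  apex-to-point distance (the apex is nearly stationary in real hearts and
  the base descends toward it — about 11 mm of basal peak-to-peak
  excursion, matching mitral-plane displacement);
* twist varying linearly from zero at the base to 10 degrees at the apex.

Defaults: 72 bpm, `omega` consistent with the heart rate, K = 20 frames,
48 points per ring, 0.5 mm in-plane measurement noise.  Because every axis
is a single harmonic, the motion lies exactly in the smoother's model
class, making frequency/position recovery well-posed; a two-harmonic
"misspecified" mode exists for robustness experiments.  The default
acquisition is 3 SA planes plus 3 LA planes at 0/60/120 degrees about the
long axis, 1 mm pixels; with 48 points per ring, each LA plane contains
exactly two points of each ring, giving 18 points seen by two views.
What the phantom does *not* emulate: MR physics (no k-space, no tag
lines), non-harmonic strain patterns, breathing/patient motion between
series, and out-of-model measurement outliers — passing tests demonstrate
the estimation machinery, not robustness to those effects.

For registration fixtures, a smooth random-blob texture masked to the
myocardial annulus is warped by the analytic in-plane motion of the chosen
plane (the in-plane component is affine per frame), and the true
adjacent-frame deformation fields are returned for scoring.

The classification cohort contains 20 subjects (13 normal, 7 abnormal —
roughly the 2:1 clinical mix), with anatomy and function jittered around
the defaults per subject; abnormal subjects carry one 90-degree hypokinetic
sector with amplitudes scaled to 30%.  A segment is labelled abnormal when
at least half of its points are hypokinetic — partial overlap between the
sector and segment boundaries makes some labels genuinely ambiguous, which
bounds attainable accuracy below 1.

## Regional features and classification

Contours of apical/mid/basal SA slices are divided into 4/6/6 equal-angle
segments about the cavity centroid, starting at the septal-insertion
landmark (the apex-cap segment of the 17-segment model is not represented
on these slices).  Per segment and frame, the mean radial distance to the
cavity centroid and the sector polygon area (shoelace formula; points put
in arc order so wedges crossing the angular seam cannot self-intersect)
are normalized by their frame-1 (end-diastolic) values; the Shannon
differential entropy (SDE) of each normalized series over the cycle is the
feature.  SDE uses a histogram estimator with Freedman–Diaconis bins and a
-10 nat floor for degenerate (point-mass) series; a Gaussian-KDE estimator
is available behind a flag.  Normalization by frame 1 makes both features
invariant to global translation, rotation and uniform scaling.

Separability of the normal/abnormal feature distributions is measured by
`B = sqrt(1 - sum_r sqrt(f_N(r) f_A(r)))` on shared bins.  Classification
is Gaussian naive Bayes on the two SDE features, fitted separately per
slice level (falling back to pooled levels when a training fold lacks a
class at some level), evaluated leave-one-subject-out with abnormal as the
positive class; ROC by threshold sweep on the posterior scores and
trapezoid AUC.  Binary labels only.

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen to exercise every code path:
registration benchmarks on 48x48 and 64x64 grids (3-level pyramid);
smoother studies at K = 20 frames, 50 seeds, 6 tracks per seed;
the multi-view advantage on 100 seeded phantom runs (6 views, 18 two-view
points each); Monte-Carlo calibration on 200 model-generated tracks; the
classification study on 20 synthetic subjects (320 segments).

## Known limitations

* No correction for patient motion between series: all views are assumed
  to share one patient frame.
* Greedy one-to-one correspondence; no multi-candidate association.
* Cross-covariance between views is fixed at zero in production fusion.
* Variable frame intervals within a cycle are not modelled (single `T`).
* The registration gradient is a small-deformation approximation; very
  large inter-frame displacements rely on the pyramid and line search.
* The SDE features summarize temporal variability only; they carry no
  phase information and are blind to dyssynchrony at preserved amplitude.
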