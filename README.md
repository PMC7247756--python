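# cardiofuse

3D left-ventricular (LV) motion estimation from routine 2D cine cardiac MR,
for researchers in cardiac image analysis.  Standard clinical cine CMR is
acquired as separate 2D planes — a short-axis (SA) stack and 2-/3-/4-chamber
long-axis (LA) views — and no single plane sees the through-plane component
of the heart's 3D motion.  `cardiofuse` tracks myocardial points in each
view, smooths the trajectories with a cyclic-dynamics model, and fuses the
per-view estimates of the same tissue point into one 3D track with a
calibrated covariance.  Regional wall-motion features and a normal/abnormal
classifier are built on top.

## Method

1. **Per-view tracking** — diffeomorphic moving-mesh registration between
   adjacent frames.  The map φ is parameterized by a monitor function μ > 0
   (its prescribed Jacobian determinant, mean 1) and the curl γ of an end
   velocity field: solve `div ρ = μ − 1`, `curl ρ = γ`, ρ = 0 on ∂Ω, then
   integrate `dψ/dt = ρ(ψ)/(t + (1−t)μ(ψ))` over t ∈ [0, 1].  Keeping μ in
   [0.5, 2] guarantees a fold-free map.  The L2 image dissimilarity is
   minimized over (μ, γ) on a 3-level pyramid.
2. **Geometry** — pixel (i, j) of a view maps to patient millimetres via
   the DICOM attributes: `q = S + i·Δᵢ·X + j·Δⱼ·Y`.
3. **Cyclic smoothing** — each point follows per-axis harmonic oscillators
   with shared, dynamic angular frequency ω: state
   `s = [x̄, x, ẋ, ȳ, y, ẏ, z̄, z, ż, ω]`, per-axis transition
   `F = [[1,0,0], [1−cos ωT, cos ωT, sin ωT/ω], [ω sin ωT, −ω sin ωT, cos ωT]]`.
   The model is nonlinear in ω, so an unscented Kalman filter and
   fixed-interval smoother (UKS) estimate mean and covariance per frame.
4. **Track-to-track fusion** — per-view estimates of the same point are
   combined by maximum likelihood under independent view errors:
   `s_ML = P_b(P_a+P_b)⁻¹ s_a + P_a(P_a+P_b)⁻¹ s_b`, fused covariance
   `(P_a⁻¹+P_b⁻¹)⁻¹`.
5. **Regional analysis** — AHA-style 4/6/6 segments on apical/mid/basal
   slices; Shannon differential entropy of normalized radial distance and
   sector area over the cycle; Gaussian naive Bayes, leave-one-subject-out
   ROC/AUC, and the Bhattacharyya separability
   `B = √(1 − Σ √(f_N f_A))`.

A built-in phantom (deforming ellipsoid with radial contraction,
apex-referenced shortening and twist, exactly one harmonic per axis)
generates geometry, noisy multi-view observations, textured image
sequences and classification cohorts with known ground truth.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from cardiofuse import pipeline

res = pipeline.run_pipeline(pipeline.RunConfig(seed=1))
rep = res["report"]
print(f"fused 3D RMSE: {rep['fused_rmse_mm']:.2f} mm")
for view, rmse in rep["view_rmse_mm"].items():
    print(f"  {view:8s} single-view {rmse:.2f} mm "
          f"-> fused {rep['fused_rmse_by_view_mm'][view]:.2f} mm")
```

Output:

```
fused 3D RMSE: 0.36 mm
  SA_z-10  single-view 1.52 mm -> fused 0.36 mm
  LA_0     single-view 1.58 mm -> fused 0.31 mm
  LA_60    single-view 1.58 mm -> fused 0.39 mm
  LA_120   single-view 1.58 mm -> fused 0.36 mm
  SA_z+0   single-view 1.93 mm -> fused 0.35 mm
  SA_z+10  single-view 2.36 mm -> fused 0.36 mm
```

The run generates a 6-view phantom (3 SA + 3 LA planes, 0.5 mm tracking
noise), smooths every view's trajectories, fuses the 18 points seen by two
views, and scores 3D position error against the analytic ground truth.
Single-view errors (1.5–2.4 mm) are dominated by the motion component
normal to each plane, which a 2D view cannot observe; fusing views with
different normals recovers it, cutting the error to ~0.36 mm — below the
in-plane measurement noise, thanks to the temporal smoothing.

The same stages are scriptable from the shell:

```bash
cardiofuse phantom --out fixture --seed 1        # sidecars + observations
cardiofuse run --out results --seed 1            # full pipeline + report
cardiofuse cohort --out features.csv --seed 0    # classification cohort
cardiofuse regional --features features.csv --out regional.json
```

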