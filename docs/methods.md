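# Methods

This note documents the models, algorithms and numerical choices behind
`perfph`, in the order the pipeline runs them, together with what the
synthetic phantoms do and do not establish about real data.

## 1. Digital phantom cohort (`perfph.synthetic`)

### Geometry

Each subject shares one grid (default 32×32×16 voxels at a nominal 2 mm).
The brain is a centered ellipsoid; the lesion is a set of concentric
ellipsoids displaced into one hemisphere — necrotic core (NC, label 1) inside
an enhancing-tumor rim (ET, label 4) inside an edema shell (ED, label 2),
BraTS-style labels. Concentric ellipsoids guarantee connected, non-empty
subregions at any grid size (a fallback assigns single voxels on grids too
small to rasterize the ellipsoids). All volumes of a subject are generated on
the same grid: co-registration, motion correction and segmentation are input
contracts of the pipeline, not simulated processes.

### Hemodynamic latents

Every brain voxel carries a latent vector (L, D, R, t0, k):

| latent | meaning | default range |
| --- | --- | --- |
| L | baseline signal level (a.u.) | 80–340 |
| D | relative bolus drop depth | 0.15–0.75 |
| R | recovery fraction after first pass | 0.50–0.95 |
| t0 | bolus arrival time (s) | baseline end + 0.75–3.75 s |
| k | bolus sharpness (gamma shape) | 2.5–4.5 |

L, D and R are all affine functions of a single per-voxel *severity*
u ∈ [0, 1]; each tissue class draws u from its own sub-interval (normal
0.25–0.55, NC 0.05–0.40, ED 0.35–0.75, ET 0.60–1.00), so ET has the highest
level and depth and NC the lowest level. t0 and k are jittered independently
of u.

Tying L, D, R to one severity scale is a deliberate identifiability choice.
Per-voxel normalization (below) removes level and depth from a curve, leaving
only its shape; the shared severity makes that residual shape (chiefly the
recovery plateau, which equals R exactly in the noise-free normalized curve)
informative about the level — the empirical signature that makes temporal PCs
of perfusion curves track tissue state. Note that R *increasing* with
severity is a phantom construction, not tumor physiology (contrast leakage in
enhancing tumor would depress recovery); the phantom trades physiological
nuance for a known, recoverable structure.

### DSC curve model

Signal–time curves follow

```
S(t) = L · [ 1 − D·g(t; t0, k) − D·(1−R)·c(t; t0, k) ] + ε
```

with `g` a unit-peak gamma-variate bolus, `g(t) = x^k · exp(k(1−x))`,
`x = (t−t0)/(tp−t0)`, time-to-peak `tp = t0 + 12/k` seconds, and
`c(t) = 1 − g(t)` for t ≥ tp (zero before) — a smoothed step modelling
incomplete recovery from leakage. This parameterization makes three exact
closed forms hold simultaneously for every R: baseline E[S] = L before t0, a
minimum of exactly L·(1−D) at the bolus peak, and a late plateau of exactly
L·(1−D·(1−R)). ε is i.i.d. Gaussian with SD `noise_sd_dsc · L`.

`noise_sd_dsc` defaults to 0.003 (0.3% of baseline): the phantom emulates the
*denoised, smoothed* curves a clinical pre-processing chain hands to the
analysis, which is also the regime in which the documented property of the
method holds on the default cohort — seven temporal PCs capture ≥ 99% of the
normalized-curve variance. At raw-acquisition noise levels (~1–2%) the
post-normalization noise floor spreads variance across all timepoints and
seven components capture ~96%; users probing that regime can set the noise
accordingly.

### z-spectrum model and acidity link

Saturated signal at offset ω (ppm from water):

```
Z(ω) = 1 − Σ_p A_p · (Γ_p/2)² / ( (Γ_p/2)² + (ω − δ_p − b0)² )
```

with three Lorentzian pools: direct water saturation (δ=0, A=0.82,
Γ=1.4 ppm), a broad symmetric MT-like background (δ=0, A=0.06, Γ=40 ppm) and
the pH-sensitive amine pool (δ=+3.0, Γ=1.0 ppm). No NOE pool is included, so
an acidity-free spectrum is exactly symmetric and the MTR_asym null is exact.
Amplitudes summing above 1 (negative signal) are rejected. S0 = 1 a.u.;
Gaussian noise of SD `noise_sd_cest` (default 0.005) is added to every
saturated sample and to S0.

True acidity lives on the fractional MTR_asym scale:

```
acidity = 0.08 · ( 0.35·nL + 0.30·D + 0.35·(1−R) ),   nL = clip((L−60)/300, 0, 1)
```

monotone increasing in level and depth and decreasing in recovery, plus
optional Gaussian scatter `link_noise_sd` (default 0.003, clipped to
[0, 0.1]). The amine amplitude is `acidity / w_cal`, where the calibration
constant `w_cal` is the window asymmetry of a unit-amplitude amine line on
the standard offset schedule (computed in closed form at import); with
symmetric pools cancelling exactly, a noise-free B0-free acquisition
quantifies to MTR_asym = acidity identically. Default noise levels put the
default cohort in a realistic performance regime (cohort-mean union Spearman
≈ 0.7 between constructed and actual maps).

### Offset schedule and B0 field

The saturation schedule is 29 unique offsets: −3.5…−2.5 ppm (negative
shoulder), −0.3…+0.3 ppm (water window) and +2.5…+3.5 ppm (amine shoulder),
each in 0.1 ppm increments (11 + 7 + 11). The B0 field is a random quadratic
polynomial in normalized coordinates, rescaled so its maximum magnitude over
the brain equals `b0_amplitude_ppm` (default 0.2) — smooth, spatially
structured, and inside the ±0.3 ppm water window where it must be estimable.

Generation is bit-deterministic given the config: subject i uses
`SeedSequence(seed, spawn_key=(i,))`, so cohorts are reproducible across
platforms and subjects are independent of cohort size.

## 2. CEST quantification (`perfph.cest`)

### B0 estimation

1. S0-normalized in-mask z-spectra are clustered with seeded K-means
   (default 8 clusters; non-finite spectra are flagged and excluded; an error
   is raised if fewer usable voxels than clusters).
2. Each cluster centroid is fitted with a constant baseline minus a
   Lorentzian dip (baseline, amplitude, half-width, center), bounded
   nonlinear least squares with analytic Jacobian; the center is bounded to
   the water window ±0.3 ppm.
3. Every voxel is then refitted from its cluster's solution with a *profiled*
   1-D fit: the width is held at the cluster value, and for each candidate
   center the baseline and amplitude are solved in closed form; the center is
   found by bounded scalar minimization (xatol 1e−12).

The fit uses the water-window points only. This is deliberate: the window is
symmetric about 0 ppm, so on a symmetric spectrum the profiled objective is
symmetric and the estimated center is exactly unbiased — the property that
makes the MTR_asym null hold to 1e−13 ppm. Including the shoulders breaks
this: the amine resonance sits inside the positive shoulder and a free-width
Lorentzian broadens to chase it (measured center error up to ~0.17 ppm),
while a one-sided shoulder biases the center ~1e−5 ppm even on symmetric
spectra through the background-pool mismatch. The profiled per-voxel fit also
cures a numerical failure of the joint trust-region fit, which stalls
~1e−5 ppm from the optimum on the shallow center valley. Voxels whose
refinement fails (no dip, non-finite, center pinned at the ±0.3 ppm bound)
fall back to the cluster-level center and are flagged.

On noise-free phantoms, a constant 0.2 ppm shift is recovered with worst-case
voxel error ~5e−4 ppm across the generated acidity range; at the default
CEST noise the per-voxel error is ~0.01 ppm RMS.

### Spectral correction and MTR_asym

The corrected value at nominal offset ω is the measured spectrum interpolated
at ω + b0 — cubic within the densely sampled water window, linear in the
shoulders. Nominal offsets whose shifted position leaves the sampled support
(contiguous ranges, a gap > 0.15 ppm breaks support) are marked missing; for
|b0| ≤ 0.3 ppm the ±3 ppm integration windows always remain fully sampled.
A zero shift is an exact identity, so correction is idempotent.

The "integral" of the 0.4 ppm window around ±3.0 ppm is the *mean* of its
sampled points (5 points at 0.1 ppm spacing, ±2.8…±3.2; missing points are
dropped, an empty window excludes the voxel). On a uniform grid the trapezoid
and the mean differ by a constant factor common to both windows; the mean
keeps the value on the conventional dimensionless MTR_asym scale. Finally

```
MTR_asym = ( W(−3) − W(+3) ) / S0
```

with W in raw signal units — the subtraction sits over the common S0
denominator, the only reading that is dimensionless. Voxels with
non-positive S0 are excluded. Mirroring every spectrum about 0 ppm (and
negating the B0 map) negates the map to machine precision.

## 3. Curve normalization and temporal PCA (`perfph.pca`)

Per voxel: (1) baseline = mean of the pre-bolus frames (count from metadata,
or auto-detected as the frames preceding the steepest drop of the mask-mean
curve minus a 2-frame margin, floor 3); (2) the curve is divided by its
baseline; (3) shifted by an integer number of frames so its global minimum
lands on a common target index — the median minimum index of the call's
voxels by default, or a cohort-level target supplied by the pipeline (median
of per-subject medians) so all subjects share one time axis; edge frames are
replicated; (4) affinely pinned so that the post-shift baseline mean maps to
1 and the minimum to 0. Both pins are exact by construction. Integer-frame
alignment avoids the implicit smoothing of sub-frame interpolation. Voxels
with non-positive baseline or no detectable bolus (minimum above
1 − `bolus_margin`, default 0.05) are excluded and recorded. Normalized rows
are invariant to any positive rescaling of the raw curve.

PCA is fitted on a stratified sample — up to `per_roi_sample` (default 1000)
voxels per tumor subregion per subject, drawn without replacement with full
(subject, ROI, voxel) provenance — pooled across all subjects and ROIs into
one cohort-level basis, then applied to every voxel. The decomposition is a
plain SVD of the mean-centered sample; components are ordered by decreasing
variance and each component's sign is fixed so its largest-magnitude loading
is positive, making results platform-reproducible. Rank-deficient input
yields fewer components (error in strict mode); an all-identical sample is a
flagged zero-model (or an error in strict mode). Per-voxel score maps are
`C·(x − mean)` with NaN at excluded voxels.

On the default cohort the first seven components capture ≥ 99% of the sample
variance, and the first PC score orders voxels by latent perfusion level
(Spearman ρ ≈ 0.98 noise-free) through the severity link described above.

## 4. Per-ROI SVR and LOSO evaluation (`perfph.regression`)

For each subregion an ε-insensitive SVR with Gaussian (RBF) kernel maps the
seven PC scores to MTR_asym. Features are standardized by training-fold
mean/SD (the same transform applied at prediction — fold-internal, so no
leakage). The kernel scale is set automatically to the median pairwise
Euclidean distance among ≤ 2000 seeded-subsampled training rows (a standard,
deterministic stand-in for proprietary auto-scale heuristics); the box
constraint defaults to 1.0 and ε to iqr(targets)/13.49 (a tenth of a robust
SD). Training requires ≥ 10 rows and non-degenerate features.

LOSO cross-validation (≥ 3 subjects): for each held-out subject, the three
ROI models are trained on the *other* subjects' sampled voxels (up to
`svr.subsample` = 200 per ROI per subject, a fixed per-subject sample reused
across folds, rows in canonical sorted order so results are independent of
voxel enumeration); the held-out subject's voxels are predicted by the model
of their own ROI only and stitched into a constructed map over ET ∪ NC ∪ ED.
A subject missing an ROI simply contributes nothing to that stratum (logged).
Fold provenance (training subject lists) is emitted for leakage audits.

Agreement is Spearman rank correlation over paired valid voxels, per ROI and
over the union, per subject; regions with < 3 pairs are not evaluable. The
p-value uses the large-sample t approximation, or the exact permutation
distribution below 10 voxels. The cohort summary is the *unweighted mean of
per-subject r* (subjects count equally, regardless of lesion size), not the
pooled-voxel correlation.

## 5. Pipeline and reproducibility (`perfph.pipeline`)

One master seed derives all stage seeds (phantom, K-means, sampling, SVR)
through `SeedSequence`; identical configs give byte-identical summaries. The
run directory materializes the full config, per-stage library versions, a
config hash, voxel-funnel accounting (generated → masked → valid → sampled →
predicted) and the cumulative explained-variance curve with the component
count needed to reach `variance_target` (0.99). By default MTR_asym is
quantified only over the ROI union, where it is consumed; full-brain
quantification is a config switch (`cest.restrict_to_rois: false`).

## 6. Scope of the phantom evidence, and limitations

Passing tests establish that the *algorithms* are correct and the chain is
leak-free and deterministic: exact nulls, known-field recovery, oracle
equivalence of the PCA, and recovery of a deterministic hemodynamics→acidity
link through the full LOSO pipeline (union ρ ≥ 0.95 noise-free, degrading
monotonically with link scatter). They do **not** establish clinical
performance: the phantoms have no MR physics (relaxation, coil profiles, EPI
distortion), no motion or registration error, no partial-volume mixing, a
literal low-order B0 field, identical latent distributions across subjects,
and an acidity link far simpler than tumor biology. The published-scale
correlations reproduced by the default cohort reflect the chosen noise
levels, not validated biology.

Default problem sizes (32×32×16 grids, 60 frames, 12 subjects; reduced
cohorts for the noise-sweep tests) were chosen so the full suite runs on a
laptop-class single CPU in minutes while keeping every ROI population large
enough for stable fits.
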