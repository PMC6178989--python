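# Methods

## Conventions and data model

All times are minutes (BIDS sidecar seconds are converted on read), all
activities kBq/mL. Volumes are NIfTI with 0-based voxel indices and RAS-mm
world coordinates through the affine. Input PET is assumed decay-corrected,
as is standard for reconstructed research PET; no decay handling exists
anywhere in the package. Label volumes reserve 0 for background; region
names travel in a BIDS-style `*_dseg.tsv` lookup because NIfTI cannot carry
them.

## Coregistration

The rigid transform has six parameters: rotations in degrees about x, y, z
(intrinsic, applied z → y → x) about the moving volume's intensity center
of mass, and translations in mm. It is fit by maximizing normalized mutual
information NMI = (H(A)+H(B))/H(A,B) of the joint intensity histogram
(64 bins, intensity range the 1st–99th percentile inside the mask, values
outside clipped into the end bins).

The fit is hierarchical. Stage 0 aligns intensity centers of mass
(translation only). Stage 1 registers the binary head masks as 0/1 images
through the coarse pyramid levels (8, 4 mm FWHM Gaussian smoothing with
matched grid decimation). Stage 2 refines on the intensity images through
8, 4, 2 mm, with the histogram restricted to the union of the two head
masks. Each level runs a Powell coordinate search (parameter tolerance
1e-3, ≤200 evaluations) — chosen because NMI under hard binning is not
smooth enough for gradient methods. Steps whose mask overlap falls below a
floor return a large penalty rather than an error, so the optimizer simply
retreats. The PET mask defaults to Otsu thresholding of the time-weighted
average, largest connected component, morphological closing; a T1 brain
mask should be supplied (brain extraction is out of scope) and otherwise
falls back to the same Otsu construction.

The pyramid schedule and optimizer are this package's own design, validated
by self-recovery: misregistrations up to 10 mm / 8° are recovered within
1 mm / 1° on phantoms (typically within 0.1 mm / 0.1°), and the achieved
NMI dominates 100 seeded random perturbations.

## Partial-volume correction

`gaussian_blur` is separable Gaussian convolution with zero-padded
boundaries (σ = FWHM / 2√(2 ln 2)); it conserves total activity for
support ≥3σ from every edge. The PSF is assumed Gaussian and spatially
invariant.

**GTM.** W_ij is the mean over region i's voxels of the blurred indicator
of region j; background is always included so that, for regions clear of
the volume edge, rows sum to 1 (the indicators partition unity). Per frame
the linear system W t = o is solved directly; the condition number is
monitored and the solve refuses above 1e8 ("merge regions"). No
non-negativity constraint is imposed; negative recovered activities are
returned as-is so they remain visible downstream. On any noiseless
piecewise-constant phantom blurred with the matched PSF the inversion is
exact up to solver tolerance — this is the mechanism behind corrected
recovery ratios near 1.

**idSURF-style deconvolution.** Van Cittert iteration
f ← S[f + α(g − G f)] from f = g, with S a Gaussian kernel (default
2.5 mm FWHM) renormalized over same-label neighbors. Defaults: 10
iterations, α = 1, stop when the relative update < 1e-4. The published
method's exact update lives in its own reference; this is a faithful
reconstruction of the qualitative description (iterative deconvolution,
anatomically constrained smoothing), not a bit-match, and all three knobs
are exposed in the config.

## Kinetic quantification

All running integrals are 0-anchored trapezoids on frame mid-times (the
curve is taken as 0 at t = 0); arterial input curves are linearly resampled
to frame mid-times first.

* **Logan**: OLS of ∫₀ᵀC_t/C_t(T) on ∫₀ᵀC_in/C_t(T) for mid-times ≥ t*
  (default 20 min). Slope = DVR with a reference input (BPnd = DVR − 1
  reported), V_T with an arterial input. The k2′ correction term is
  omitted (reduced Logan); with slow kinetics this biases DVR low when t*
  precedes late-time linearity — a documented limitation. No automatic t*
  search.
* **Patlak**: OLS of C_t(T)/C_in(T) on ∫₀ᵀC_in/C_in(T), T ≥ t*; slope Ki
  (min⁻¹), intercept V.
* **SRTM**: basis functions B_{k2a} = C_ref ⊛ e^{−k2a t}, computed exactly
  for a piecewise-linear C_ref on the nonuniform frame grid (per-segment
  closed form, recursively accumulated). For each k2a on a 30-point
  log-spaced grid in [0.01, 1] min⁻¹ the two linear coefficients are solved
  by least squares; the SSE-minimizing k2a is then polished by a bounded
  1-D search between its grid neighbours, because the raw grid spacing
  (~17% per step) is coarser than the 3% parameter-recovery contract.
  A boundary optimum raises a warning ("grid does not bracket optimum").
* **SUVR**: ratio of duration-weighted mean activities over a late window;
  the window is a required configuration input (no universal default
  exists across tracers).

Voxelwise maps apply the chosen model per voxel TAC; voxels failing a model
precondition are set to 0 and marked in a failure mask, never interpolated.

## Automated QC

Per stage the similarity trio is CC, MI, FSE between the static PET and the
resampled T1 (coregistration) or between stage input and output volumes
(PVC — an extension beyond the coregistration trio, which is the anchored
case). Across subjects, each (stage, metric) sample is fit with a
Gaussian-kernel KDE, bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5),
evaluated on a wide grid (at least [min−3h, max+3h]; wider in practice so
the tail integral is not truncated). The outlier score of value x is the
lowest-density-region tail probability p(x) = ∫_{f(u)≤f(x)} f(u) du.

Two finite-sample details matter for flagging. First, a subject is scored
against the KDE of the *other* subjects (leave-one-out): if its own kernel
is included, an arbitrarily gross outlier still carries its own 1/n
probability mass and can never fall below a 0.05 threshold in cohorts of
~20 — the score saturates rather than shrinking with distance. Second, the
raw leave-one-out score is anti-conservative for ordinary sample extremes,
so the add-one correction p = (1 + (n−1)·p_raw)/n is applied, the standard
conformal adjustment that makes the score a valid p-value: a gross outlier
scores 1/n (< 0.05 for n ≥ 21) while null cohorts flag well below the
nominal rate. Flag threshold 0.05, configurable; metrics are flagged
independently with no multiple-testing correction, matching per-metric
review practice. Zero-spread samples yield a degenerate sentinel model that
flags nothing. Cells with fewer than 5 subjects are skipped with a warning.

## Reporting

Results are long-format ("vertical") CSV, one value per row, header
`sub,ses,task,run,stage,region,metric,value`, deterministic ordering,
failed fits as empty cells so group n stays auditable. Group descriptives
(mean, sd, min, max, n; sd = 0 for singletons) are keyed by any subset of
subject/session/task.

## Synthetic phantom

The generator emulates a simulated-PET validation: scanner physics
(scatter, randoms, attenuation, reconstruction) is deliberately replaced by
Gaussian PSF blur plus frame-dependent Gaussian noise, because the object
under test is the pipeline's inversion behavior, not scanner realism.
Consequences: passing tests demonstrate correct geometry, correct PVC
inversion and correct kinetic fitting under the stated noise model; they do
not speak to reconstruction artifacts, motion, attenuation errors or
non-Gaussian PSFs in real data.

Geometry (2 mm grid, 48×56×48): cortical shell (outer semi-axes
34×40×32 mm, inner scale 0.8), putamen-like ellipsoid 12.4×8.8×8.8 mm
(~4.0 cm³), caudate-like 10×7×7 mm, cerebellum-like 11×8×8 mm, and a white
matter-like filler; every labeled voxel sits ≥3σ of the 6.5 mm PSF from the
grid edge. Frame schedule 6×0.5, 4×3, 12×4 min (~63 min).

Tracer archetypes (parameters are declared stand-ins chosen by kinetic
class, since no empirical TAC tables are built in): gamma-variate reference
A·t^b·e^{−t/τ} (peak 20 kBq/mL at 15 min; b = 1, τ = 15); FDG-like =
2.0 × reference (exact SUVR 2); FDOPA-like irreversible
C = Ki·∫C_ref + V·C_ref (Ki = 0.01 min⁻¹, V = 1; exactly Patlak-linear
under the package's integration rule, so the generating Ki is the exact
ground truth); raclopride-like reversible SRTM kinetics (R1 = 1,
k2 = 0.1 min⁻¹, BPnd = 2.0) integrated by RK4 on a ≤0.01-min grid and
frame-averaged. The filler carries 0.5 × reference.

Noise: per voxel, zero-mean Gaussian with sd = noise_scale·√(value/Δt).
The default noise_scale = 4.7 was calibrated once so the late-frame
regional-mean SNR of the putamen-like region is ≈20, the regime in which
GTM recovery stays within a few percent of unity. All outputs are pure
functions of (spec, seed).

Note on reversible kinetics: with k2a = k2/(1+BPnd) ≈ 0.03–0.04 min⁻¹ the
target/reference ratio does not reach the DVR within a ~60-min scan
(transient equilibrium); the equilibrium property is therefore verified on
a long (300 min) schedule with a slowly varying input, and graphical DVR
estimates at t* = 20 min on slow kinetics carry a known transient bias.

## Pipeline

Subject-level runs (coregister → resample labels → PVC → quantify) are
independent and deterministic given inputs + config; logs carry the
package version and a config hash rather than timestamps, so repeated runs
are byte-identical and can be diffed. The group level aggregates completed
subject directories (QC requires ≥5 subjects, otherwise it is skipped with
a warning while descriptives are still produced). Exit codes: 0 success,
1 configuration error, 2 at least one subject failed (others proceed).
Parallelism is the caller's: launch participant-level runs concurrently,
then run the group level once.

## Validation problem sizes

The built-in experiments run at desk scale by design: one anatomy shared
across noise realizations, 5-realization cohorts for recovery ratios
(reported values are cohort means, mirroring the across-subject averaging
of the original experiment), 21-subject cohorts × 20 repetitions for QC
injection (using a one-shot noisy static observation whose mean and
variance match the frame-wise model), and a 5-subject BIDS tree for the
determinism check.

## Known limitations

* No motion correction across frames; no decay correction.
* GTM assumes the label geometry is exact and the PSF known; a +20% PSF
  error biases small regions by ~10–15% (monotonically less for larger
  regions).
* Reduced Logan (no k2′) underestimates DVR when t* precedes late-time
  linearity.
* The QC trio for PVC/quantification stages is an extension point; only
  the coregistration trio is anchored in practice.
* The `.dft` reader supports a minimal text dialect (`start end activity`
  or `time activity` rows, `#` headers), not the full Turku format family.
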