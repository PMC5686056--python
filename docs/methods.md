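# Methods

This note documents the models, the parameter choices and the numerical
decisions behind `dcehabitat`, and what the synthetic phantom does and
does not establish about behavior on clinical data.

## Data model and conventions

A case is a 4D intensity array (x, y, z, t) with voxel spacing in mm and
a `TimeGrid` (frame times in seconds, strictly increasing from 0, plus
`n_pre`, the number of pre-contrast frames). Defaults mirror a common
clinical protocol: 12 frames at 30 s, 1.25 × 1.25 × 2.5 mm voxels,
`n_pre = 2`. All masks live on the same grid — the package never
resamples; aligning contours to the DCE grid is upstream work. Volumes
are reported in cc, times in seconds; intensities are arbitrary units and
are never rescaled implicitly. The number of pre-contrast frames is not
always recorded in clinical protocols; 2 is the package default and a
config knob everywhere it matters (baseline subtraction).

## Motion correction

Frames are corrected sequentially, each registered to its *corrected*
predecessor so corrections compose without re-introducing drift. The
transform is a 2D in-plane affine (translation in px, rotation in deg,
isotropic scale) applied identically to all slices, about the centroid of
the registration region — the prostate mask dilated slice-wise by
18.75 mm (15 px at 1.25 mm in-plane). Pelvic inter-frame motion is
dominantly in-plane at this slice thickness; a 3D transform was
deliberately left out of scope.

The similarity is mutual information from a 32 × 32 joint histogram of
the intensities inside the region, maximized by a deterministic
multi-start Powell search (identity plus ±2 px translations, 250
function evaluations per start). Three safeguards matter in practice:

* **Valid-overlap MI.** Resampled voxels that fall outside the grid are
  marked invalid (NaN fill) and excluded from the histogram; otherwise a
  constant fill region concentrates the histogram and produces spurious
  MI maxima at degenerate transforms (e.g. extreme shrink).
* **Plausibility bounds.** |shift| ≤ 8 px, |rotation| ≤ 10°,
  scale ∈ [0.80, 1.25]. Inter-frame pelvic motion beyond these is not
  physiological at 30 s spacing.
* **Identity tie-break.** The histogram MI is piecewise constant in
  noiseless data, so the optimizer can wander on flat plateaus. A
  non-identity transform is trusted only when it improves MI over the
  identity by ≥ 0.02 nats; otherwise the identity is returned. This makes
  motion-free noiseless series pass through bit-unchanged and rejects
  registrations of uncorrelated noise, while genuine sub-pixel shifts
  (MI gains ≳ 0.07) are still corrected.

A candidate correction is applied only when the SSD inside the region
strictly decreases (mean absolute difference is reported alongside).
Rejected corrections leave the frame untouched, so the output SSD never
exceeds the input SSD. On noisy series, accepted corrections include a
contribution from interpolation smoothing (resampling reduces the
moving frame's noise variance), so per-pair SSD improvements on noisy
phantoms overstate pure motion correction; the per-pair transforms in
the report are the honest measure. Pairs whose moving frame lies at
t ≥ 90 s carry a `paper_window` tag, matching the clinical convention of
quantifying motion from 90 s on (the first frames are pre-contrast and
enhancement-onset frames with intrinsically large intensity changes).

## NMF decomposition

Prostate voxel curves, baseline-corrected by the mean of the pre-contrast
frames and clipped at zero (the factorization needs a non-negative
matrix; at realistic SNR the clipping touches only noise), form
*D* (P × T). `run_nmf` factorizes *D* ≈ *W S* by multiplicative updates
on the Frobenius loss from a deterministic NNDSVD-style initialization
(`nndsvda`; the plain variant's exact zeros would lock multiplicative
updates). Stopping: relative loss change 1e−10 or 2000 iterations.

Two numerical points were decided empirically and are worth recording:

* **Solver choice.** Coordinate-descent NMF reaches lower Frobenius
  residuals, but on realistic curve sets — three smooth, strongly
  correlated tissue signatures — the factorization is near-degenerate and
  CD slides along the flat directions into rotated pattern mixtures,
  destroying the tissue separation that purity segmentation needs.
  Multiplicative updates stay close to the NNDSVD basin and keep the
  patterns tissue-separated; they are the default and only solver.
* **Identifiability.** Exact recovery of a constructed factorization
  (the test-suite oracle) is only well-posed when the factorization is
  unique; with overlapping smooth curves, zero-residual rotated solutions
  exist. The exact-recovery fixtures therefore use temporal signatures
  with disjoint active windows.

Patterns are normalized to unit maximum with weights rescaled so *W S*
is unchanged; all downstream logic is invariant to this convention, and
it keeps *W* in intensity units so weight maps are comparable across
cases with the same acquisition. The well-perfused pattern is the argmax
of trapezoidal AUC on t ∈ [0, 90] s (integration stops at the last frame
≤ 90 s if 90 s falls between frames; exact ties go to the lowest index,
with a warning). The pipeline default is a fixed k = 3; a data-driven
estimate (minimum of the Malinowski factor-indicator function on the PCA
eigenspectrum of *D*, clamped to [2, 5], eigenvalues below 1e−12 of the
largest treated as zero) is available by flag. The indicator is a
stand-in for the original significance rule, which is not fully
specified in the source literature.

## Segmentation

The β-purity rule includes voxel *i* iff
*W*<sub>wp,i</sub> / Σ<sub>m</sub> *W*<sub>m,i</sub> > β/100 (strict;
zero-total-weight voxels excluded), with β ∈ {40, 50, 60, 70} and default
60. Otsu thresholding (256-bin between-class variance on the positive
weights) is the alternative method. Cleanup removes 26-connected
components below 0.05 cc — the most permissive connectivity, so thin
lesions are not split across the 2.5 mm slice gap. A cleaned ROI below
0.5 cc is rejected (a normal terminal status, not an error). The whole
cleaned ROI is assigned to PZ iff its PZ-overlap fraction strictly
exceeds the configured fraction (default 10 %), else TZ — one zone per
case; NAT masks (zone minus ROI) are derived for both zones regardless
of the assignment so NAT reference features are always computable. The
single binary rule resolves the ambiguity of symmetric "and vice versa"
phrasing for intermediate fractions.

## Kinetic features

The ROI curve is reconstructed from the factors (mean of the ROI voxels'
weight rows times all k patterns), which denoises it; muscle and
biopsy-overlap curves are plain baseline-corrected voxel means (no
clipping, so negative noise excursions cancel in the average). The
bi-exponential model is the difference-of-exponentials form above —
fixed as a matched pair with the phantom generator, which is an
interpretation: "bi-exponential" is not a unique functional form. The
fit is bounded nonlinear least squares (s₀ ≥ 0, t₀ ∈ [0, 120] s,
k₁ ∈ (1e−4, 1], k₂ = r·k₁ with r ∈ [0, 0.999]) over five deterministic
starts; lowest RMSE wins, ties by smaller k₁. Derived quantities:
τ = ln(k₁/k₂)/(k₁−k₂), s<sub>m</sub> = model peak,
wo<sub>biexp</sub> = [S(t₀+τ) − S(t<sub>end</sub>)]/(t<sub>end</sub>−t₀−τ)
— the mean model slope from peak to last frame, positive under washout.
An instantaneous end-slope variant is available
(`fit_biexp(..., washout_slope="end")`); the mean slope is the default
because it is closed under the model and robust. With k₂ = 0 the model
plateaus: τ = ∞, wash-in 0, washout 0.

AUC windows are 60–120 s (early) and 240–330 s (late) on the measured
(piecewise-linear) curve with interpolated endpoints; AUFC uses the same
windows on the fitted model with 0.25 s trapezoid quadrature (1 s steps
leave >1e−4 relative error at fast uptake rates). The late linear model
is OLS on the frames in [270, 330] s; wash-out = −slope. Features are
computed on baseline-corrected curves throughout — consistent with the
factorization domain — so fitted s₀ near zero is expected and the
features are enhancement features.

Muscle normalization divides each feature by the muscle's value; a ratio
is flagged invalid when the muscle feature's magnitude is below
1e−6 × max|muscle curve| and propagates as NaN, never as an infinity.
Ratio features are invariant to global intensity scaling applied to both
curves — the property that motivates muscle normalization.

## Aggressiveness map and biopsy scoring

ω is the mean of *W*<sub>wp</sub> over the segmented ROI; the continuous
map is *W*<sub>wp,i</sub>·*F*/ω, which averages to *F* over the ROI by
construction (asserted to 1e−9 relative in the acceptance checks). The
1–10 scale is bounded by the 5th/95th empirical percentiles (linear
interpolation — the convention is declared inside the persisted JSON so
scales are portable) of a cohort's feature values; the bounded interval
is split into ten uniform half-open bins, top bin closed, with
out-of-range values pinned to 1 and 10. The bin-edge convention (left
edge of bin 1 scores 1, upper bound scores 10) is fixed here because
only the out-of-range rule is externally specified. Scales are persisted
artifacts fit once on a cohort; a per-case self-scale exists for demos
and is labeled non-canonical. Voxels with zero well-perfused weight
carry the background sentinel 0, never a 1–10 score.

Biopsy tracks are intersected with the ROI (usROI); features use the
average raw signal in the usROI (reconstructed mode by flag), and the
map mean is taken over the biopsy track within the prostate. Empty
intersections are flagged and excluded from feature statistics.

## Statistics

Spearman ρ uses average ranks for ties with a t-approximation p-value; an
exact permutation p-value (full enumeration) is available for n ≤ 10.
ROC AUC is the Mann–Whitney statistic with half credit for ties,
aggressive (GS ≥ 7) as the positive class. Both are checked against
brute-force oracles (exhaustive permutations; all-pairs counting) in the
test suite. Gleason groupings: {6, 3+4, >3+4} → {1, 2, 3} and
{6, 3+4, 4+3, 8–10} → {1, 2, 3, 4}; a patient's label is the highest GS
of the session. Omnibus group tests (Kruskal–Wallis/Dunn) are standard
procedures delegated to scipy/statsmodels by the user; the package does
not wrap them. The segmentation sweep runs every (method × PZ-fraction)
cell over a cohort and reports ρ(ROI volume, GS group) over the
non-rejected cases plus PZ/TZ/rejected counts per cell.

## The phantom: what it emulates, and what it does not

Geometry: an axial ellipsoidal prostate (semi-axes 22 × 17 × 11 mm)
whose posterior half is the PZ, a cuboid GM sample outside the gland,
and spherical lesions clipped to their declared zone. The posterior
*half* (rather than a thin shell) is a deliberate simplification: the
package's own invariant — lesions contained in their zone — cannot hold
for ≥ 0.5 cc spheres inside a thin shell at 2.5 mm slices.

Kinetics: every tissue follows the bi-exponential model with the package
preset (arbitrary units; baseline 100 for all tissues). The presets are
constructed so that (i) muscle enhances lowest and peaks before the
270–330 s window, keeping its late slope a genuine small washout and the
normalized wash-out ratio sign-safe, and (ii) all six muscle-normalized
features increase strictly with lesion grade 6 < 3+4 < 4+3 < 8 on
noiseless curves. This monotonicity is the phantom's *contract* — the
grade-association tests measure whether the pipeline preserves an
ordering the generator put in, not whether such an ordering exists in
patients.

Noise: Gaussian by default (simplest for recovery statistics), Rician
available. SNR follows the standard MRI convention — tissue baseline
signal over noise sigma — so SNR 20 means σ = 5 intensity units at
baseline 100; thermal noise in MRI magnitude images is
signal-independent, and quoting SNR on the unenhanced image is the usual
practice. Intensities are clipped at zero after noise injection. Motion
injection applies per-frame in-plane rigid transforms (linear
interpolation, frame-minimum fill) and records them as ground truth.

The default cohort generator cycles the four grades over 24 cases, draws
lesion radius from a grade-dependent table (5.4–7.4 mm ± 0.3) so volume
grows with grade, and places ~76 % of lesions in the PZ. Simulated
targeted biopsies are 3 × 3 × 1 voxel footprints at random cores
(one-voxel-eroded lesion interior), emulating lesion-targeted sampling.

What passing tests do **not** show: robustness to coil bias fields,
arterial-input variability, deformable motion, zonal-contour error, or
tissue heterogeneity within a lesion — none of which the phantom
models. Cohort-level clinical effect sizes (correlations with biopsy
Gleason score, AUROC) cannot be reproduced without patient data; the
phantom cohort statistics verify internal consistency of the pipeline,
not clinical performance.

## Problem sizes and runtimes

Defaults used by the test suite and the acceptance script: 64 × 64 × 12
voxel phantoms (~8900 prostate voxels), 12 frames; 10-seed medians for
factorization and segmentation properties; 20 seeds for motion recovery;
100 seeds for noisy curve fits; 5 cohorts of 24 phantoms for the
end-to-end ordering. These sizes were chosen so the full acceptance run
completes in a few minutes on one CPU while keeping medians stable.

## Known limitations

* The bi-exponential form is an interpretation fixed jointly with the
  phantom; fitting clinical curves generated by a different enhancement
  process will produce model-mismatch bias in AUFC and τ.
* Histogram-MI registration has an accuracy floor of ~0.2–0.4 px at
  SNR 20 (the sample-MI maximum is genuinely displaced by noise).  An
  error in an accepted pair's transform propagates down the sequential
  chain — later frames are then corrected toward the mis-corrected
  predecessor.  The plateau tie-break penalty keeps this small, but the
  chain design makes single-pair errors non-local by construction.
* The fit-based features (AUFC, wash-in) are unstable on very small
  noisy regions (few voxels); the direct AUC features are the robust
  choice for biopsy-level analysis.
* `estimate_k` is a heuristic stand-in; with strongly overlapping
  tissue classes the eigenspectrum criterion can under- or over-count.
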