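# Methods

This note records the models, conventions and numerical choices behind
`sctdose`, and what the synthetic test bed does and does not establish
about real data.

## Geometry and conventions

All volumes live on regular, axis-aligned grids. Array axis order is
`(z, y, x)` with `z` the axial (slice) axis; the world position of a voxel
center is `origin + index × spacing` (mm). Two grids are *co-registered*
iff shape, spacing and origin match exactly; every cross-volume operation
either requires this or resamples explicitly (trilinear, with a declared
fill value: −1000 HU for CT-like volumes, the physically neutral air
value, and 0 otherwise). Oblique NIfTI orientations are rejected at load
rather than silently reinterpreted; negative diagonal affines are resolved
by axis flips. Masks resampled across grids use a 0.5 threshold on the
trilinearly interpolated indicator, the usual treatment-planning behaviour
at ~2 mm grids; partial-volume weighting is deliberately not modelled, so
endpoint estimates for very small structures carry a voxel-size error.

Structure margining (`dilate_isotropic`) adds every voxel whose center
lies within the margin of an input voxel center (Euclidean distance in
world units, via an exact distance transform). Center-to-center distance
slightly undershoots the continuous Minkowski dilation — by about half a
voxel of radius, ~8% in volume for a 7.8 mm sphere grown by 2 mm at 1 mm
spacing — and never overshoots; this is acceptable because the same
definition is applied consistently to every structure.

## Synthetic study conditions

The phantom emulates a head CT/MRI pair: an ellipsoidal head (default
semi-axes 62/88/70 mm) with a 6 mm bone shell at 700 HU, soft tissue at
30 HU, air at −1000 HU, plus Gaussian CT noise (sd 10 HU). The MRI channel
is a monotone map of tissue class (air 0, bone dark, soft tissue bright,
lesion brighter — qualitatively T1-like with contrast enhancement),
modulated by a smooth multiplicative bias field (cosine mixture, default
amplitude 0.2) and additive noise, and exactly zero outside the head.
Organs at risk are schematic geometric primitives (spheres and cylinders
at plausible offsets): anatomical realism is not a goal; constraint
checking only needs varied dose–structure overlap. The default single
lesion of radius 7.8 mm dilates (2 mm margin) to a ~3.9 cm³ PTV, matching
the median metastasis size treated with this technique; cohort runs vary
lesion radius over 6–11 mm and position over the brain interior.

Dose is analytic rather than computed by a transport engine. Each PTV is
reduced to its effective sphere (radius `R = (3V/4π)^(1/3)`); PD2
(3 × 11 Gy at isocenter) uses `D(r) = 33 · exp(−ln(1/0.7)(r/R)²)`, which
places exactly 70% of the isocenter dose (23.1 Gy) at the PTV surface, and
PD1 (3 × 7.7 Gy peripheral) a plateau of 23.1 Gy inside `R` with a
Gaussian falloff reaching half the prescription at `1.6 R` (configurable).
Lesions superpose additively. These fields have closed-form isodose
volumes — the gradient index of a PD2 lesion is analytically
`(ln(D_iso/(D_ref/2)) / ln(D_iso/D_ref))^{3/2} ≈ 5.05` — which is what
makes the downstream metrics testable. What the analytic model does *not*
reproduce: scatter, build-up, tissue heterogeneity effects, or
beam/collimator structure; nothing in the package should be read as a dose
engine.

The "recomputed on pseudo-CT" dose is modelled as a perturbation of the
initial dose with exactly known ground truth: a world-space translation, a
multiplicative rescaling and additive Gaussian noise. In the pipeline the
perturbation magnitude is tied to the pseudo-CT HU error (shift
`0.02 mm per HU` of soft-tissue RMSE, scale `1 + 5·10⁻⁴ per HU`, both
configurable), giving correlated dose differences of realistic size
(~0.3 mm, ~0.7% for a 14 HU RMSE). Passing rates near 100% under these
conditions are therefore expected, and mirror the regime in which clinical
pseudo-CT equivalence studies operate; the cohort test exercises the
*ordering* of passing rates across criteria, not their absolute values.

## Pseudo-CT chain

Normalization clips CT to [−500, 1000] HU (outliers are deliberately
destroyed) and MRI to its per-volume [1%, 99%] quantile range, then
stretches linearly to [−1, 1]; the fitted bounds are stored and the
inverse transform is exact on the clip interval (≤ 1e-6 HU round-trip).
MRI quantiles are computed over nonzero (in-FOV) voxels by default, with
an opt-out, since background zeros would otherwise dominate the lower
quantile. Axial slices are resampled to the network size by
pixel-center-aligned bilinear interpolation, which preserves the physical
field of view and is exact on affine fields.

The generator is a U-Net-style encoder–decoder (4×4 stride-2
convolutions, instance normalization, LeakyReLU; nearest-neighbour
upsampling followed by 3×3 convolution in the decoder; tanh output), with
skip connections concatenating each encoder activation at the matching
decoder resolution. The discriminator is a patch classifier whose decision
grid is 16×16 at a 256² slice and scales proportionally (4×4 at 64²).
Losses are binary cross-entropy on patch logits plus an L1 pixel term with
weight 100; optimization is Adam (lr 2·10⁻⁴, β₁ 0.5), batch size one. The
network backend is a self-contained numpy implementation, which makes
training bit-reproducible for a fixed seed. Resize-convolution decoding
was chosen over transposed convolution for implementation simplicity and
freedom from checkerboard artifacts; dropout defaults to 0 (exposed in the
configuration). The slice size must be at least `2^depth` so the
bottleneck stays ≥ 1 px. Desk-scale defaults (64² slices, depth 5, base
width 8, 20 epochs) train in well under a minute on one CPU; the
paper-scale geometry (256², depth 7, 300 epochs) is configurable but slow
on CPU, and reproducing clinical image quality on real anatomy is out of
scope — tests establish that the architecture learns (trained MAE far
below the untrained generator; monotone 1-pair overfit) and that the
surrounding transforms are exact, not that the GAN generalizes.

## Image comparison

HU classes follow fixed thresholds — bone strictly above 150 HU, soft
tissue within [−150, 150] — decided on the reference CT only, so both RMSE
operands share one region of interest. RMSE takes the square root (the
metric's name governs). DRRs are orthographic parallel ray sums of
`max(HU − floor, 0) × step length` (default floor −1000; bone-only variant
floor 150), compared over pixels where either image carries bone signal.
A divergent-beam (point source) geometry is not modelled; the orthographic
operator preserves the comparison's semantics (a skull-driven alignment
signal) while remaining fully specified.

## Gamma analysis

For each reference voxel at or above 10% of the reference maximum,

    γ(r) = min over e of sqrt(|e − r|²/dta² + (D_eval(e) − D_ref(r))²/ΔD(r)²)

with ΔD equal to the dose tolerance times the local reference dose (local
mode) or times the reference maximum (global mode; the same maximum
anchors the threshold). Below-threshold voxels are excluded from both
numerator and denominator of the passing rate. Roles are fixed — initial
dose as reference, recomputed dose as evaluated — and the evaluated dose
is sampled by trilinear interpolation (interpolated search generally
yields equal-or-higher passing rates than voxel-center search).

The production engine searches a distance-sorted candidate lattice of step
dta/10 within 3 × dta, retiring a voxel once the distance term alone
exceeds its running minimum, then descends on the 5× finer sub-lattice
(step dta/50) by recentred box search. In *local* mode at steep gradients
the agreement valley `{D_eval = D_ref(r)}` can be thinner than any
practical lattice step (width ΔD/|∇D| ≈ 0.05 mm at the 10% threshold of an
SRT field), and a descent can stall outside the right basin; for small
problems (≤ 2048 evaluated voxels) the engine therefore finishes with an
exhaustive scan of the fine lattice over each voxel's remaining feasible
ball (every candidate whose distance term alone stays below the current
minimum — a pruning that cannot change the optimum), capped at one DTA of
radius. At cohort scale this scan is skipped and the descent result is
accurate to a few hundredths of a gamma unit, far below the level that
affects passing rates.

The test oracle (`gamma_oracle`) is an independent numba kernel doing a
dense per-voxel scan at step dta/50 within 5 × dta, with the same sound
distance pruning plus a coarse feasible first pass that only supplies an
upper bound; its result is identical to a literal dense scan. Engine and
oracle agree to ≤ 0.02 gamma units on random smooth dose pairs; both are
quantized to the same dta/50 lattice, which is what makes that comparison
meaningful (the continuous minimum can sit a few hundredths *below* both
in thin valleys).

## DVH, endpoints and indices

Cumulative DVHs use 0.01 Gy bins from zero to the global maximum with
binary voxel membership. Dx% uses exact order statistics — the largest
dose d such that at least x% of the structure receives ≥ d, ties toward
the higher dose — with no binning; Dmax is the maximum voxel dose
(near-maximum alternatives like D0.035cc are derivable from Dx% but not
reported). Radially symmetric analytic doses produce massive dose ties, so
the DVH evaluated at Dx% can step past x% within one bin; tests account
for this. The conformity index uses the Paddick-inverse form
`(V_PTV × V_PIV)/V_overlap²` (≥ 1, equality iff the prescription isodose
volume coincides with the PTV), with the plain ratio `V_PIV/V_PTV` exposed
separately as `coverage_ratio`. The reference isodose is 23.1 Gy for the
standard protocols and 21 Gy for the reduced ones (3 × 7, 3 × 10). The
organ-at-risk table encodes the usual intracranial SRT limits (optic
nerves Dmax < 13.8 Gy, chiasm < 10.5 Gy, brainstem < 16.8 Gy, brain
V10 Gy < 5% and V21 Gy < 20.9 cm³, with secondary fallbacks); brain
volume constraints are interpreted as percent of the structure itself. A
constrained structure that is absent is reported "not evaluable", never
silently passed.

## Statistics

Initial-vs-recomputed endpoint series are paired (the same cases underlie
both), so the paired two-sided t-test is the default; identical series are
flagged degenerate rather than given a p-value. Spearman correlation uses
average ranks on ties. The equivalence sample size follows the TOST normal
approximation `n/group = ⌈2σ²(z₁₋α + z₁₋β/2)²/δ²⌉` with α the one-sided
level of each test and β = 1 − power; with σ = 5, margin 3, α = 0.05 and
power 0.95 this gives 73 per group, 146 in total. The alternative
`z₁₋α/2 + z₁₋β` convention is selectable. No multiple-testing correction
is applied across endpoints.

## Problem sizes and determinism

Default problem sizes are chosen for desk-scale runs: phantoms of
70×96×80 voxels at 2 mm (cohort runs 48×60×52), 16³ grids for
engine-vs-oracle comparisons, 10–20 case cohorts, and the GAN smoke
configuration above. Every stochastic component takes an explicit seed;
studies derive per-case seeds from a master seed via a seed sequence, so a
rerun of the same configuration is byte-identical, including the report
JSON. Known limitations: no DICOM-RT I/O (NIfTI only), no oblique grids,
no biological dose models, schematic anatomy, and an analytic dose model
whose agreement with clinical dose engines is out of scope by design.
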