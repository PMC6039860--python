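# Methods

## Problem and measurement model

`pvatquant` quantifies the circumferential relationship between perivascular
adipose tissue (PVAT) and vessel-wall thickness in paired cross-sectional
vascular MR slices: a fat-suppressed (wall-weighted) image, on which the wall
appears as a bright annulus, and a co-registered water-suppressed
(fat-saturated) image, on which PVAT appears bright. For each slice the
pipeline:

1. segments PVAT on the fat image by intensity thresholding;
2. fits the measurement centre as the least-squares circle through the wall
   mask's outer boundary;
3. casts 72 radial cords at 5° spacing, clockwise from an anatomically
   defined zero direction, and measures wall thickness t_wall(θ) and PVAT
   thickness t_pvat(θ) along each cord;
4. classifies each slice as normal or abnormal wall from its maximal
   thickness;
5. summarizes the angular distributions (per-angle means, IQRs,
   coefficients of variation, peak angles) and
6. regresses wall thickness on PVAT thickness with a hierarchical
   mixed-effects model on an angularly subsampled cohort.

All lengths are millimetres; angles live on the 5° grid {0, …, 355}.

## Segmentation

PVAT pixels are those with intensity strictly greater than μ_I + 2σ_I,
where μ_I and σ_I are the mean and *population* (n-divisor) SD of the whole
fat image — the full pixel grid is the population, not a sample. The
statistics are computed before any exclusion; a user-supplied exclusion mask
(image background, the very bright subcutaneous rim) only censors the output.
Two consequences are deliberate and tested: a constant image yields an empty
mask (strict inequality), and the mask is invariant under positive affine
intensity rescaling. A large bright rim legitimately inflates the threshold —
this is a property of whole-image statistics, and the reason the exclusion
path exists. Wall segmentation is an *input* (phantom truth or external
annotation); no automatic wall operator is defined, only shape/emptiness/
connectivity validation.

## Geometry

**Centre.** Kåsa's algebraic circle fit (closed form, deterministic) on the
wall mask's outer boundary — mask pixels with a 4-neighbour outside the mask
at larger radius from the mask centroid. The RMS radial residual is reported
as `fit_rms_mm`; focal plaque visibly degrades it, flagging non-circular
walls. Fewer than 6 boundary points or a rank-deficient normal system is an
error.

**Angle frame.** Carotids: 0° is anatomical anterior, i.e. image "up",
direction (0, −1) in (x, y) pixel-centre coordinates with y down the rows.
Aorta: 0° points from the vertebral-body centre toward the fitted aorta
centre (the vertebral reference point is required input for aortic slices).
Angles always increase clockwise as displayed. Pixel centres sit at
(index + 0.5) × spacing.

**Thickness.** Each cord is sampled at 0.1-pixel steps (≤ 0.04 mm
quantization at 0.39 mm spacing) with nearest-neighbour mask lookup;
thickness is the *total* in-mask length, summing disjoint runs, because fat
lobules need not be contiguous. The wall's outer-boundary radius on a cord
is its outermost in-wall sample (fallback: the fitted circle radius when a
cord misses the wall, which is flagged); the PVAT window spans from there to
that radius plus the vessel-class extent threshold. Cords that leave the
image are measured to the boundary and flagged.

**Accuracy.** Two error sources separate cleanly. The sampler itself is
exact to one step: measured against the phantom's *analytic* region
membership (a rasterization-free oracle the phantom exposes), noiseless
profiles are recovered within one ray-step at all 72 angles. Measured
against *rasterized* masks, the binary boundary quantization adds up to
about one pixel-spacing per cord (slightly more where the thickness profile
changes steeply within a pixel); on noiseless rendered slices with constant
profiles, recovery is within one pixel-spacing at every angle. Real masks
are rasterized, so pixel spacing — not the sampler — bounds accuracy in
practice.

## Thresholds and classification

The PVAT search extent per vessel family is mean + 2·SD (sample SD, n−1) of
PVAT measured on sample images; the stored defaults, 20 mm (aorta) and 9 mm
(carotid), are the values derived that way in the study this pipeline
operationalizes (n = 15). The abnormal-wall cut is mean + 3·SD (n−1) of the
maximal per-slice wall thickness in a user-designated visually normal
subsample; a slice is abnormal iff its maximum over the 72 cords exceeds the
cut. Both derivations use the n−1 divisor because they are estimated from
small samples, and the cut is one-sided upper because wall thickening is
one-directional. The normal subsample is an input label set — the visual
wall-pattern screen that defines it is human judgement, out of scope.

## Angular statistics

Per-angle means and SDs pool all (patient, slice) measurements; the IQR is
taken over the 72 per-angle means with linear-interpolation (type-7)
quantiles. The coefficient of variation is the pooled sample SD over the
mean of all measurements of a tissue (a per-patient variant is available).
CV equality is tested with the Feltz–Miller asymptotic chi-square test, with
a within-sample percentile bootstrap as a cross-check; neither test is named
by the source analysis, so an assumption-light standard pair was chosen.
Peak angles are local maxima (strictly greater than both circular
neighbours) of the mean profile after circular moving-average smoothing over
15°, ranked by height; a flat profile has no peaks.

Neighbouring 5° cords are strongly autocorrelated (circular lag-1 ACF on
smooth phantom profiles ≈ 0.85), so the regression cohort keeps only angles
20° apart — 18 per slice — which demonstrably lowers the lag-1 ACF. The
subsample phase defaults to 0° and is configurable; the source analysis does
not state which phase was kept.

## Hierarchical model

On the subsampled cohort, for patient i, slice j, angle k:

    wall_ijk = α + β·pvat_ijk + angle_k + slicepos_j   (fixed)
               + b_i + a_k + s_ij + e_ijk              (random)

with independent random intercepts b_i ~ N(0, σ²_person), a_k ~ N(0,
σ²_angle) (angle labels shared — crossed — across patients), s_ij ~ N(0,
σ²_slice) keyed by patient:slice compound labels (nested), and residual
e_ijk. Angle and slice position additionally enter as categorical fixed
effects to absorb patterns common to all patients, so β captures
person-specific covariation beyond the shared geometry. The fixed angle
terms make σ²_angle weakly identified; that redundancy is retained
deliberately (a switch drops the fixed angle terms). Estimation is REML via
statsmodels' MixedLM in its variance-components formulation (single group,
crossed effects inside it). The 95% CI and p-value for β are Wald intervals
with a normal reference — appropriate at the tens-of-thousands-of-segments
scale this analysis targets; β is reported raw (mm wall per mm PVAT) and,
optionally, standardized, always labelled separately.

Degenerate inputs: a cohort with a numerically perfect affine fit (the
noise-free simulation limit) has no REML solution, so the fit returns the
exact least-squares coefficient with a zero-width CI and a
`degenerate_zero_residual` diagnostic. Fits refuse full 5°-grid cohorts
unless explicitly overridden. Strata emptied by exclusions come back as
not-estimable results, never exceptions.

## Phantom generator

The generator emulates exactly what the pipeline consumes. A slice is an
annular wall (inner radius = lumen, angular thickness τ(θ) = base + periodic
Gaussian plaque bump) and a PVAT band outside it (thickness π(θ): constant,
single bump, or the aortic double-peak pattern with bumps at 120° and 220°),
rendered as disjoint regions at contrast 1.0 over background 0.0 — which
makes the 2-SD threshold's behaviour analyzable — plus an optional border
rim at intensity 2.0 and per-pixel N(0, σ²) noise. Identical spec and seed
give bit-identical output. Geometry that cannot fit the frame together with
its PVAT search extent is rejected at construction.

Cohorts add the variance structure the model assumes: wall = τ_base(θ) +
b_i + a_k + s_ij + β_true·(pvat − mean π) + e_ijk, with PVAT = π(θ) + its
own person offset + per-cord jitter; all thicknesses are clipped at a
0.05 mm floor (no rejection sampling), with a warning when more than 10% of
draws hit it. The generating draws are carried in the truth table so
variance accounting is directly checkable.

Defaults (study conditions, chosen once):

| parameter | default | basis |
|---|---|---|
| pixel spacing | 0.39 mm | carotid-protocol in-plane resolution |
| carotid wall base | 1.4 mm | reported mean carotid wall |
| carotid PVAT base | 0.8 mm | reported mean carotid PVAT |
| aortic wall base | 2.38 mm | reported mean aortic wall |
| aortic PVAT profile | base 1.8 + 2.6·bumps(120°, 220°, w=30°) | double-peak pattern; per-angle-mean IQR spans ≈ 1.9–4 mm, mean ≈ 3 mm, matching the reported aortic pattern |
| β_true | 0.04 mm/mm | magnitude of the carotid-normal coefficient |
| σ_person, σ_angle, σ_slice, σ_resid | 0.30, 0.10, 0.15, 0.25 mm | wall SD ≈ 0.42 mm pooled, inside the reported 0.6–0.8 mm once angular structure is added |
| PVAT person offset / cord jitter | 0.30 / 0.40 mm | carotid PVAT ≈ 0.8 ± 0.5 mm with ~7% at the floor — a strongly right-skewed, floor-truncated distribution like the reported one, below the generator's 10% distortion warning |

What the phantom does *not* emulate: MR physics (coil shading, flow
artefacts, partial volume), 3-D geometry, bifurcations, anatomical
background tissue. Passing tests therefore certify the measurement and
statistics chain on idealized contrast, not robustness to scanner artefacts.

## Problem sizes used in the shipped checks

Monte-Carlo suites are sized to keep the full test run in minutes while
leaving Monte-Carlo error far from the asserted margins: segment accounting
uses a 1,180-slice mask-rendered manifest (the study's combined slice
count); type-I error uses 200 replicate cohorts of 10 patients × 4 slices;
CI coverage uses 100 replicates of 20 patients × 10 slices; peak-pattern
recovery uses a 50 × 20 cohort table, where the per-angle-mean Monte-Carlo
error (≈ 0.016 mm) is far below the inter-bin contrast of the smoothed
double-peak profile. The narrative regression driver fits 20 patients × 10
slices (the slice random-effect dimension, not the row count, dominates
REML runtime).

## Known limitations

* Thickness from rasterized masks is pixel-limited; sub-pixel accuracy holds
  only against analytic geometry.
* The Kåsa fit is biased for strongly non-circular walls (heavy plaque);
  `fit_rms_mm` exposes this but no elliptical fallback is provided.
* Whole-image threshold statistics are sensitive to large bright structures;
  exclusion masks are the intended remedy, not automatic rim detection.
* Wald CIs can be mildly optimistic for few patients; the shipped
  calibration checks run at 10–20 patients, below which results should be
  treated cautiously.
* The CV comparison pools measurements; clustered sampling is not reflected
  in the Feltz–Miller reference distribution (the bootstrap cross-check
  mitigates, within-sample resampling only).
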