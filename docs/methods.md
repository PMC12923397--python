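# Methods

## Problem setting

In diabetic macular edema, hard exudates (HEs) are intraretinal lipid
deposits visible on OCT as hyper-reflective foci (HRF). The pipeline
quantifies HE burden on macular OCT cubes — a stack of B-scans, each a row
of A-scan depth profiles — and follows it over an anti-VEGF treatment
course with visits at weeks 0, 4, 12, 24 and 52. All grids are indexed
`(bscan, axial, ascan)`.

## Scan geometry and volumes

`ScanGeometry` describes the physical raster: defaults are 512 A-scans ×
128 B-scans over 6 × 6 mm with a 2 mm axial depth at 1024 pixels (the
common macular-cube convention). The axial pixel count of commercial
exports varies and is deliberately a free parameter; nothing downstream
assumes a specific resolution, and all physical quantities derive from the
voxel pitches. The volume of a binary HRF mask is voxel count × voxel
volume; the 1024-pixel default gives a voxel of
(6/512)(6/128)(2/1024) ≈ 1.07 × 10⁻⁶ mm³.

## Segmentation

The analysis band runs from the internal limiting membrane (ILM) to the
top of the RPE reflective complex, per A-scan column. Surfaces are either
supplied (synthetic ground truth) or estimated: the ILM as the first
axially smoothed intensity crossing of `background mean + k·SD` per
column (background taken from the top rows of each B-scan), the RPE by
locating the brightest smoothed band below the ILM and walking up to its
half-rise edge. Columns with no supra-threshold pixel raise an error
naming them.

The reference segmenter computes, per B-scan, the mean and SD of the
intensities inside the band and marks band voxels above `mean + k_sd·SD`
(default `k_sd = 3`). Statistics are per B-scan rather than per volume to
match the per-B-scan framing of the quantification rule. `k_sd ≤ 0` is
rejected rather than silently producing a full-band mask. The band's
upper bound is exclusive so the bright RPE complex itself never
contaminates the threshold statistics; every output voxel lies within
[ILM, RPE] of its column, always.

A compact trainable alternative — logistic regression over local
intensity features (point intensity, 3×3/7×7 means, horizontal and
vertical 9-pixel window means, local SD) — implements the same
per-B-scan mask contract. The horizontal-window features are what let a
linear model distinguish compact bright foci from the laterally extended
RPE band. Training samples all positive pixels plus an equal random draw
of negatives under a fixed seed, so training is deterministic. It is a
deliberately small, CPU-trainable model: the slot exists so that
downstream quantification is segmenter-agnostic, not to reproduce any
particular deep architecture. A k-fold cross-validation harness
partitions image/mask pairs by a seeded shuffle and reports per-fold and
mean Dice and voxel accuracy. Dice of two empty masks is defined as 1
(the conventional resolution of 0/0); accuracy uses all voxels of the
scan as denominator.

## Quantification

Only clusters of at least 3 contiguous hyper-reflective pixels within a
B-scan count as HRF. Contiguity is evaluated in the 2D (axial, ascan)
plane of each B-scan independently — never across B-scans, since ~47 µm
inter-scan spacing makes cross-slice continuity unreliable — with
8-connectivity by default (4-connectivity available). The filter is
idempotent and monotone: output voxels are a subset of the input, and a
larger minimum size never increases volume.

The en-face projection map counts segmented voxels per column and
conserves the total count. The ETDRS grid labels every column by the
distance of its center point (pixel-center convention) from the fovea
center — defaulting to the geometric scan center, configurable since no
foveal localization is performed — using half-open annuli: central
subfield < 0.5 mm, inner ring [0.5, 1.5), outer ring [1.5, 3.0), outside
≥ 3.0 mm. Every column has exactly one label, so regional volumes plus
the outside component always sum exactly to the total. Regional volumes
partition the 3D mask by column rather than collapsing it to a binary
en-face footprint, so depth-stacked foci are fully counted; the
footprint-area variant (`regional_enface_areas`) is available for
sensitivity analysis and generally underestimates. A 6 × 6 mm scan's
corners lie outside the 3 mm circle, which is why CSF + IR + OR ≤ Total
with equality only when no focus sits in a corner.

## Synthetic OCT volumes

The phantom renders, per column: dark vitreous (0.05) above the ILM, a
mid-reflective retinal band (0.40), a bright RPE stripe (0.78, 2 px)
starting at the RPE surface, and a darker sub-RPE region (0.12). ILM and
RPE surfaces are smooth low-frequency maps (two random sinusoids, ~2% of
the axial range in amplitude). Optional hypo-reflective ellipsoids (0.08)
inside the band emulate fluid pockets. HRF blobs are ellipsoids in voxel
space placed strictly between the surfaces, rendered flat at
`band level + c·σ` where σ is the additive noise SD; the planted mask and
catalog are returned exactly. Additive Gaussian noise (σ = 0.04) stands
in for speckle — a simplification; real OCT speckle is multiplicative
and spatially correlated. Identical seed and parameters reproduce the
volume bit-identically.

The default contrast is c = 6 noise SDs: clinically, HRF are
unambiguously bright relative to local speckle, and c ≥ 4 is the floor at
which per-B-scan thresholding is well posed; c = 8 is the high-contrast
stress setting. With `k_sd = 3`, blob voxels are then ≥ 3σ above the
threshold, noise false positives are isolated and removed by the
contiguity filter, and end-to-end volume recovery lands well inside the
15% (default) and 5% (high-contrast) acceptance envelopes — median
relative error is below 1% on 20-volume batches at 192 × 48 × 256
geometry (chosen as a faithful scaled-down raster for batch experiments).
What passing these tests shows is that the measurement chain —
band restriction, thresholding, contiguity filtering, voxel-volume
arithmetic, regionalization — is correct; it does not certify segmenter
performance on real speckle, motion artifacts or low-signal scans.

## Synthetic cohorts

The cohort generator emulates a 260-eye treated DME cohort. Baseline
regional volumes are right-skewed: region mean targets
(CSF 0.0011, IR 0.0069, OR 0.0183, corners 0.0030 mm³, total 0.0293 mm³)
are multiplied by a shared per-eye lognormal severity (log-SD 1.0) and a
per-region lognormal (log-SD 0.6), giving the heavy right tail implied by
regional SDs exceeding their means. Visit-week volume is
`baseline × factor × lognormal(1, visit_noise)` with per-region,
per-week factors; defaults follow the observed trajectory (total rising
to ~112%/119% of baseline at weeks 4/12, falling to ~56% at week 52).
Because the total is the sum of the four regional components, the total
trajectory is reproduced automatically. With visit noise 0 and no
missingness, cohort-mean ratios equal the planted factors exactly.

Complete regional resolution is planted as a zero point mass among eyes
observed at a week (defaults: CSF 29.2%, IR 3.8%, OR 0.4% at week 52);
surviving values are scaled by 1/(1−p) so cohort-mean trajectories are
unchanged. Covariates are drawn with planted Pearson correlations to
baseline total HE (HbA1c +0.198, age −0.158, diabetes duration −0.221)
via a sample-standardized mixing construction. Week-52 visual acuity
follows a linear model on standardized predictors — week-52 CST
(β = −0.300), baseline outer-ring HE (β = −0.280), pseudophakic lens
status (β = −0.153) — with residual SD set by default to
`sqrt(1 − var(linear predictor))` so the planted coefficients are
standardized betas of the generated outcome (an explicit SD can be
supplied). Each eye misses at most one follow-up visit
(rate 0.10); 5% of eyes get a disqualifying signal strength ≤ 3 and 3% a
zero baseline volume, to exercise the inclusion filter. The generator
does not model measurement error correlated across regions within a
visit, informative missingness, or treatment-arm effects.

Inclusion filtering mirrors the study rules: exclude signal strength ≤ 3,
no HEs at baseline, or more than one missing follow-up visit, with one
logged reason per excluded eye (in that precedence).

## Cohort statistics

- Percent-of-baseline is the ratio of cohort means (week mean over
  baseline mean), not the mean of per-eye ratios — the only reading
  under which the published percentages equal the published means'
  ratios. Reported at one-decimal rounding.
- Paired t-tests are two-sided with complete-case pairing per timepoint;
  all-zero difference vectors return t = 0, p = 1 rather than 0/0. The
  Bonferroni family defaults to m = 4 (the four follow-up weeks within a
  region, the natural comparison family); `min(1, m·p)` never decreases a
  p-value and caps at 1.
- Resolution percentages use a configurable denominator; the published
  convention (count over all analyzed eyes) is the default.
- The univariable screen fits one simple regression per candidate and
  passes p ≤ 0.10; its type-I rate calibrates to the threshold under the
  null by construction.
- Stepwise regression is bidirectional with entry p ≤ 0.05 and removal
  p > 0.10 (the common SPSS-style defaults), on z-scored variables so
  coefficients are standardized betas. Any step that would raise a
  variance inflation factor above 5 is refused — this is the
  multicollinearity guard, and it is why near-duplicate predictors (e.g.
  total vs outer-ring baseline HE, which share the eye-level severity
  factor) never co-enter. Ties in entry p-values break lexicographically
  by name, making the fit invariant to candidate order. Partial R² is
  the last-entry increment — R²(full) − R²(without the predictor), the
  squared semi-partial correlation; the squared partial correlation is
  the other common reading and can be derived from the reported
  quantities if needed.

Two caveats observed in simulation and worth knowing: at realistic cohort
size (n ≈ 260) stepwise may retain a collinear proxy (total baseline HE)
in place of the planted outer-ring predictor — the classic instability of
stepwise selection under collinearity, which the VIF guard bounds but
cannot remove; and at n = 2000 any null candidate entering the pool has a
slightly inflated (~8%) chance of selection because conditioning on true
predictors shrinks residual variance. Neither is a defect of the
implementation; both are properties of the procedure.

## Numerical and I/O choices

Volumes are stored as 16-bit multi-page TIFF (one page per B-scan) with a
JSON sidecar carrying geometry, signal strength, seed and optionally the
surfaces; quantization to uint16 is the only loss and a
write–read–write cycle is bit-stable. Masks use {0, 1} 8-bit TIFF.
Cohorts are plain CSV (visits + covariates). The YAML run configuration
is strictly validated (unknown keys are errors) and every pipeline run
writes its resolved configuration, package version and a plain-text,
stage-prefixed log next to its outputs; identical config and seed
reproduce all numeric outputs byte-identically.

## Limitations

- The synthetic phantom omits device optics, motion, shadowing,
  vendor file formats, and realistic speckle statistics; performance
  numbers on it do not transfer to clinical scans.
- Only ILM and RPE are delineated; no multi-layer segmentation, and no
  CST computation from images (CST is an input covariate).
- The trainable segmenter is a pixel classifier, not a deep
  encoder-decoder; it exists to exercise the pluggable-segmenter
  contract and the cross-validation harness.
- Group-balance testing against external cohorts is out of scope.
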