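# hefq — hard-exudate quantification on OCT volumes

Hard exudates (HEs) are lipid deposits that form in the retina in diabetic
macular edema (DME) and appear on optical coherence tomography (OCT)
B-scans as small bright spots — hyper-reflective foci (HRF). `hefq`
implements a complete, testable pipeline for quantifying HE burden from
macular OCT cubes and relating it to treatment outcomes:

1. **Segment** — delineate the internal limiting membrane (ILM) and retinal
   pigment epithelium (RPE), then mark hyper-reflective voxels inside that
   band. The default segmenter thresholds each B-scan at
   `mean + k·SD` of the band intensities; a compact trainable pixel
   classifier with the same mask contract is included, along with Dice /
   accuracy metrics and a k-fold cross-validation harness.
2. **Quantify** — keep only clusters of ≥ 3 contiguous pixels per B-scan
   (8-connected, no linking across B-scans), convert voxel counts to mm³
   using the known voxel dimensions, build an en-face projection map, and
   partition volumes over the ETDRS grid: central subfield (< 0.5 mm),
   inner ring (0.5–1.5 mm), outer ring (1.5–3 mm) from the fovea center.
3. **Analyze** — longitudinal cohort statistics over visits at weeks
   0/4/12/24/52: percent-of-baseline trajectories, paired t-tests with
   Bonferroni correction, complete-resolution counts, Pearson correlation
   screens, and univariable-screen (p ≤ 0.10) + bidirectional stepwise
   regression with standardized betas, partial R² and a VIF
   multicollinearity guard.
4. **Simulate** — synthetic OCT volumes with planted HRF blobs (exact
   voxel-level ground truth) and synthetic longitudinal cohorts with
   planted trajectories, covariate correlations and outcome effects, so
   every stage above has a quantitative oracle. Real clinical OCT data are
   not required anywhere.

The core volume statistic is simply

    V_HE = N_voxels × (Δx · Δy · Δz)   [mm³]

with `N_voxels` the count of segmented, contiguity-filtered HRF voxels and
`Δx, Δy, Δz` the physical voxel pitches (e.g. 6/512 × 6/128 × 2/1024 mm for
a 512 × 128 × 1024 cube over 6 × 6 × 2 mm).

## Worked example

```sh
python analysis/01_simulate_data.py --seed 0   # volumes + 260-eye cohort
python analysis/02_segment_quantify.py         # segmentation -> volumes
python analysis/03_trajectories.py             # Table-style trajectory summary
python analysis/04_correlations.py             # Pearson screen
python analysis/05_regression.py               # screen + stepwise model
```

which prints (seed 0):

```
segmented 10 volumes: median relative volume error 0.4%, median Dice 0.996
237 of 260 eyes analyzed; exclusions: {'low signal strength': 12, 'no hard exudates at baseline': 11}
total HE volume, percent of baseline by week: w4=120.1%, w12=118.1%, w24=103.9%, w52=55.2%
12/16 paired comparisons significant after Bonferroni (m=4)
complete resolution at w52: CSF 60/226 (26.5%)
stepwise model for week-52 VA (n=226, adjusted R^2=0.219):
  cst_w52: beta=-0.355 (p=7.5e-09, partial R^2=0.125, VIF=1.00)
  ...
```

Reading this: segmentation recovers the planted HE volumes to well under a
percent at default contrast; the simulated cohort's total HE volume rises
~20% by week 12 before falling to ~55% of baseline at one year; about a
quarter of eyes fully clear the central subfield; and week-52 central
subfield thickness, baseline HE burden and pseudophakic lens status emerge
as independent predictors of week-52 visual acuity.

Everything is also scriptable through the `hefq` CLI
(`hefq simulate volume|cohort`, `hefq segment`, `hefq quantify`,
`hefq analyze`, `hefq run --config cfg.yaml --seed 0 --out runs/demo`);
`hefq run` executes all four stages and writes the resolved config, log and
result tables next to each other.

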