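# Methods

`salnet` implements an end-to-end analysis that classifies structural-MRI
volumes by severity with a residual convolutional network, attributes the
decision to voxels by gradient saliency, aggregates saliency over a brain
parcellation, and mines the resulting subjects x regions matrix for
cross-region correlation networks, functional-network involvement,
phenotype-score correlations, and hemisphere asymmetries.  Because the
clinical imaging data this style of analysis targets is access-restricted,
the package ships a synthetic-cohort generator whose planted ground truth
drives parameter-recovery tests.  This note records the models, the
defaults and why they are what they are, and what the synthetic results do
and do not establish.

## Synthetic cohort generator

**Geometry.** Volumes live on an isotropic `grid`^3 lattice (default 48) in
`(sagittal, coronal, axial)` axis order with sagittal index 0 on the right
hemisphere.  The atlas fills an ellipsoidal brain: a cortical shell
(normalised radius 0.55–1.0) holding 75 cortical regions per hemisphere, a
core holding 13 subcortical regions per hemisphere, and two midline
structures (brain-stem and fornix analogues) that are not split across
hemispheres — 178 regions in total.  Right-hemisphere regions are grown as
Voronoi cells around farthest-point-sampled seeds and mirrored across the
mid-sagittal plane, so the atlas is exactly mirror symmetric; cortical
regions are grouped into 6 lobes by angular sector (as even as possible,
13 or 12 regions each) and assigned round-robin to 8 functional networks
(Default Mode, Salience, Frontoparietal, Social, Language, Sensorimotor,
Dorsal/Ventral Attention, Limbic/Emotion).  Every region is guaranteed at
least 8 voxels; a grid too small for the requested region count raises a
sizing error naming the limit.

**Latent effect model.**  Each subject carries a severity budget `t` drawn
uniformly per group — high (1.5, 2.0), low (0.5, 1.0), control (0.3, 0.8);
controls are deliberately the low tail of the spectrum.  The budget is
shared across `n_latents` = 4 effect factors with centred allocation
noise:

```
z[s, l] = t[s] + latent_spread * (eps[s, l] - mean_l eps[s, :]),   eps iid N(0, 1)
```

Centring (`latent_spread` = 0.8) makes the budget the only component
common to different factors.  Pooled over the high and low groups this
keeps the cross-factor correlation near `Var(t) / (Var(t) +
latent_spread^2 * (1 - 1/L))` ≈ 0.3 in Pearson terms, i.e. a Kendall tau
well below the 0.4 graph threshold, while the budget still separates the
groups cleanly once effects are pooled over factors.  This is the property
the correlation-network stage needs: strong within-factor, weak
cross-factor dependence.

**Planted effects.**  Each factor owns a disjoint block of regions
(default 10 cortical + 2 subcortical).  A fraction
`affected_left_fraction` = 0.75 of each block's cortical members is drawn
from the left hemisphere, and left-hemisphere amplitudes are additionally
scaled by `asymmetry_factor` = 2.5.  Both numbers are anchored to the
hemisphere dominance the analysis is meant to recover: a left/right
mean-saliency ratio of roughly 2.5 and left/right significant-region
counts of roughly 3:1.  Count asymmetry is the load-bearing mechanism —
a trained classifier needs *less* weight on a stronger signal, which makes
gradient-based saliency roughly amplitude-neutral, so amplitude asymmetry
alone does not reliably survive attribution.

Each affected region r in block l perturbs the volume by

```
effect_scale * loading[r] * z[s, l] * asym(r) * (1 + texture_r) * mask_r
```

with `loading[r] ~ U(0.6, 1.0)`, a fixed smooth zero-mean texture field
per region (amplitude 0.3), on top of a smooth intensity template plus
voxel noise `noise_sd * N(0,1)` (clipped at zero).  Defaults
`effect_scale` = 0.25 and `noise_sd` = 0.05 put the planted effect at five
times the voxel noise — a strongly separable regime (pooled affected-region
mean intensity separates the groups at d ≈ 7) that the recovery tests
treat as the reference condition; `effect_scale = 0` is the null.

**Phenotypes.**  Subscores are noisy linear functions of the latents:
`subscore_j = 30 + 25 * (z @ w_j) + N(0, subscore_noise_sd)` with positive
weights normalised per subscore, so each subscore mixes all factors unless
a test overrides the weights.  SRS totals are affine in the budget and
clipped into group-consistent bands: high strictly above 70, low strictly
below 59 (scores between the bands are never generated).  Controls carry
no scores.

**Cohort size.**  150 subjects (60 high, 60 low, 30 control) with a
held-out test set of 31 scored subjects.  These sizes echo the scale of
the motivating analyses (regional masks for 150 subjects; reported
accuracies that are integer multiples of 1/31).

## Classifier

A residual bottleneck network in 2D or 3D, implemented in numpy inside the
package (`salnet.nn`): conv stem (3^3, stride 2), batch norm, ReLU, 2x max
pool, bottleneck stages (1x1 reduce — 3^3 — 1x1 expand, projection skips,
stage-entry stride 2), global average pooling, and a head.  Stage plans:
`resnet50` (3, 4, 6, 3 — the classic 50-layer plan), `resnet26`, and
`tiny` (1, 1).  Channel widths are `(16, 32, 64, 128) * width_scale`.
Heads: `softmax` (2 logits, cross-entropy), `tanh` (1 logit, squared error
to +-1), `sigmoid` (1 logit, BCE), and `feature` (an n-unit fully
connected layer replacing the classification layer).  Adam with fixed
epochs; inputs are z-scored with training-set statistics; every source of
randomness is seeded, so training is bit-reproducible on one machine.

The desk-scale configuration used by the pipeline and the tests is
`tiny` / `width_scale 0.25` on 48^3 volumes (about 3.6k parameters,
~15 s per training on one CPU).  The full `resnet50` plan is available but
not exercised by the test suite.  Training enforces the protocol rather
than assuming it: train/test id sets must be disjoint, both classes must
appear on both sides, and unscored controls can never enter training.

**Hybrid variants.**  The trained backbone's classification layer is
replaced by a *randomly initialised, untrained* fully connected layer
(default 64 units) whose output feeds a kNN (Euclidean, odd k, default 5)
or a linear SVM fitted on training-subject features.  A best-of-R restarts
protocol (default 3) re-draws the random layer and reports the best test
accuracy together with the per-restart distribution.

**Slice-range protocol.**  The 2D variant trains one classifier per
contiguous group of slices (default slices 24–103 in groups of 8, i.e. 10
groups per axis) along a chosen anatomical axis, labels each slice with
its subject's group, and scores subject-level by majority vote over the
subject's slices (slice-level accuracy is logged alongside).  The default
range requires at least a 104-slice axis; desk-scale tests use smaller
custom ranges.

## Saliency

Per subject, saliency is derived from the gradient of the target-class
pre-activation score at the model's predicted class.  The default is
gradient-times-input, |gradient * voxel|: in a ReLU network the raw
gradient is piecewise constant in the input, so on an intensity-perturbed
phantom it carries almost no per-subject magnitude information — measured
within-block saliency correlations stayed near tau 0.26 with plain
|gradient| versus 0.47 with gradient-times-input.  The plain absolute
gradient remains available as a mode.

Two stabilising choices, both visible in the pipeline config:

* **Ensemble averaging.**  Saliency is averaged over a small ensemble
  (default 3) of identically configured, differently seeded trainings,
  each member scaled to unit mean first.  Desk-scale networks are small
  enough that a single model's attribution is seed-noisy; averaging three
  raised block-recovery ARI from the 0.7–0.97 range to 1.0 on every tested
  cohort seed.  Spatial Gaussian smoothing of the maps was evaluated for
  the same purpose and rejected: it blurs saliency across region borders
  and created spurious cross-block graph edges.
* **Global-factor correction.**  The gradient magnitude carries a
  multiplicative per-subject scale common to all regions — the analogue of
  the global signal in functional connectivity.  Rank-correlation
  statistics (region-region networks, score-region tables) use log-space
  global-signal regression; level statistics (hemisphere means, avg/STD
  panels, control congruence) use proportional scaling (each subject's row
  divided by its mean), which removes the scale while preserving the
  relative regional profile.  The raw region means are what the saliency
  stage writes to disk; corrections are applied downstream and are
  reproducible from that file.

Aggregation: mean saliency over each region's voxels (background
excluded) gives the subjects x regions matrix.  Hemisphere comparison is a
pooled-variance two-sample t-test over per-region averages — the units are
regions, so 75 cortical regions per hemisphere give df = 148 — plus the
same test on per-region high-low ranges |mean_high - mean_low|.  Sagittal
projections average each hemisphere's sagittal slices into one 2D overlay
field per hemisphere; on odd grids the exact midline slice belongs to
neither.

Saliency magnitudes depend on arbitrary scalings (network scale, input
normalisation, the corrections above), so the package reports magnitudes
only on its own scale and never compares them to externally printed
absolute values.

## Correlation networks

Kendall tau-b (tie-corrected) between region columns across pooled
high+low subjects; two-sided significance by exact permutation enumeration
for n <= 9 and the tie-corrected normal approximation otherwise.  Edges
survive at p < alpha (default 0.01, uncorrected by design; a
Benjamini-Hochberg mode would be a one-line addition but the reference
protocol uses raw p) and tau > threshold (positive correlations; an
absolute-value mode keeps negative edges).  Constant columns are flagged
and skipped.  Scopes: cortical-cortical, cortical-subcortical (which also
retains subcortico-subcortical pairs), and all.

Derived summaries:

* **Top edges** — the n largest by tau (default 500), ties broken by p
  then region-id pair for determinism.
* **Spring layout** — seeded force-directed embedding with edge attraction
  proportional to tau, so realised edge length tracks 1 - tau and
  high-degree regions drift to the centre; coordinates are left unscaled
  so distances are comparable across graphs.
* **Hub ranking** — per threshold in the sweep {0.1 ... 0.6} (divisor 6 in
  all averaged summaries; the sweep deliberately excludes 0.0, which is
  available behind a flag), the degree of every region in scope and the
  top-50 table (ties: higher mean incident tau, then id); the averaged
  table sums each region's degrees over the per-threshold top-50 tables it
  appears in, divides by the number of thresholds, and re-ranks.
* **Composition** — within-lobe fraction (same lobe *and* hemisphere),
  per-(hemisphere, lobe) shares, within-L/within-R/cross shares, and for
  graphs touching subcortex the attachment shares to LH cortex, RH cortex,
  and within-subcortical.  An empty graph reports undefined (None), not
  zero.

## Phenotype statistics

* **Network involvement** — counts of top-hub regions per functional
  network with percentages of the total; regions mapped to no network are
  excluded from the total.  Averaged involvement takes arithmetic means of
  per-threshold counts and percentages over the sweep.
* **Score-region correlations** — Kendall tau of each of the five SRS
  subscores against each of the 150 cortical regions across scored
  subjects, keeping rows at p < 0.05 (alpha = 1 keeps the full table),
  with per-hemisphere and per-lobe tallies.
* **Avg/STD grid** — the 8x8 {LH, RH} x {Avg, STD} x {High, Low} panel:
  each axis is a per-region vector over one hemisphere's cortical regions
  for one group; off-diagonal panels report Pearson r and the OLS slope,
  diagonal panels report Shapiro-Wilk W and p (reported, never
  thresholded).
* **Control congruence** — per-region mean saliency of controls regressed
  on that of low-severity subjects: Pearson r, slope, intercept.

## Pipeline

`run_pipeline(config, out_dir)` executes simulate → train → saliency →
corrnet → networks → phenotype → report, writing TSV/JSON/GraphML
artifacts plus a manifest with the config snapshot, seeds, stage timing
and SHA-256 digests of every output.  Identical config+seed reproduces
identical digests.  The corrnet/networks/phenotype/report stages can rerun
from the on-disk outputs of earlier stages without re-training.  Any stage
failure aborts with the stage name; partial outputs are preserved.  The
`salnet` console script is a thin argparse wrapper over these stages.

## What the synthetic results show — and what they do not

The generator plants exactly the structure the analysis assumes: additive,
region-aligned intensity effects, one latent factor per region block,
linear subscores, controls on the low tail.  Passing recovery tests
therefore show that the pipeline's statistics *can* recover such structure
when present, at the stated sizes and noise levels, and the null tests
show the significance machinery is calibrated when it is absent.  They do
not show that real T1-weighted morphometry carries such signals, that a
gradient saliency map of a full-scale network localises them, or that any
particular accuracy is attainable on clinical data — real cohorts add
registration error, site effects, age and sex structure, and morphometric
(not intensity) differences that this generator does not emulate.
Reported desk-scale accuracies are properties of the synthetic regime
only.

## Numerical and degenerate-input conventions

Float32 model arithmetic with seeded numpy RNGs throughout; convolution as
patch-matrix products, with the input gradient evaluated as a
stride-stuffed flipped-kernel convolution (verified against finite
differences).  Batch-norm uses running statistics at evaluation.  Kendall
pairs with a constant column are excluded with a warning rather than
propagated as NaN; empty graphs report undefined fractions; an empty
control set, a single-subject group in an STD panel, or fewer than two
regions in a hemisphere are errors, not silent zeros.  Tie-breaks in every
ranking are total (statistic, then p, then region id) so outputs are
deterministic under ties.
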