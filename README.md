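# salnet

Saliency-correlation network analysis for structural-MRI severity
classifiers — with a fully synthetic, ground-truthed cohort generator.

## The problem

Given T1-weighted structural MRI volumes from subjects spanning a severity
spectrum (quantified by the Social Responsiveness Scale: a total plus five
subscores — cognition, awareness, communication, mannerisms, motivation),
the analysis asks three questions:

1. **Can a volumetric classifier separate high from low severity?**
   A 3D residual bottleneck CNN (with softmax / tanh / sigmoid heads, a 2D
   per-slice-range variant, and hybrid variants that feed an *n*-unit
   feature layer into a kNN or SVM) is trained on scored subjects only.
2. **Which brain regions drive the decision?**  Voxel saliency
   s(v) = |∂(class score)/∂x_v · x_v| is extracted per subject and averaged
   over the regions of a two-hemisphere parcellation (75 cortical + 13
   subcortical regions per hemisphere plus brain stem and fornix),
   yielding a subjects × regions saliency matrix.
3. **How are salient regions organised?**  Pairwise Kendall τ-b between
   region columns (significance-filtered at α = 0.01, thresholded at
   τ > 0.4, swept over τ ∈ {0.1, …, 0.6}) defines correlation graphs whose
   degree-ranked hubs, functional-network involvement percentages,
   spring-layout embeddings, lobe/hemisphere composition fractions,
   SRS-subscore correlation tables (p < 0.05 over 150 cortical regions),
   hemisphere t-tests (pooled over per-region means, df = n_L + n_R − 2),
   and control-vs-low-severity congruence summarise the structural
   network picture.

Real cohorts of this kind are access-restricted, so the package ships a
synthetic-cohort generator that plants severity-dependent effects in known
region blocks with known latent loadings, hemispheric bias and
subscore weights — every downstream statistic can therefore be tested as a
*parameter-recovery* problem against the generator's truth.  The CNN
machinery itself (2D/3D convolution, batch norm, pooling, Adam, and
backprop to the input for saliency) is implemented in numpy inside the
package, so there is no deep-learning-framework dependency.

## Worked example

```python
from salnet import run_pipeline, report

cfg = {
    "cohort": {"n_high": 20, "n_low": 20, "n_control": 8, "grid": 32,
               "n_cortical_per_hemi": 20, "n_subcortical_per_hemi": 4,
               "n_lobes": 4, "n_latents": 2,
               "affected_cortical_per_block": 5,
               "affected_subcortical_per_block": 1},
    "train": {"epochs": 8, "batch_size": 8, "learning_rate": 2e-3,
              "test_size": 10, "ensemble": 2},
    "corrnet": {"top_edges": 100, "top_n": 10},
    "seed": 42,
}
run_pipeline(cfg, "demo_run")
print(report("demo_run"))
```

prints (abridged):

```
[classifier accuracies]
  softmax    1.0000 (trained head)
  hybrid-kNN 1.0000
  hybrid-SVM 1.0000

[region saliency]
  top regions by mean saliency: 35, 38, 25, 8, 34, 37, 46, 45, 29, 17
  LH mean 1.080098  RH mean 0.964180  t=1.018 p=3.150e-01 df=38

[threshold-averaged hubs]
  region   34  avg connections 8.33
  region   37  avg connections 7.83
  ...
  (threshold divisor: 6)

[subscore-correlated regions, LH/RH]
  awareness      9/2
  cognition      0/1
  ...

[control congruence]
  r=0.8953 slope=0.8729 intercept=0.127145 over 50 regions
```

Reading it: the 40 scored subjects of this 32³ demo cohort separate
perfectly on the held-out test set; the hub table lists the regions whose
saliency correlates (τ-filtered, averaged over the six thresholds — hence
the divisor 6) with the most other regions, and regions 34/37/38 are
members of the generator's planted blocks; `9/2` means nine left- versus
two right-hemisphere regions correlate significantly with the awareness
subscore; and the control group's regional saliency profile is nearly
collinear with the low-severity group's (r ≈ 0.90), i.e. unscored controls
land on the low end of the severity spectrum.  At the default study scale
(48³, 150 subjects, 4 latent blocks, 3-model saliency ensemble) the same
pipeline recovers the planted block partition exactly (adjusted Rand
index 1.0) and the left-hemisphere dominance at p < 10⁻⁵ with df = 148.

The `salnet` console script wraps the same stages
(`salnet run --config cfg.json --out run/ --seed 1`, plus per-stage verbs
and `salnet report --out run/`).

## Layout

| Module                | Contents |
| --------------------- | -------- |
| `salnet.core`         | domain types (volumes, atlas, records, saliency matrix) |
| `salnet.synthetic`    | cohort/atlas generator with planted ground truth |
| `salnet.io`           | NIfTI / TSV / GraphML / JSON readers and writers |
| `salnet.nn`           | numpy CNN engine (conv, BN, pooling, Adam, backprop) |
| `salnet.classifiers`  | residual classifiers, heads, hybrids, slice ranges |
| `salnet.saliency`     | voxel saliency, regional aggregation, hemisphere tests |
| `salnet.corrnet`      | Kendall-τ graphs, hubs, layouts, composition |
| `salnet.phenotype`    | network involvement, score tables, avg/STD grid, congruence |
| `salnet.pipeline`     | stage orchestration, manifests, reports |
| `salnet.cli`          | `salnet` console entry point |

See `docs/methods.md` for the models, defaults, and the limits of what the
synthetic benchmarks establish.
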