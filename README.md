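# subtyper

Deep-learning ensemble clustering for discovering neurobiological patient
subtypes from voxelwise resting-state ALFF (amplitude of low-frequency
fluctuations) maps.

Trans-diagnostic psychiatric cohorts are clinically heterogeneous: patients
who share a DSM diagnosis can differ sharply in resting-state brain
function, and patients with different diagnoses can look alike.  `subtyper`
implements a clustering workflow designed for exactly this setting and aimed
at researchers who have per-subject ALFF volumes in a common space, a brain
mask, and a phenotype table, and who want data-driven subtypes that are
*stable* rather than artifacts of one particular embedding of the data.

## Method

1. **Voxel screen.**  A voxelwise GLM of ALFF on group (patient/control)
   with sex and mean-centered age as covariates; the two-sided group
   *t*-map is thresholded at voxel *p* < 0.001 and cluster-corrected at
   *p* < 0.05 using Gaussian-random-field theory (residual smoothness
   estimated from standardized-residual gradients) or, alternatively, a
   Freedman–Lane permutation null of the maximal cluster extent.  When the
   supervised screen retains nothing — which happens when subtype effects
   are sign-opposed and cancel in the group mean — the pipeline falls back
   to an unsupervised high-variance voxel screen.
2. **Embedding.**  A symmetric AutoEncoder per bottleneck dimension
   d ∈ [2, 10], with the halving layer schedule
   `n → 2048 → 1024 → 512 → 256 → 128 → 64 → 32 → d` (for n = 2175 inputs),
   ReLU hidden layers, linear bottleneck/output, trained with Adam on mean
   squared reconstruction error.
3. **Ensemble clustering.**  Complete-linkage agglomerative clustering
   (Euclidean distance) of each of the nine latent representations; the
   nine partitions are label-aligned by optimal one-to-one matching and
   each subject gets the plurality label ("consensus").
4. **Robustness merging.**  The whole embed–cluster–consensus procedure is
   re-executed J times (default 6) with fresh AutoEncoder seeds.  Each
   cluster *i* receives a robustness index

   R_i = |⋂_j C_i^j| / |⋃_j C_i^j|,

   where C_i^j is cluster *i*'s matched member set in run *j*.  The two
   least-robust clusters are merged iteratively until every cluster
   satisfies R_i > δ (default 0.8).
5. **Validation.**  Subtype-vs-control contrast maps with voxelwise
   Cohen's *d*, Welch *t*-tests on clinical factor scores with
   Benjamini–Hochberg FDR, and logistic associations of continuous risk
   scores with subtype membership summarized by Nagelkerke's pseudo-R².

A fully synthetic cohort generator (`subtyper.simulate`) plants latent
subtypes with sign-opposed frontal/posterior effects, covariate effects and
Gaussian voxel noise, so the entire pipeline is testable end-to-end with a
known ground truth.

## Worked example

```python
from subtyper import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({
    "simulate": {"n_patients": 200, "n_controls": 100,
                 "grid_shape": [16, 16, 16], "effect_size": 1.0},
    "robustness": {"J": 6, "delta": 0.8},
    "master_seed": 1,
})
result = run_pipeline(cfg)
print("subtype sizes:", result.subtype_labels.value_counts().to_dict())
print("robustness:", [round(r, 3) for r in result.report.robustness])
print("ARI vs planted truth:", result.ari_vs_truth)
```

Output:

```
subtype sizes: {0: 100, 1: 100}
robustness: [1.0, 1.0]
ARI vs planted truth: 1.0
```

The simulated cohort hides two equal-sized patient subtypes with opposed
frontal/posterior ALFF shifts of one noise standard deviation.  The
pipeline recovers both subtypes exactly (adjusted Rand index 1.0 against
the planted labels), and both survive the robustness criterion without
merging (R = 1.0 across all six runs).

The same workflow is scriptable from the shell:

```bash
subtyper run --config config.yaml --out results/ --seed 1
```

with `simulate`, `select`, `embed`, `cluster`, `merge` and `validate`
subcommands for stage-by-stage use on real or simulated cohorts.

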