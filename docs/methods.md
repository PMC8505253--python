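# Methods

This note documents the models, defaults and design decisions behind
`subtyper`, and what the synthetic-cohort experiments do and do not show.

## Synthetic cohort model

The generator emulates a two-arm case/control resting-state ALFF study in
which the patient arm contains latent subtypes.  Per subject, the volume is

```
y(v) = baseline + beta_age * z_age + beta_sex * (sex - 1/2)   [mask voxels]
     + s_k(v) * effect_size * sigma                           [patients only]
     + sigma * eps(v)
```

where `s_k(v) ∈ {+1, −1, 0}` is subtype *k*'s sign pattern over the
designated "frontal" and "posterior" mask regions (subtype 1: frontal +,
posterior −; subtype 2 the converse), and `eps` is i.i.d. standard normal
noise, optionally smoothed with a Gaussian kernel (FWHM in voxels) and
rescaled to unit marginal variance so that `effect_size` remains a per-voxel
Cohen's *d* in noise-SD units.  Covariates are global over the mask — the
simplest model satisfying the screening GLM's assumptions.  Defaults
(200 patients, 100 controls, 16³ grid with a ~50% ball-shaped mask — about
2,000 mask voxels, comparable to real whole-brain analyses at desk scale —
two equal subtypes, `effect_size=1`, `noise_sd=1`, age 18–60 uniform,
`age_beta=sex_beta=0.2` SD) are the package's reference study conditions.
Clinical "factor" columns and continuous "risk score" columns (polygenic
score stand-ins) are drawn standard normal with configurable shifts tied to
subtype-1 membership (`factor_effect=0.8`, `score_effect=0.8`,
`medication_effect=0.5` attenuating factor 1 in medicated subtype-1
patients).  Ground-truth labels are stored in a separate truth file so the
pipeline cannot consume them.

What the simulation does **not** emulate: realistic spatial covariance of
ALFF (the smoothing knob is a stand-in, not an estimate), site/scanner
effects, non-Gaussian noise, partial-volume effects, or correlated
covariates.  Passing tests therefore demonstrate algorithmic correctness
and statistical calibration under the stated model, not performance on real
scanner data.

## Voxel screen

Ordinary least squares per mask voxel with design
`[intercept, group, sex, age_centered]`; the group coefficient is tested
two-sided with `t = β̂/se(β̂)` at `n − rank(X)` degrees of freedom.  Age is
mean-centered and the binary factors coded 0/1 for numerical stability;
this leaves the group contrast unchanged.  Rank-deficient designs raise an
error naming the collinear columns.

Cluster correction binarizes |t| at the two-sided voxel-p critical value
(t distribution, not normal), extracts connected components with
26-connectivity (configurable to 6/18), and assigns corrected p-values by:

- **GRF** (default): smoothness is estimated per axis from the variance of
  first differences of standardized residuals
  (`FWHM = sqrt(4 ln 2 / λ)`, floored at 1 voxel; white noise ⇒ ≈1.18
  voxels).  Expected cluster count uses the 3-D Euler-characteristic
  density at the Gaussianized threshold times the resel count (both test
  sides contribute), cluster extent follows the classical
  `P(N ≥ k) = exp(−β k^{2/3})` approximation, and the corrected p is the
  Poisson clumping bound `1 − exp(−E[m] P(N ≥ k))`.
- **Permutation**: Freedman–Lane residual permutation under the reduced
  (covariates-only) model; the corrected p of a cluster is the proportion
  of permutations (with the +1 correction) whose maximal suprathreshold
  extent reaches the observed extent.  This is the calibration oracle for
  the GRF path.

Sign-opposed subtype effects in equally sized subtypes cancel in the
patient-vs-control mean, leaving the supervised screen blind to exactly the
structure of interest while still inflating patient-arm variance at
affected voxels.  The pipeline therefore falls back — only when cluster
correction retains nothing — to the top-N mask voxels by patient variance
(N = 512 by default), the volumetric analogue of highly-variable-gene
selection.  The spec of the screening module itself is unchanged: an empty
selection passed to feature extraction is still an error.

Feature selection is fit on all subjects (patients vs controls), but the
feature matrix handed to clustering contains patients only.

## AutoEncoder

One independent AutoEncoder per bottleneck width d (the schedule ends
`… 32 → d`, implying a per-d bottleneck rather than a truncated shared
model).  The encoder halves from the largest power of two strictly below
the input width down to 32, then maps to d; the decoder mirrors the
encoder.  Hidden layers are ReLU; the bottleneck and output are linear,
which suits z-scored inputs of either sign.  Features are z-scored per
column before training (stored transform reapplied at encode time);
otherwise the MSE objective would be dominated by high-variance voxels.
Constant columns either raise an error or are dropped, per configuration.

Training is end-to-end (no greedy layer-wise pretraining) with Adam,
learning rate 1e-3, batch size 32, float32 arithmetic, He initialization.
The trainer tracks full-data MSE per epoch, keeps the best-loss weights,
and optionally stops early when the relative improvement stays below a
tolerance (pipeline default 1e-4, patience 10).  All randomness (weight
init, batch order) derives from the config seed, so identical inputs and
seed yield bit-identical latents.  Non-finite losses abort with a
diagnostic suggesting a lower learning rate.  The pipeline default of 60
epochs is the desk-scale operating point: on rank-d data the linear-path
optimum (the PCA solution) is reached to within 1% of the data variance
under a generous epoch budget, and on the reference conditions the loss
curve is flat well before 60 epochs.

## Ensemble clustering and consensus

Each latent matrix is clustered by complete-linkage agglomeration on
Euclidean distances, cut at exactly k clusters.  k is shared across the
nine representations; by default it maximizes the mean silhouette over
k ∈ [2, 10] computed on the first run's latents — the number of
intermediate clusters is the largest open choice in this workflow, and the
silhouette rule makes it explicit and reproducible.  Labels are aligned to
the median-d partition (d = 6) by maximum-agreement one-to-one assignment
on the contingency table; clusters without a counterpart receive fresh
labels above the reference range.  Consensus is the per-subject plurality
vote with deterministic smallest-label tie-break; subjects whose winning
label got under half the votes are flagged as low-agreement rather than
dropped.

## Robustness merging

A "run" is a re-execution of all nine AutoEncoders with fresh seeds plus
re-clustering and consensus; the (deterministic) voxel screen is not
repeated.  AE initialization is the stochastic element this step targets —
runs vary the algorithm, not the sample, so no subject resampling is done.
The reference partition is the grand consensus of the J run consensuses.
For each reference cluster, its counterpart in each run is found by optimal
Jaccard matching (unmatched ⇒ empty set), and
`R_i = |⋂_j C_i^j| / |⋃_j C_i^j|` (empty union ⇒ 0).  While
`min R_i ≤ δ` (strict "greater than δ" stopping) and more than one cluster
remains, the two lowest-R clusters (ties by smaller index) are merged in
the reference *and* inside every run's matched sets, so the recomputed R
reflects the merged entity; recomputation after each merge is the only
self-consistent reading of an iterative scheme.  The loop performs at most
k₀ − 1 merges, and the final partition is always a coarsening of the
reference.  Defaults J = 6, δ = 0.8.

## Validation statistics

- Subtype-vs-control contrast maps reuse the screening GLM and correction
  on the subtype + all-controls subset, and add voxelwise Cohen's *d*
  (pooled-SD convention, df-weighted).  Subtypes with fewer than 3 members
  are refused.
- Factor scores: Welch (unequal-variance) two-sample *t*-tests — subtype
  arms are typically unbalanced — with Benjamini–Hochberg FDR across the
  factors of one comparison family (q = 0.05), 95% CIs at
  Welch–Satterthwaite df, and Cohen's *d* per row.  Untestable factors are
  flagged, not dropped.
- Risk scores: per-column maximum-likelihood logistic regression of the
  subtype-vs-control indicator on the score (covariates optional, off by
  default), Wald p, and Nagelkerke pseudo-R²
  `[1 − (L₀/L₁)^{2/n}] / [1 − L₀^{2/n}]`, which is invariant to affine
  rescaling of the score.  Significance defaults to α = 0.004, a
  conservative level for the many correlated thresholds a polygenic-score
  screen typically evaluates.  On (quasi-)separation the fit falls back to
  a small L2 penalty, reports a bounded R² with a convergence flag, and
  never crashes.

## Pipeline and reproducibility

A master seed deterministically derives every stage seed through
`SeedSequence(master, spawn_key=(stage, …))` counters (all below 2³¹); the
simulation seed is derived from the master seed unless set explicitly in
the simulation section.  Stage outputs are pure functions of inputs and
stage seed; when an output root is set, each stage writes artifacts plus a
JSON manifest keyed by a configuration hash, and the cohort and
per-run-labels stages are reloaded from cache on re-execution (embedding
checkpoints are not cached individually — the run level is the unit of
resumability).  Config files are YAML with strict unknown-key rejection.

## Numerical choices and degenerate inputs

- t statistics with zero standard error report t = 0 (p = 1) rather than
  NaN; constant residual fields make smoothness undefined and raise.
- Duplicate subjects merge at distance zero and are always co-clustered.
- Hierarchical-cut labels are renamed by first occurrence, making cluster
  numbering deterministic.
- Empty suprathreshold maps are a valid (empty) screening result, not an
  error; only feature extraction from an empty selection raises.
- GRF expected counts are floored at 1e-300 to avoid underflow at extreme
  thresholds.

## Known limitations

- The high-variance fallback assumes subtype effects inflate marginal
  variance; weak or perfectly variance-balanced effects would evade both
  screens.
- GRF corrected p-values rely on smooth-field assumptions; at FWHM near one
  voxel they are conservative relative to the permutation oracle.
- The silhouette k-rule can undercount clusters when subtypes overlap
  heavily; the robustness merge can only coarsen, never split, so an
  undersized k is unrecoverable downstream.
- Up to four sign patterns are defined for planted subtypes; more subtypes
  require user-supplied patterns.
- Consensus invariance to relabeling holds when the optimal matching is
  unique; with exactly tied contingency tables the tie-break is
  implementation-defined.
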