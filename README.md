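# affordmap

Simulation and analysis of **affordance coding in conceptual state spaces**:
a complete, tested pipeline for experiments in which participants navigate
a number line whose states afford specific actions, and the question is
whether those *afforded actions* — rather than state identity or graph
distance — are reflected in multivoxel fMRI patterns and in gaze behavior.

The package is aimed at cognitive-neuroscience researchers who want to
prototype, power, or validate this style of analysis end-to-end without
any participant data: a synthetic-data generator produces whole cohorts
(BOLD runs, binocular gaze streams, probe behavior) with known ground
truth, and every estimator in the chain is tested for calibration and
recovery against that truth.

## The task and the models

States 1–4 occupy four consecutive integers followed by one unused number;
the module tiles the number line with period 5, so state structure
generalizes to unseen numbers (if 29 affords 27 and 31, then 79 affords 77
and 81). Affordances are S1 = {−2, +2}, S2 = {+1, +2}, S3 = {−2, −1},
S4 = {−2, +2}. Three model RDMs over the four states (canonical
upper-triangle vectors in the order 1-2, 1-3, 1-4, 2-3, 2-4, 3-4):

- **affordance** `d(i,j) = 2 − |A_i ∩ A_j|` → (1, 1, 0, 2, 1, 1)
- **link distance** (shortest path) → (2, 1, 1, 1, 1, 2)
- **action magnitude** (shared unsigned magnitudes) → (1, 1, 0, 0, 1, 1)

Affordance and link distance are exactly decorrelated by design.

The neural side uses the cross-validated Mahalanobis ("crossnobis")
distance: per-run GLM betas `b_i^m` are whitened with a shrinkage estimate
Σ̂ = (1−γ)S + γ·diag(S) of the residual covariance, and

```
d(i,j) = mean over run pairs m<n of (b_i^m − b_j^m)ᵀ Σ̂⁻¹ (b_i^n − b_j^n) / P
```

(P voxels). Cross-validation makes the estimator unbiased, so null
distances center on zero and can be negative. Neural RDMs are compared to
the affordance model with a tie-corrected Spearman correlation, partialling
out link distance and magnitude by the recursive formula
`r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` in rank space; subject
coefficients are Fisher z-scored and tested with a one-sample t
(one-sided, Bonferroni α = 0.025 for the two-hemisphere family).

The ocular side scrubs blinks (±100 ms), averages the eyes, epochs
[−500, 2500] ms around onset, takes per-timepoint condition medians
(σ = 4.25 ms truncated Gaussian smoothing), and tests the state-2 − state-3
x difference across subjects with a one-sample-t cluster permutation test
(sign-flip null over maximum cluster mass, one-tailed α = 0.05). Per-subject
effect sizes (median difference over the significant cluster) are
correlated with probe performance and with the RMS-normalized neural
(2,3) distance.

## Worked example

Simulate a 16-subject cohort with a planted affordance geometry
(signal scale 6) and a planted +20 px gaze lateralization, then run every
stage:

```bash
cat > demo.yaml <<EOF
generative:
  n_subjects: 16
  n_runs: 4
  n_trials: 40
  n_probe: 8
  n_voxels: 60
  signal_scale: 6.0
  gaze_runs: 2
  gaze_hz: 500.0
  gaze_shift: 20.0
seed: 7
n_perm: 2000
EOF
affordmap all --config demo.yaml --out demo_out
affordmap report --out demo_out
```

prints

```
affordance_partial: t(15) = 3.376, p = 0.00208
gaze cluster window: 906-1744 ms
```

and the rendered report:

```
- **affordance_partial**: t(15) = 3.376, p = 0.00208 (alpha 0.025)
- gaze cluster 560-670 ms, p = 0.1419
- gaze cluster 906-1744 ms, p = 0.0004998
- gaze-performance r = 0.042, p = 0.8779
- brain-gaze r = 0.185, p = 0.4923
```

Reading the output: the group affordance effect (partialling link distance
and magnitude) is recovered at p = 0.002, significant at the corrected
α = 0.025; the cluster test re-identifies the planted lateralization
window (generated at 899–1,757 ms, recovered 906–1,744 ms, p ≈ 0.0005)
while a spurious early cluster stays non-significant. The two linking
correlations hover near zero — correctly, because this cohort plants the
*same* shift and geometry in every subject, leaving no between-subject
variation for a correlation to track.

The same stages are available as library calls (`simulate_subject`,
`fit_glm`, `crossnobis_rdm`, `partial_spearman`,
`cluster_permutation_test`, …); see `docs/methods.md` for the full model
description, parameter defaults, and calibration results.

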