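# Methods

`affordmap` re-implements, on fully synthetic data, an analysis pipeline
for asking whether *action affordances* — the set of moves available from a
state — are reflected in multivoxel fMRI patterns and in gaze behavior,
when the state space is a conceptual one (a number line) rather than a
physical environment.

## The task model

The environment is a repeating four-state module tiled along the number
line with period 5: states 1–4 occupy four consecutive integers, the fifth
integer is unused, and the pattern repeats (`21 22 23 24 · 26 27 28 29 ·`
…). Every number is greater than 20. Each state affords exactly two signed
arithmetic actions:

| state | actions | unsigned magnitudes | successor states |
|-------|---------|--------------------|------------------|
| 1 | −2, +2 | {2, 2} | 3, 4 |
| 2 | +1, +2 | {1, 2} | 3, 4 |
| 3 | −2, −1 | {1, 2} | 1, 2 |
| 4 | −2, +2 | {2, 2} | 1, 2 |

The construction is closed: every afforded action maps a state-bearing
number to a state-bearing number (verified at the residue level at graph
construction). Shifting the module offset relabels numbers per participant
without changing any state-level structure.

Recall-task runs contain 80 trials, 16 of which are probe trials (a
candidate successor pair to accept/reject; half are the true successors).
The 64 stimulus-trial conditions are serially counterbalanced: the 63
ordered transitions are spread over the 16 ordered state pairs with counts
differing by at most 1. Because 64 ≡ 0 (mod 4), the shortfall relative to
a uniform allocation is always 1 (mod 4), which we realize exactly by
deleting k balanced-degree arc sets plus one path-creating arc from the
uniform transition multigraph and walking a randomized Eulerian path. This
also makes condition counts exactly equal — no restart search over
sequences is needed.

ISIs are truncated-exponential on [0.5, 8.0] s with the rate solved
(Brent) so the post-truncation mean is 3.0 s (fMRI) or 2.5 s
(eyetracking). The drawn ISIs are permuted (up to 10,000 shuffles) until
the Spearman correlation between each ISI and the model-based distance of
its flanking trial pair is below 0.1 in magnitude for every supplied model
RDM; the bounds and search budget are package choices, as is the 1.5 s
stimulus duration (chosen so run durations land near the 6–7 minute runs
the schedule implies).

## Model RDMs

All RDMs are 4×4, symmetric, zero-diagonal, and share one canonical
vectorization (upper triangle in the order 1-2, 1-3, 1-4, 2-3, 2-4, 3-4).

- **Affordance**: 2 − |shared signed actions|; vector (1, 1, 0, 2, 1, 1).
- **Link distance**: shortest path on the state graph; vector
  (2, 1, 1, 1, 1, 2). Computed on the undirected graph; under these
  affordances directed distances are identical (tested against a directed
  BFS oracle).
- **Action magnitude**: 2 − |shared unsigned magnitudes|, multiset
  semantics by default (so S1 ≡ S4 and S2 ≡ S3, vector (1, 1, 0, 0, 1, 1));
  set semantics available via a flag.
- **Behavioral**: per-subject absolute RT difference, or 2-D Euclidean
  distance between median gaze positions.

The affordance and link-distance vectors have exactly zero Pearson
correlation — the design deliberately decorrelates the hypothesis from the
classic state-space control. One caveat we document rather than hide: a
dissimilarity model counting shared successor *states* correlates with the
magnitude model at r = −0.5 under both set and multiset semantics, not
−1.0; `shared_successor_rdm` exists so this can be checked directly, and
the frozen value lives in the test suite.

## Synthetic data generator

Defaults mirror the study conditions: 57 subjects, 8 fMRI runs (80 trials,
16 probes, TR = 1 s), ~140 voxels (a right entorhinal ROI), 4 eyetracker
runs at 1,000 Hz, probe response windows 1.4 s (fMRI) / 1.2 s
(eyetracking), and a gaze-lateralization window of 899–1,757 ms after
stimulus onset.

**BOLD.** Ground-truth condition patterns are constructed by classical MDS
from a weighted mixture of the model RDMs treated as squared distances
(`embed_geometry`); the low-dimensional configuration is rotated into
voxel space through a seeded random orthonormal basis, so pairwise squared
distances equal `signal_scale ×` the target exactly and patterns are
centered. Per run, BOLD = design × (patterns + run jitter) + AR(1) noise
(coefficient 0.3) with an exponential spatial correlation over voxels
(length scale 2 voxels; diagonal option for oracle tests) — non-diagonal
noise is what the Mahalanobis whitening is for, so the generator must
produce it. Nuisance (probe) events get random per-run amplitudes.

**Gaze.** A slow fixational drift (Gaussian noise smoothed at ~50 ms, sd
25 px) around screen center, plus per-eye white jitter (3 px); state-2
trials add +shift and state-3 trials −shift (default 15 px) on x inside
the configured window, with 100 ms linear ramps at the window edges to
avoid discontinuity artifacts in the smoothing stage. Blinks are
Poisson-placed (0.25 /s, 100–300 ms) flagged gaps.

**Behavior.** Probe responses are Bernoulli(accuracy = 0.85); RTs are
Gaussian around per-state means (0.60/0.66/0.66/0.60 s, sd 0.12 s), and
draws beyond the response window become flagged missed responses. These
behavioral parameters are invented but realistic: accuracy well above the
binomial-test inclusion threshold, RT differences large enough that the RT
RDM is a meaningful covariate.

What the generator does *not* emulate: retinotopy or any true visual
response, saccade dynamics (drift is a stand-in for fixational behavior),
head motion, physiological noise structure, scanner drift, or learning
dynamics. Passing recovery tests therefore show the *estimators* are
correct and calibrated, not that real data would behave this way.

## Estimation

**GLM.** Stick regressors per state convolved with a canonical
double-gamma HRF (peak delay 6, undershoot delay 16, ratio 1/6 — peak near
5 s), sampled on the TR grid from a 0.1 s internal grid; probe and other
event types get their own regressors; intercept included; rank checked.
Plain OLS per voxel; residuals feed the noise model.

**Crossnobis.** Noise covariance per run from GLM residuals with
diagonal-target shrinkage Σ̂ = (1−γ)S + γ·diag(S), γ analytic
(Schäfer–Strimmer) by default. Betas are whitened by Σ̂^(−1/2) and the RDM
entry is the mean over unordered run pairs of the inner product of
condition-difference patterns from the two runs, divided by the voxel
count (so values are comparable across ROI sizes). The estimator is
unbiased: entries may be negative, and pure-noise simulations center on
zero. Robustness procedures: mean-RDM positivity, split-half
permutation-based reliability voxel selection, and across-participant
noise ceilings (upper: correlation with the group mean; lower:
leave-one-out).

**Inference.** Tie-corrected Spearman = Pearson on midranks. Partial
correlation by the first-order recursion applied covariate-by-covariate in
rank space; order invariance is asserted at runtime (violations beyond
round-off indicate rank-collinear covariates) and the recursion is tested
to 1e-10 against an independent rank-regression-residual implementation.
Group inference: Fisher z, one-sample t, one-sided for directional
hypotheses; Bonferroni α = 0.05/2 = 0.025 for the two-hemisphere family,
0.05/6 ≈ 0.0083 for pairwise RT contrasts.

**Gaze.** Blinks ±100 ms masked (boundary-inclusive), eyes averaged,
epochs [−500, 2500] ms, per-timepoint condition medians with masked
samples excluded (no interpolation — medians tolerate missingness),
truncated-Gaussian smoothing (σ = 4.25 ms, ±10 ms support, renormalized).
The state-2 − state-3 x difference is tested with a one-sample-t cluster
permutation test: cluster-forming threshold = one-tailed t₀.₀₅ at df = n−1
(configurable), cluster mass = summed t, null = max mass over random
per-subject sign flips, p = (1 + #{null ≥ obs})/(1 + n_perm). The
implementation is vectorized over permutations and agrees
cluster-for-cluster with MNE's `permutation_cluster_1samp_test` in the
test suite. Effect size per subject = median difference over the
significant cluster window, correlated with probe accuracy (Pearson) and,
after RMS normalization of each subject's RDM vector, with the neural
(2,3) distance.

## Calibration and problem sizes

Monte-Carlo acceptance checks run the complete chain on scaled-down
cohorts, a deliberate package choice so the whole suite runs on one CPU:

- fMRI branch: 4 runs × 20 trials, 16 voxels. Null calibration: 500
  cohorts of 20 subjects; the one-sided group test at α = 0.05 rejects at
  the nominal rate (checked against a 99% binomial interval).
- Recovery: signal scale 3.5 under those conditions gives subject-level
  mean partial correlation ≈ 0.3 with z-scale sd ≈ 0.76; with 28-subject
  cohorts the analytic power is ≈ 0.86, and the 200-cohort empirical power
  check requires > 0.80. (At 20 subjects this SNR gives only ~74% power —
  the subject-level 6-point rank correlation is intrinsically coarse, so
  the recovery configuration uses the larger cohort.)
- Gaze branch: one 16-trial run per subject at 500 Hz; 500 null cohorts of
  20 subjects with 500 permutations each for familywise-error calibration;
  planted-shift recovery (40 px, low drift) must re-identify a cluster
  overlapping 899–1,757 ms in > 95% of cohorts.

## Numerical notes and limitations

- Degenerate inputs raise typed errors: constant vectors in correlations,
  |r| = 1 in Fisher z, rank-deficient designs (offending columns named),
  non-embeddable RDM mixtures (negative Gram eigenvalue), single-run
  crossnobis, fully-masked gaze streams.
- Zero-variance voxels in the covariance trigger a warning and a small
  ridge; the shrunk covariance is Cholesky-checked.
- The Euclidean embedding requires the mixture to be a valid
  squared-distance matrix; all nonnegative mixtures of the three model
  RDMs used here are embeddable.
- Permutation p-values use the +1 correction and are never exactly zero.
- Only the `greater` tail is implemented for the cluster test, matching
  the directional hypothesis; a two-tailed variant would need a different
  null summary.
- The pipeline is deterministic in the seed: subject simulations draw from
  `SeedSequence.spawn`, and the report hash is a pure function of the
  configuration.
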