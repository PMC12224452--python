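# Methods

`crossgen` implements a cross-paradigm multivariate decoding analysis for
source-space MEG epochs: does a neural signature of semantic composition
(adjective–noun phrase vs. single noun) learned in a controlled two-word
paradigm generalize to naturalistic story listening, and does the later
latency of the naturalistic effect survive regression of stimulus
confounds? Because raw MEG recordings are not an input to this package, the
pipeline is exercised end-to-end on a synthetic source-space generator that
reproduces the statistical structure the analysis is sensitive to.

## Source-space geometry

Source spaces are icosahedral meshes: recursive edge-midpoint subdivision
of a regular icosahedron projected to the unit sphere, with vertices
deduplicated by first occurrence (a deterministic ordering). A level-k mesh
has `10·4^k + 2` vertices; level 4 reproduces the 2562
sources-per-hemisphere convention, while tests and demonstrations use
levels 0–2 (12–162 sources).

Anatomical labels are replaced by a deterministic partition of the sphere
into six contiguous caps (Voronoi cells of farthest-point-sampled seeds)
named after the left-hemisphere language-mask regions — LATL, LMTG, LIFG,
LvmPFC, LAG, LSMG — so that result summaries can speak the field's
vocabulary. The language mask is the union of named regions, in ascending
vertex order.

A "searchlight radius of 20 sources" is interpreted as a 20-member set: the
center plus its 19 nearest masked neighbors. Distances are Euclidean chord
distances on the sphere, which are monotone in geodesic distance and hence
give identical neighbor orderings; ties break by ascending vertex index.
`k` is configurable. Cluster inference runs on a spatiotemporal graph whose
node `(v, t)` is adjacent to masked mesh neighbors at the same timepoint
and to `(v, t±1)`.

## Synthetic data generator

Epochs span 0–875 ms after target-word onset at 200 Hz, stored on the
half-open grid 0, 5, …, 870 ms (175 samples). The generative model is
additive:

1. **Noise**: i.i.d. Gaussian with SD `noise_sd` (default 1), then
   `spatial_smoothing_passes` (default 1) of neighbor averaging on the
   masked mesh graph, then AR(1) filtering along time with coefficient
   `temporal_ar1_phi` (default 0.3). The smoothing and autocorrelation are
   the package's own noise model — the covariance of real source estimates
   is not part of the design — and both are exposed in `SimConfig`.
2. **Class effects** (`EffectSpec`): a unit-norm spatial pattern over
   chosen vertices, fixed by `pattern_seed`, times an amplitude in noise-SD
   units, added to phrase-class epochs inside a latency window. Two
   paradigms sharing a `pattern_seed` but differing in window emulate one
   compositional signature expressed at different latencies.
3. **Confound loadings** (`ConfoundSpec`, naturalistic only): each of the
   seven word-level regressors is drawn standard normal per epoch-word;
   `class_shift` adds a standardized mean difference to the phrase class,
   and `loading_gain` adds `gain × z(regressor) × pattern` at the loading
   vertices/window. A class-shifted regressor with a late loading window
   creates a decodable late class difference that is entirely mediated by
   the confound — the structure the residualization analysis must remove.

Defaults are desk-scale conventions chosen once: 10 subjects, 40 epochs per
class (balanced, so 50% is an exact chance level), level-2 mesh. Per-subject
seeds are `master_seed XOR crc32(subject|paradigm)`, making every epoch set
a pure function of its configuration. Stimulus-side generators (word
tables, 10-ms prosody frames with a smooth per-word bump, rater-by-sentence
matrices `latent(s) + ε(r,s)`, and per-layer embedding sets with class /
context / word-position directions) store their own ground truth (e.g. true
per-word frame maxima) in clearly separated outputs used only as test
oracles.

What the generator does **not** emulate: source leakage from an inverse
operator, heteroscedastic sensor noise, evoked components common to both
classes, non-Gaussian artifacts, or real linguistic covariance between the
seven regressors (they are drawn independently, so the collinearity report
is exercised but never stressed). Passing tests therefore certify the
pipeline's statistical behavior — calibration, recovery, invariances — not
the neuroscientific claims themselves.

## Decoding

The classifier everywhere is a feed-forward network with one hidden layer
of two logistic units and a sigmoid output, trained on mean binary
cross-entropy with a small L2 penalty (1e-4). Ties at probability exactly
0.5 resolve to the noun class. Two trainers share this architecture:

* single fits (temporal generalization, embeddings) use L-BFGS with
  analytic gradients, at most 500 iterations, seed-controlled
  initialization;
* the searchlight sweep trains all (source × timepoint) cells of a fold
  simultaneously with full-batch Adam (learning rate 0.1, 200 steps,
  float32), vectorized over cells. A null-calibration run performs ~10^5
  independent fits; batching them is what keeps the sweep at minutes rather
  than hours, and full-batch training keeps it deterministic given the
  seed.

Features at a searchlight cell are the member sources' values at that
timepoint, z-scored with training-fold statistics (applied to the test
fold), which makes accuracy maps invariant to per-source affine rescaling.
Evaluation is stratified 5-fold cross-validation by default. Training-set
evaluation (`evaluation_mode="train"`) is also provided: testing training
accuracies against chance is a defensible reading of the original protocol,
but a flexible classifier's training accuracy is biased above chance under
the null, which would invalidate the group t-test — hence cross-validation
as the default.

## Group inference

Per-subject accuracy maps minus the 50% chance level enter a mass-univariate
one-sample one-tailed t-test (`sd` with n−1 denominator). TFCE enhances each
cell by `Σ_h extent_h(v)^E · h^H · dh` with the standard exponents E = 0.5,
H = 2; `dh` defaults to `max(t)/100` with a floor of 0.05 t-units, and the
threshold count is capped at 5000 per transform (degenerate permutations
can produce astronomically large t; refining `dh` upward there costs no
accuracy). Family-wise correction uses the max-statistic over sign-flip
permutations of subject deviations — exact under the symmetric one-sample
null. When `2^n_subjects` is below the requested permutation count the
flips are enumerated exhaustively and p-values are the exact
`count/n_flips`; Monte-Carlo mode uses the `(1+count)/(n+1)` convention so
p is never zero. Inside permutation schemes |t| is capped at 100: cells
where every subject decodes at exactly 100% have zero variance, and the cap
keeps them maximal (rather than infinite) in both observed and permuted
maps, leaving the comparison exact. Only above-chance accuracy is ever
flagged (one-tailed throughout).

Temporal generalization matrices are tested with a 2-D cluster-mass
permutation: cell-level one-tailed t against 0.5, forming threshold at the
t quantile of p = 0.05, 4-connected components scored by summed t, null =
max cluster mass under sign flips.

Clusters are reported with all three extent conventions (cells, distinct
sources, distinct timepoints) since reported "N sources" counts are
ambiguous among them.

## Temporal generalization

Classifiers are trained on **all** epochs of the training paradigm at each
timepoint of a training window — evaluation is on the other paradigm, so no
cross-validation is needed — and tested at every timepoint of the test
paradigm; z-scoring statistics come from the training data only. The source
set and window are normally taken from a significant spatiotemporal cluster
(`restrict_to_cluster`); an empty cluster raises an explicit "no significant
cluster" error rather than silently testing everything. Features are the raw
source values at the cluster's vertex set (ascending order), and per-timepoint
classifiers are independent (no temporal smoothing). For residualized
naturalistic data the default pairing trains on residuals and tests on the
raw two-word data.

## Confound regressors and residualization

The seven regressors: peak RMS intensity and peak f0 over the word's 10-ms
frames (a frame belongs to a word when its start lies in
`[onset, onset+duration)`); word rate = duration in ms / letter count;
log unigram frequency (natural log by default); surprisal = −log₂ P(word |
preceding words of the same sentence) from a pluggable provider (bits by
default — both log bases are configurable and irrelevant after z-scoring);
and per-sentence rater-mean valence and arousal broadcast to member words.
Inter-rater agreement is summarized by ISC: each rater's Pearson r with the
across-rater mean (which includes the rater, so the no-signal floor is
1/√R, not 0), averaged.

Residualization is per-subject and mass-univariate: at each (source,
timepoint), the epoch values are z-scored across epochs (per cell) and
regressed by OLS on the seven z-scored regressors plus an intercept; the
residuals replace the data. Residuals are exactly orthogonal to every
regressor, and re-residualizing is a no-op (already-residualized input
skips the dependent-variable z-scoring, which would otherwise rescale each
cell). Rank-deficient designs are rejected with the dependent columns
named. Note that removing a class-correlated regressor necessarily removes
the class-signal component it explains: a genuine effect survives
residualization only to the extent it is not collinear with the confounds —
which is precisely the question the analysis asks.

## State space

Classical (Torgerson) MDS — double-centered Gram eigendecomposition of
squared Euclidean distances — embeds the per-timepoint phrase and noun mean
patterns from a cluster's sources into one shared 2-D space (all
`2 × n_times` condition-mean vectors embedded jointly, so trajectories are
comparable across time). The embedding is deterministic; reflections are
canonicalized by making each output dimension's largest-|value| entry
positive. The phrase–noun distance timecourse is reported both in the 2-D
embedding and in the full feature space, since truncation can distort
distances.

## Embedding analyses

The embedding side consumes per-layer vectors from a provider interface;
the package ships only the synthetic generator (class, context and
word-position directions in orthogonal axes). Word-position residualization
regresses the binary first/later-token indicator out of every embedding
dimension per layer. Because single nouns are first tokens only in the
two-word context, the indicator is *inherently* correlated with class
there; residualization therefore attenuates and recenters the two-word
class axis rather than removing "only the position direction" — an
intrinsic property of the correction, visible in the tests. Cross-context
classification fits the same two-unit network on one context
(standardizing with training-context statistics) and reports training-set
and other-context accuracies; with a shared class axis plus a context
offset this reproduces the qualitative train > test > chance ordering.

## Pipeline and power

`run_full` chains simulate → decode → TFCE inference → cluster-restricted
TGMs with 2-D cluster tests → regressor z-scoring, collinearity report and
residualization → re-decode/re-inference/TGM of residuals → state-space
trajectories, and reports the naturalistic cluster window before vs. after
residualization. Stage outputs are cached in content-addressed npz files
(key = SHA-256 of the stage configuration), so cached and fresh runs are
bit-identical; reports contain no timestamps and serialize
deterministically. Desk-scale defaults (level-2 mesh, 8 subjects, 1000
permutations, decoding on a 25-ms grid) can be raised to study scale
(level-4 mesh, 10,000 permutations, full 5-ms grid) with `study_scale`.

`power_one_sample_t` evaluates the noncentral t distribution (df = n−1,
noncentrality d·√n) against the central-t critical value; tails are
configurable with a two-sided default (for n = 31 and d = 0.6 both tails
round to 0.9 at one decimal).

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scale, chosen as
the package's own desk-scale conventions: chance-level validation uses the
162-source level-2 mesh with 20 timepoints and 10 subjects; effect-recovery
and residualization studies use the 42-source level-1 mesh on 20–35 ms
decoding grids; type-I calibration uses 200 null datasets of exact binomial
chance accuracies (the sampling distribution of a chance classifier scored
on 40 epochs) at 40–100 cells with 500 permutations. Calibration at these
sizes certifies the inference machinery; it does not shortcut the decoding
stage, whose own null behavior is checked by the label-permutation study.

Known limitations: the two-unit network's decision boundary is nearly
linear, so simulations with linearly separable effects do not probe the
hidden layer's extra capacity; the searchlight trainer's fixed 200 Adam
steps are a throughput/fit compromise validated on the simulated SNR range
rather than an optimality claim; and the six-cap region partition is
geometric, not anatomical — region names are vocabulary, not claims about
cortex.
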