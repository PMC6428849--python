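# Methods

This note records the statistical model behind `seromir`, the conventions
chosen where the procedure admits more than one reading, and what the
synthetic study generator does and does not emulate.

## Array-level signal processing

Each array carries three probe classes: targets (one per miRNA),
negative controls (no complementary sequence; they measure non-specific
background), and three internal-control miRNAs (miR-149-3p, miR-2861,
miR-4463) whose serum levels are empirically stable and which anchor the
between-array scale.

**QC.** An array passes when the coefficient of variation of the raw
linear negative-control signals (sample SD / mean) is strictly below 0.15
and strictly fewer than 10 probes of any class are flagged.  Both
inequalities are strict — an array with exactly 10 flagged probes fails.
The CV is computed on untrimmed signals; trimming enters only the
detection/background statistics below.  Flags are scanner-assigned input
data; the generator assigns them at random and no uneven-hybridization
detector is implemented.

**Presence call and background.** The detection threshold is the trimmed
mean + 2 × trimmed sample SD of the negative-control signals, where
`floor(0.05 n)` signals are removed from each end after sorting.  The
floor rule keeps at least one value at any n and is conservative for small
control counts; the (n−1)-denominator SD is used throughout.  A target or
internal-control probe is present when its raw linear signal strictly
exceeds the threshold.  Present probes get `log2(signal − trimmed NC
mean)`; absent probes get the array floor, 0.1 log2 units below the lowest
present value.  "Lowest signal on the array" is read as the lowest
*present, background-corrected* value — the raw minimum would be a
negative-control artifact.

**Normalization.** Every log2 value on an array is shifted by
`log2(preset / linear mean of the three internal controls)`, where the
controls are averaged in linear space.  The preset is configurable and
defaults to 2^8 = 256, a value of no analytical consequence: the entire
chain is scale-equivariant, so multiplying every signal on an array by any
constant leaves the normalized output unchanged (this is a tested
invariant), and the preset only fixes the global origin of the log2 scale.
A probe floor or absence among the three controls aborts normalization for
that array.

## The selection funnel

Stages run on distinct cohorts, mirroring a chronologically split study:
abundance and univariate screens on *discovery*, trend and differential
screens plus the index search on *training*, and final evaluation on
*validation* only.

1. **Abundance** — keep probes with log2 value strictly > 6 in strictly
   more than 50% of malignant *or* of benign samples.  Normalized values
   are used (the alternative, pre-normalization signals, is not stated
   anywhere and normalized values make the cut scale-free).
2. **Univariate LOOCV score** — for each probe, leave each sample out,
   recompute both class means, and classify the held-out value by the
   midpoint-of-means rule (the one-dimensional Fisher discriminant; a
   boundary value calls malignant, consistent with the score ≥ 0 index
   rule).  The score is the hit fraction; probes with score strictly > 0.6
   survive.  Plain accuracy is used rather than a class-balanced measure.
   The choice of the univariate classifier is the key reproducibility
   caveat of the whole funnel: nothing pins it down externally, and the
   midpoint rule was chosen for consistency with the downstream index.
3. **Step-wise cluster screen** — probe profiles are agglomerated by
   average linkage on Euclidean distance (scipy) and the dendrogram cut
   into a fixed number of flat clusters (default 10, clipped to the probe
   count).  A cluster passes when its centroid's group means rise strictly
   healthy < benign < malignant; strictly decreasing clusters are reported
   separately but not selected.  "Step-by-step" is formalized as strict
   monotonicity of the cluster-centroid group means.
4. **Differential screen** — on a positive relative-expression matrix
   (the 2^−ΔCt scale of qRT-PCR), keep probes with two-sided
   pooled-variance Student t-test p < 0.05 *and* a higher malignant than
   benign mean.  Welch's test is available behind a flag.  Zero pooled
   variance yields p = 1 for equal means and p = 0 (logged) otherwise.
   In the synthetic pipeline this stage runs on a truth-derived
   re-measurement with independent noise for all training benign/malignant
   samples; restricting it to a small subset (as a wet-lab budget would)
   is possible by passing fewer samples but needlessly discards power.
   Internal-control probes are excluded from the funnel — they are
   abundant by construction and carry no class signal.

Each stage's output is a subset of its input, asserted on every run.

## Index construction and evaluation

The index is the two-class Fisher direction `S_pooled^-1 (mu_1 - mu_0)`
with the pooled (n−2 denominator) within-class covariance and the
equal-prior midpoint intercept; no renormalization of the coefficient
vector is applied, so coefficients are unique only up to the convention.
A singular pooled covariance falls back to a ridge `S + λI` with
`λ = 1e-6 · trace(S)/p` (logged); disabling the ridge turns this case into
an error.  Scores ≥ 0 call sarcoma, boundary inclusive.

Subsets of sizes 2–9 of the candidate panel are enumerated exhaustively
(guarded at 10^6 subsets) and scored by LOOCV accuracy; the per-fold refit
uses rank-one downdates of the class sums and scatter matrices and is
exactly equivalent to refitting from scratch (tested against a brute-force
oracle).  Ties break deterministically: higher LOOCV AUC of the held-out
scores, then lexicographic marker order, and across sizes the smaller
panel wins at equal accuracy.

Performance at the 0 threshold is summarized by sensitivity, specificity,
PPV, NPV and accuracy with Wilson score 95% intervals (Clopper-Pearson
behind a flag), and by the Mann-Whitney AUC (ties half credit) with a
DeLong interval.  These interval methods are conventions — nothing in the
procedure dictates them — and the report records which was used.  Odds
ratios for index positivity, univariate or age- and sex-adjusted, come
from logistic regression (statsmodels); non-convergence or any
|coefficient| > 20 is reported as a separation error rather than a number.

The per-group sample size for a two-sample design uses the normal
approximation `n = ceil(2 (z_{1−α/2} + z_{power})² (sd/effect)²)`, which
gives 72 at the design assumptions (effect 0.5 log2, SD 1, α 0.05, power
0.85); the t-quantile iteration (one unit more conservative, 73) is
available behind a flag.

## The synthetic study generator

The generator emulates the statistical structure the pipeline assumes —
not real miRNA biology.  Per probe, a baseline log2 mean is drawn once
from Uniform(6, 12), so the abundance cut has both passers and failers;
planted markers draw from Uniform(8, 11) so that a marker's detectability
is governed by its effect size rather than by an accidental collision with
the abundance floor.  Within a group, values are Normal(baseline + shift,
SD 1.0 by default, matching the design's representative SD); planted
markers add their benign shift in benign (and, by default, intermediate)
samples and their malignant shift in malignant samples.  Every probe on an
array is multiplied by a common 2^Normal(0, 0.2) scale factor — the
disturbance internal-control normalization exists to remove.  Negative
controls are lognormal around log2 = 4 with SD 0.1: low enough that
typical targets are called present, and tight enough that the linear CV
(≈ 0.07) lets arrays pass the CV < 0.15 QC rule, as real production arrays
overwhelmingly do.  Internal controls sit at log2 = 8 (the preset) with SD
0.1.  Ages are truncated-Normal(48, 20) on [1, 95] and sex is
Bernoulli(0.55 male); these only exercise the adjusted odds-ratio path.
Probes are flagged independently with probability 0.01.

Determinism: one seed sequence per study; probe baselines, each array, the
metadata stream and the qPCR re-measurement each use their own substream
keyed by the seed and an index, so regeneration is byte-identical and
independent of order.

What the generator does *not* emulate: real miRNA identities or sequence
chemistry, inter-probe correlation structure, batch effects beyond the
single array scale factor, heavy-tailed or zero-inflated serum
distributions, and cohort-level covariate shift.  Passing pipeline tests
therefore demonstrate that the chain of estimators recovers the structure
it assumes, with correctly calibrated nulls — not that the published
clinical performance transfers to any particular real cohort, which would
require the deposited expression data.

## Problem sizes and study conditions

The reference synthetic condition used by the acceptance checks plants
three step-wise markers at benign +0.5 (the design's minimum detectable
difference) and malignant +2.0 log2 units among 300 target probes, with
150 samples per group in each cohort — comparable to the per-cohort group
sizes of the motivating study and comfortably above the 72-per-group
design requirement.  Under these conditions the funnel recovers the
planted panel and validation sensitivity/specificity concentrate around
0.90/0.94.  Null calibration uses 1000 probes (differential screen), 100
label permutations of 200 samples (LOOCV score) and 1000 samples (AUC).

## Known limitations

- The published Index I–VIII coefficients imply a fitting convention
  (coefficient scale, intercept origin) that cannot be recovered from
  their printed form alone; refitting the discriminant on any cohort will
  therefore not numerically reproduce the catalog coefficients, and the
  catalog is shipped as data rather than re-derived.
- The univariate LOOCV classifier and the dendrogram cut rule are
  under-determined by the procedure's description; the midpoint rule and a
  fixed cluster count (default 10) are this package's choices.
- The intermediate tumor group is excluded from performance evaluation (it
  is neither a positive nor a negative class) and receives the benign
  shift by default, with a per-marker override for bimodal behaviour.
- The GEO series-matrix reader takes values as deposited and performs no
  re-normalization; it makes no attempt to reconstruct cohort assignments
  that are not encoded in the sample characteristics.
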