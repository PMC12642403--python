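# Methods

`speechtrf` implements an encoding-model analysis of continuous-speech
neural responses: linguistic prediction features are computed from the
speech stream, a linear convolutional response model is estimated per
"virtual source" by boosting, and model-comparison maps are tested at the
group level with permutation statistics.  Everything runs on synthetic
data with known ground truth, generated by the package itself.

## Context models and prediction features

Three context models assign each phoneme event a predictive distribution,
from which two (or three) features are derived:

* **Surprisal** `I(phone_k) = -log p(phone_k | context)`.
* **Phoneme entropy** `H = -sum_i p(i | context) log p(i | context)` over
  the phoneme inventory — the expected surprisal of the *next* phoneme,
  so the value attached to event `k` conditions on the context ending at
  `k`.
* **Cohort entropy** (lexical and sentence levels only): the same entropy
  taken over the distribution of candidate *words* consistent with the
  phonemes heard so far in the current word.

The **sublexical** model is a 5-gram phoneme model: the conditioning set
is the previous four phonemes heard, crossing word boundaries (an
utterance-initial pad symbol defines the first contexts; a config flag
restricts contexts to the current word instead).  The **lexical** model
is an incremental cohort: at word onset a frequency-proportional prior is
placed over the lexicon, and each phoneme zeroes out prefix-inconsistent
candidates and renormalizes; the probability of a phoneme is the total
candidate mass consistent with it.  The **sentence** model is the same
cohort with the prior replaced by word probabilities from a word-level
n-gram (order 5 by default; the toy analyses use a bigram because higher
orders memorize a few-hundred-word corpus).

Entropies are the standard nonnegative `-sum p log p`.  All features use
a single configurable log base (natural log by default; base 2 for
bit-valued examples): predictors are standardized before fitting, so the
base only rescales a track by a constant.

N-gram models use interpolated absolute discounting with a configurable
discount `d` (default 0.1 where smoothing matters, `d = 0` reduces
exactly to maximum-likelihood count ratios, which is what the count-
oracle tests exercise).  The base of the recursion is the uniform
distribution over the vocabulary.  Word models may include an explicit
`<unk>` type so out-of-vocabulary queries receive its smoothed
probability while per-context distributions still sum to one.  Models
round-trip through the ARPA format (log10 probabilities, linear backoff
weights written as log10).

If a phoneme eliminates the entire cohort (noisy alignments), the state
falls back to a uniform distribution over the inventory for the rest of
the word: surprisal and phoneme entropy take their uniform values, cohort
entropy is set to 0, and the event is flagged.

## Predictor tracks

Features are laid out as impulse tracks at the analysis rate: a unit
impulse at every word onset, a unit impulse at every phoneme onset that
is not a word onset (avoiding colinearity between the two), and
feature-scaled impulses at phoneme onsets for each surprisal/entropy
feature.  Events map to the nearest sample with ties toward the earlier
sample; colliding impulses are summed.  Acoustic controls come from an
8-band gammatone filterbank with log-spaced center frequencies between 10
and 5000 Hz (FIR kernels — the IIR realization is numerically unstable at
low center frequencies at audio rates): per band, the half-wave rectified
filter output is lowpassed and resampled to the analysis rate (envelope),
and its half-wave rectified first difference gives the onset track.

## mTRF estimation by boosting

The response at each source is modeled as the sum over predictors of the
predictor convolved with a kernel supported on lags [-100, 1000) ms.
Kernels live on a basis of 50 ms Hamming windows whose centers tile the
window at a one-sample stride (at the default 100 Hz: 110 elements per
predictor); negative lags give anticipatory samples.  Predictors and
responses are standardized by centering and dividing by the mean absolute
value; the quality index below is computed on the standardized response.

Fitting is steepest coordinate descent on the l1 training error: every
unfrozen (predictor, element) coordinate is probed with a fixed +/- step
(default 0.005 in units of the standardized response scale), the step
with the greatest training-error reduction is applied, and if it
increases l1 error on the validation segment it is reverted and that
predictor's whole kernel is frozen.  Training stops when all predictors
are frozen; if a full sweep offers no training-error reduction, the
remaining predictors are frozen at that sweep (at the first iteration
this yields a valid all-zero fit).  Ties resolve to the lowest predictor
index, then the earliest lag, then +step, making runs bit-deterministic.

Estimation uses fourfold cross-validation over contiguous equal segments
(any remainder joins the last segment).  For each test segment the three
rotations of (two training segments, one validation segment) are fit and
the three mTRFs averaged; training error is evaluated on the union of the
two training segments' samples (equivalent to the average for equal
lengths).  Convolutions are computed per segment with zero padding, so
segments never leak into each other.  Concatenated test-segment
predictions give the model quality index `q = 1 - l1(residuals)/l1(y)`
per source (1 for a perfect prediction, 0 for the null prediction).  The
**improvement** of a feature is `q(full) - q(reduced)` where the reduced
model omits that feature and shares the partition, basis and step.

The inner loop is compiled (numba) over column-sparse designs; a
cross-validated three-predictor fit of a 5-minute response at 100 Hz
takes tens of seconds per source on one CPU.

## Group statistics

Per-subject improvement maps live on an abstract source space: positions,
graph adjacency, hemisphere labels, and (when defined) a left-right
pairing.  The battery comprises:

* **Smoothing**: normalized Gaussian weights over source distances
  (default sigma = one inter-source spacing on synthetic grids; sigma = 0
  is the identity).
* **Mass-univariate one-sample test with TFCE**: per-source t over
  subjects, threshold-free cluster enhancement
  `sum_h extent(h)^E * h^H * dh` with E = 0.5, H = 2, dh = 0.1 (negative
  values enhanced symmetrically on the negated map), and a sign-flip
  max-statistic null: exhaustive when the 2^n flips fit in the requested
  permutation count (and 4096), otherwise seeded random flips.  Reported
  are family-wise p per source and the t/p at the strongest enhanced
  source.  Zero-variance sources are guarded by capping |t| at 100, and
  TFCE coarsens dh for maps that would need more than 5000 thresholds, so
  degenerate inputs stay finite and fast.
* **Hemispheric comparison**: right-hemisphere values are mapped onto
  their paired left sources, per-subject left-minus-right differences run
  through the same one-sample machinery; the **lateralization index**
  `LI = R/(L+R)` summarizes per-subject hemisphere strengths (0.5 =
  symmetric; negative strengths are clipped at 0, where the index is
  otherwise undefined, and L+R = 0 yields a missing value).
* **ROI tests**: per-subject spatial means over an ROI mask, one-sample
  t per group (df = n-1, two-sided).
* **Language regression**: OLS of the per-subject ROI scalar on native
  language, dummy coded with English (or the first level) as baseline;
  pairwise independent two-sample t-tests between language pairs follow
  up significant regressions.
* **Spatiotemporal cluster test** on kernels: pointwise two-sample t over
  a (source, lag) grid, clusters as connected components above the
  two-sided cluster-forming threshold (alpha = 0.05), cluster-mass
  statistic, label-permutation max-mass null; clusters report their time
  span and spatial extent as % of ROI sources.
* **Peak analysis**: local extrema of spatially averaged kernels above a
  prominence floor (10 % of max |kernel|), matched across subjects by
  ordinal position within sign, with independent t-tests on peak size and
  latency between groups.

Permutation p-values use `(1 + #exceedances)/(1 + B)` for random draws
(exactly valid under exchangeability) and plain exceedance proportions
for exhaustive enumerations.  Calibration tests in the suite use a few
hundred random permutations rather than the production default of
10 000 — validity is unaffected, only resolution — to keep the
Monte-Carlo budget modest.

## Synthetic data

The generator emulates every input at desk scale:

* **Lexicon**: random transcriptions of length 2–6 over a 10-phoneme
  inventory (40 words by default), Zipf-distributed frequencies
  (exponent 1), with a guaranteed shared-prefix pair so cohorts are
  nontrivial.
* **Corpus and events**: word sequences from a Dirichlet-random bigram
  grammar; gamma-distributed phoneme durations (mean 80 ms, sd 20 ms)
  laid out as a strictly increasing event table — the statistics of
  casual speech at the granularity the model cares about.
* **Ground truth**: kernels are sums of basis bumps at stated latencies
  (defaults: an early positive and a late negative peak per predictor,
  mimicking typical auditory response morphology) with 10 % per-source
  amplitude jitter — by construction in the span of the fitting basis.
* **Responses**: standardized tracks convolved with the true kernels plus
  1/f colored noise band-limited to 1–10 Hz, scaled per source to a
  target SNR (variance ratio; default 1).
* **Group studies**: all subjects share the stimulus (as with a fixed
  audiobook); each subject gets independent noise, and each group's
  kernels are scaled by per-hemisphere effect multipliers, which is how
  lateralized or between-group effects are injected.  A separate
  map-level generator draws per-subject improvement maps directly for
  statistics-layer simulations (calibration and LI recovery), where
  running thousands of boosting fits would add nothing but time.

What the generator does **not** emulate: real phonotactics and lexical
statistics (the toy grammar has no syntax or morphology), acoustics
beyond band envelopes, sensor-space MEG, head geometry, source leakage
and correlated noise between sources, or forced-alignment errors (beyond
the cohort fallback path).  Passing tests therefore demonstrate that the
estimator and statistics behave correctly under the generative model they
assume — not that the assumptions hold for any particular real dataset.

## Problem sizes and numerical choices

Default study conditions are 5-minute recordings at 100 Hz, 10 sources
per hemisphere, and three groups of 12 subjects.  The test suite runs the
noiseless kernel-recovery check at the full stated scale (3 predictors,
5 min at 100 Hz, 4 sources) and scales the many-seed simulations down
(improvement validity: 1 source, ~40 s at 50 Hz, 20 seeds; end-to-end
study: 3 x 5 subjects, 1 source per hemisphere, ~40 s) — sizes chosen as
the smallest at which the effects of interest are far from threshold.
The sham-ordering check runs on a noiseless response, where the freezing
mechanism (and not the terminal race between overfitting predictors)
determines the order.

Numerical tie-breaks and guards are noted inline above; beyond those, the
package has no hidden tolerances: information measures are exact up to
floating point, and all stochastic components consume explicit seeds.
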