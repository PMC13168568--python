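# Methods

## The model

`speechtrf` implements a linear forward (encoding) model of continuous
speech: the neural response at source *j* is a sum of feature time series
convolved with temporal response functions (TRFs),

    y_j(t) = sum_f sum_k beta_jf(tau_k) * x_f(t - tau_k) + noise,

with lags tau_k spanning [-50, 700) ms in 10 ms steps at the 100 Hz analysis
rate. The half-open lag window is the only convention consistent with T = 75
lag points; each lag carries a 50 ms Hamming basis window (sum-normalized,
centered on the lag by default), so the TRF evaluated in lag time is the
coefficient vector convolved with that window (`TRFModel.time_kernel`).

Feature families:

* **gammatone** — an 8-band auditory spectrogram. Center frequencies are
  equally spaced on the Glasberg–Moore ERB-number scale
  (ERB(f) = 21.4·log10(1 + 0.00437 f)) between 20 and 5000 Hz, endpoints
  included. Each band is a 4th-order gammatone filter; the envelope is
  half-wave rectification followed by a 4th-order Butterworth low-pass at
  40 Hz and polyphase resampling to 100 Hz. Amplitudes are linear (no power
  or log compression). Low bands are filtered in second-order sections at a
  per-band decimated rate (fs/2^k down to ~16·fc, minimum 1 kHz): the
  8th-order direct-form discrete gammatone is unstable or loses several
  percent to coefficient cancellation when fc/fs is very small. Frame
  timestamps are left edges.
* **acoustic edges** — the half-wave rectified first difference of each
  envelope band, scaled by the frame rate, first frame zero. A constant
  envelope yields zeros; offsets are rejected by the rectification. (A
  multi-delay neural edge-detection variant could be slotted behind the same
  interface; the rectified derivative is the definition implemented.)
* **phoneme features** — impulse channels at phoneme onsets
  (frame = floor(onset·rate); simultaneous events sum): a constant onset
  indicator, cohort surprisal, and cohort entropy.
* **word features** — impulse channels at word onsets with externally
  supplied word-level surprisal/entropy values (computed by a language
  model upstream; this package consumes them as a table).

## Cohort statistics

Word recognition is modeled incrementally: the cohort after a phoneme
prefix is the set of lexicon entries beginning with that prefix, weighted by
word occurrence frequency. For phoneme *i*,

* conditional probability P_i = mass(cohort_i) / mass(cohort_{i-1}),
* surprisal S_i = -log2 P_i (bits),
* entropy E_i = Shannon entropy (bits) of the frequency-weighted
  distribution over next phonemes given the current cohort (by default the
  cohort *after* phoneme i, i.e. uncertainty about phoneme i+1; conditioning
  on the previous cohort is a switch).

Probabilities are exact integer-mass ratios (`fractions.Fraction`); logs are
taken last. When a cohort member's sequence equals the prefix, a terminal
"word ends here" outcome enters the entropy distribution (otherwise the
next-phoneme distribution would be improper when words are prefixes of
longer words); this can be switched off.

Lexicons are loaded from TSV, forms with non-alphabetic characters removed
(Unicode letter classification, so Turkish dotted/dotless i and Chinese
characters survive), duplicate (form, pronunciation) records merged by
summing frequency, non-positive frequencies rejected with a warning count.

**Empty-cohort fallback.** Pseudoword streams guarantee prefixes that leave
the cohort empty. Two policies exist: `uniform` (probability 1/|inventory|,
entropy log2|inventory|, cohort stays empty; the module default) and
`restart` (re-enter the full lexicon as if word-initial and consume the
phoneme from there). Every fallback event is flagged and counted. The
synthetic experiments annotate with `restart`: the uniform policy collapses
pseudoword surprisal to a constant — degenerate after z-scoring and at odds
with listeners who treat each syllable of a nonword stream as a potential
word onset.

## Estimation

Predictors and responses are z-scored per channel/source (statistics over
unpadded samples only, recorded for inverse transforms), then every trial is
zero padded from 50 ms before onset to 700 ms after offset; regressors never
mix samples across trial boundaries.

TRFs are estimated by coordinate-wise boosting: starting from zero kernels,
the single (channel, lag) coefficient whose ±step change (step 0.005 in
normalized units) maximally reduces the training l2 error is adjusted;
training stops when the validation error has not reached a new minimum for
`patience` = 10 consecutive validation checks (one check per `check_every` =
20 iterations; a per-iteration patience would abort on the ordinary zigzag
of small coordinate steps), or when no step reduces the training error, or
at `max_iter` = 10,000. The returned kernel is the one at minimum validation
error. Cross-validation is fivefold over contiguous trial blocks (no sample
shuffling, to avoid autocorrelation leakage); within each fold the next
block (cyclically) is the validation set and the rest train. Coordinate ties
resolve to the lowest (channel, lag) index and a positive step is preferred
on an exact sign tie, so fits are bit-reproducible.

The iteration is driven by Gram matrices (X'X summed per fold block), making
each coordinate update O(p) instead of O(np); this is algebraically
identical to recomputing residuals against the raw design and is verified
against a naive reference implementation in the tests.

Accuracy is the proportion of variance explained, 1 - SS_res/SS_tot, on
held-out samples with padding excluded (it may be negative). A feature
family's contribution is measured by ablation: the accuracy of the full
model minus that of a model refit without the family's channels (same
folds, same hyperparameters).

## Group statistics

* One-sample two-sided t-tests of source-averaged accuracy improvements
  against zero.
* Paired cluster-based permutation tests across lag time on TRF weight time
  courses (per subject: |kernel| averaged over sources and family channels;
  "response units" by default, i.e. rescaled by the recorded response sd so
  amplitudes are comparable across separately z-scored conditions). The
  cluster-forming threshold is the two-sided paired-t critical value at
  0.05; cluster mass is the sum of t inside a run; the null is the maximum
  cluster |mass| over random sign flips of the subject differences (30,000
  permutations by default); p-values use the add-one convention and count
  float-level ties so the identity permutation is always in the null. The
  first and last 20 ms of the lag axis are excluded from all statistics.
* Peak latencies: argmax within early (-50..100 ms), mid (100..350 ms) and
  late (350..700 ms) windows, mask respected, ties to the earliest lag.
* Mixed-effects models and aligned-rank ANOVAs are not reimplemented; the
  pipeline exports tidy per-(subject, source, family) tables for external
  statistical software.

## Synthetic experiments

The generator produces everything needed to validate the pipeline with
known ground truth.

**Lexicon and streams.** A toy lexicon of 20 bi-syllabic CV-CV words over
10 consonants × 5 vowels with Zipf frequencies (round(1000/rank)). Streams
are isochronous: 16 syllables of 250 ms (4 s sequences; a 200 ms variant
exists), 5% cosine ramps, peak level −15 dBFS, 8 sequences per condition by
default. Syllable tokens are deterministic per identity: a consonant portion
(band-passed noise; a decaying burst for stops) followed by a harmonic vowel
(f0 120 Hz, two formant resonances). The consonant–vowel transition time
depends on the consonant (stops release early, fricatives late), so phoneme
onsets are not strictly periodic — as in aligned natural syllables.
Conditions: `words` (sampled from the 10 highest-frequency words),
`random_syllables` (the same syllable multiset per sequence, shuffled;
consecutive pairs form pseudo-words), `sentences` (4-word class templates)
and `word_list` (template order broken).

**Ground truth.** Per-family kernels are gamma-density bumps: acoustic
families peak near 80–100 ms, phoneme (and word) features near 400–450 ms,
all zero at negative lags. The kernels act on the **standardized** features:
neural gain adapts to the stimulus distribution, so condition effects are
exactly the injected multiplicative modulation factors rather than
by-products of raw feature scales (pseudoword cohort features are
intrinsically larger — they are genuinely more surprising — which would
otherwise dominate the contrast). Each family's kernel is scaled once, on
the first condition, so its summed drive has sd proportions
gammatone : edges : phoneme : word = 0.4 : 0.7 : 1.0 : 0.5, and the same
scaled kernel serves every condition. Predictors are padded first and the
response is simulated on the padded grid: the response to late-trial
stimuli rings into the post-offset padding, which is precisely the edge
artifact the padding absorbs (truncating it instead biases every recovered
amplitude down by ~half).

Per subject, family gains are jittered (sd 0.1) and per-source gains drawn
from U(0.7, 1.3) — once per subject, condition-independent, as subject
traits, so paired contrasts isolate condition effects. White Gaussian noise
is added per source with var(signal)/var(noise) = SNR (default 0.5); a 1/f
option exists behind a flag but recovery targets are defined under white
noise. All randomness derives from a single seed.

**Presets** (`make_experiment`): `words_vs_syllables` injects a ×1.5
phoneme-kernel amplitude in words; `familiarity` presents identical word
streams as "native" vs "unfamiliar" with a ×1.3 acoustic-edge amplitude in
the unfamiliar condition (the edge kernel is confined to early lags by
construction, so this is an early effect); `sentences_vs_wordlist` injects
×1.4 on phonemes in sentences and includes word-level features; `null` has
no condition effects. Defaults: 15 subjects, 2 sources, 8 sequences per
condition. Manifests echo the full configuration and seeds.

## Identifiability, and how recovery is measured

With isochronous streams and one fixed token per syllable identity, the
phoneme features are a function of syllable identity and hence linearly
decodable from the acoustic channels; in addition, 75-lag designs on
250 ms-periodic stimuli alias at ±250 ms. Full-model attribution of
variance between feature families is therefore **not identifiable** in
these stimuli — exact least squares on the full design flips the sign of
the phoneme-kernel projection from stimulus set to stimulus set. (The same
ambiguity is latent in real experiments of this design; there it is
resolved statistically across richer material.) Consequences for validation
on synthetic data:

* **Ablation improvements** remain well-defined (they measure unique
  predictive contribution) and are the robust accuracy-level readout:
  phoneme ablation is strongly positive when phoneme kernels are generative
  and collapses to the overfitting noise floor (|mean| ≤ 0.01) when they are
  zeroed.
* **Amplitude recovery** (`pipeline.family_amplitude`) subtracts the other
  families' known generative contributions from each response (ground-truth
  residualization) and reads the family kernel out with exact least squares
  on the family-only design. Least squares rather than the boosted fit:
  early stopping shrinks amplitudes differentially with condition SNR,
  biasing cross-condition ratios (measured 1.19 boosted vs 1.47 for an
  injected 1.5). The amplitude is the projection of the summed family
  kernels (response units) onto the true kernel shape, both centered across
  lags so the DC offset that absorbs the feature means drops out. Measured
  recovery: words/syllables phoneme ratio 1.47 ± 0.05 over 10 seeds
  (injected 1.5); familiarity edge ratio 1.31 (injected 1.3).
* **Cluster tests on weights** for the synthetic condition contrasts use
  boosted family-only models on the same residualized responses
  (`pipeline.residualized_family_models`): the package's own estimator on an
  identifiable problem. Both injected contrasts are then detected reliably
  (significant positive clusters in 10/10 and 5/5 seeds).

## What passing tests do and do not show

The generator emulates the stimulus *timing and feature structure* of
isochronous syllable-stream experiments and a linear source-level response.
It does not emulate: MEG sensor physics or source leakage, 1/f neural
noise (by default), token-to-token acoustic variability, coarticulation
across syllable boundaries, or any nonlinearity of real neural responses.
Passing recovery tests show the pipeline's estimator and statistics are
correct and calibrated for the model class they assume — not that real
cortical responses follow that model. Two specific cautions:

* The accuracy-improvement *contrast* between words and random syllables
  comes out syllables > words under this generative model (restart-fallback
  pseudoword features carry more unique variance than the nearly degenerate
  10-word-pool word features), opposite to the empirical direction reported
  for real listeners. The injected words > syllables effect is recovered
  where it is identifiable: in the weight time courses and the amplitude
  ratio.
* Weight-based contrasts on the *full* collinear model are unstable across
  stimulus realizations for the reasons above; the residualized readouts
  are the validated route on synthetic data.

## Numerical choices and problem sizes

Exact integer arithmetic for cohort masses; float64 throughout the
estimator; the Gram update is exact, not approximate. Cluster p-values
count ties to within 1e-9 relative tolerance. Degenerate inputs fail fast:
zero-variance channels, empty lexicons after filtering, events off the
grid, non-finite responses, fewer trial blocks than folds.

Test and acceptance runs use desk-scale sizes chosen as the package's
default study conditions: 15 subjects, 2 sources, 8 four-second sequences
per condition, SNR 0.5; estimator checks use 6 trials of 5 s white-noise
channels; calibration uses 200 null datasets at 1000 permutations and 50
injected-effect datasets. The headline 30,000-permutation default is used
for single reported contrasts; Monte-Carlo sweeps use 1000–2000
permutations per dataset.
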