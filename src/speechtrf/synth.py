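"""Synthetic experiments with known ground truth.

Everything needed to exercise the pipeline without external downloads:

* toy CV-CV lexicons with Zipf-distributed frequencies;
* isochronous syllable streams in four conditions (words, random syllables,
  sentences, word lists): 16 syllables of 250 ms per 4 s sequence by default
  (a 200 ms variant exists), 5% cosine ramps, level normalized to -15 dBFS;
* ground-truth TRFs per feature family (gamma-density bumps peaking near
  100 ms for acoustic features and 400 ms for phoneme features) with
  condition-dependent multiplicative amplitude effects;
* simulated multi-subject source responses through the forward model
  y = sum_f (beta_f,condition * x_f) + Gaussian noise, with per-subject
  amplitude jitter and per-source gains, all driven by a single seed.

Syllable acoustics are harmonic vowel complexes with consonant-dependent
onsets (noise bursts for stops) — enough to give the gammatone/edge features
realistic structure, deliberately not a speech synthesizer.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .features import gammatone_spectrogram, onset_spectrogram
from .lexicon import (Lexicon, annotate_events, make_lexicon, PHONEME_TIER,
                      WORD_TIER)
from .predictors import (LagDesign, PredictorSet, SourceResponse,
                         build_predictor_set, events_to_impulses, lag_axis_ms,
                         lag_expand, normalize, normalize_response, pad_trials)

__all__ = [
    "StimulusSpec", "Stream", "GroundTruth", "Experiment", "ConditionData",
    "CONSONANTS", "VOWELS", "PRESETS", "make_toy_lexicon", "syllable_token",
    "make_streams", "gamma_kernel", "default_truth", "scale_truth_kernels",
    "simulate_responses", "build_condition_predictors", "make_experiment",
    "FAMILY_DRIVE_SD", "vowel_onset_fraction",
]

CONSONANTS = ("p", "t", "k", "b", "d", "g", "m", "n", "s", "l")
VOWELS = ("a", "e", "i", "o", "u")
_STOPS = frozenset("ptkbdg")

#: Vowel resonances (F1, F2) in Hz for the harmonic tokens.
_FORMANTS = {"a": (700, 1220), "e": (460, 1900), "i": (300, 2300),
             "o": (450, 900), "u": (320, 800)}

#: Fraction of the syllable occupied by the consonant before the vowel
#: starts. Stops release quickly; fricatives, nasals and liquids are longer.
#: Consonant-dependent transition times keep phoneme onsets from being
#: strictly periodic in isochronous streams, as in aligned natural syllables.
_VOWEL_ONSET_FRACTION = {"p": 0.24, "t": 0.28, "k": 0.32, "b": 0.22,
                         "d": 0.26, "g": 0.30, "m": 0.44, "n": 0.40,
                         "s": 0.50, "l": 0.36}


def vowel_onset_fraction(consonant: str) -> float:
    return _VOWEL_ONSET_FRACTION.get(consonant, 0.4)


@dataclass
class StimulusSpec:
    """Stimulus construction parameters for one condition."""
    condition: str = "words"
    syllable_ms: float = 250.0
    n_syllables: int = 16
    n_sequences: int = 8
    ramp_fraction: float = 0.05
    level_dbfs: float = -15.0
    sample_rate: int = 16000
    seed: int = 0

    @property
    def sequence_s(self) -> float:
        return self.n_syllables * self.syllable_ms / 1000.0


@dataclass
class Stream:
    """One synthesized sequence: audio plus its phoneme/word event table."""
    audio: np.ndarray
    fs: int
    events: pd.DataFrame
    syllables: list[str]
    words: list[str]


def make_toy_lexicon(n_words: int = 20, n_consonants: int = 10,
                     n_vowels: int = 5, seed: int = 0) -> Lexicon:
    """Bi-syllabic CV-CV lexicon with Zipf-distributed integer frequencies.

    Words are distinct pairs of CV syllables drawn from an inventory of
    ``n_consonants * n_vowels`` syllables; frequency of the rank-r word is
    round(1000 / r). Deterministic under ``seed``.
    """
    if n_consonants < 1 or n_vowels < 1 or n_consonants * n_vowels < 4:
        raise ValueError("syllable inventory too small (need >= 4)")
    syllables = [c + v for c in CONSONANTS[:n_consonants]
                 for v in VOWELS[:n_vowels]]
    capacity = len(syllables) ** 2
    if n_words > capacity:
        raise ValueError(
            f"{n_words} words exceed the {capacity}-pair combinatorial capacity")
    rng = np.random.default_rng(seed)
    picks = rng.choice(capacity, size=n_words, replace=False)
    entries = []
    for rank, p in enumerate(picks, start=1):
        s1, s2 = syllables[p // len(syllables)], syllables[p % len(syllables)]
        phonemes = (s1[0], s1[1], s2[0], s2[1])
        entries.append((s1 + s2, phonemes, max(1, round(1000 / rank))))
    return make_lexicon(entries)


def _token_rng(syllable: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(syllable.encode()) & 0x7FFFFFFF)


def syllable_token(syllable: str, dur_s: float, fs: int,
                   ramp_fraction: float = 0.05,
                   level_dbfs: float = -15.0) -> np.ndarray:
    """Deterministic band-limited token for one CV syllable.

    Consonant portion (first 40% of the syllable): band-passed noise burst for
    stops, sustained band-passed noise otherwise, center frequency set by the
    consonant. Vowel portion: harmonic complex (f0 = 120 Hz) shaped by two
    formant resonances. Cosine ramps on ``ramp_fraction`` of both ends; peak
    level normalized to ``level_dbfs``.
    """
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    c, v = syllable[0], syllable[1]
    out = np.zeros(n)

    # vowel: harmonic complex with formant envelope
    f0 = 120.0
    f1, f2 = _FORMANTS.get(v, (500, 1500))
    v_start = int(vowel_onset_fraction(c) * n)
    rng = _token_rng(syllable)
    h = 1
    while h * f0 < 4500:
        f = h * f0
        amp = (np.exp(-0.5 * ((f - f1) / 180) ** 2)
               + 0.7 * np.exp(-0.5 * ((f - f2) / 250) ** 2) + 0.03)
        out[v_start:] += amp * np.sin(2 * np.pi * f * t[v_start:]
                                      + rng.uniform(0, 2 * np.pi))
        h += 1
    # short vowel onset ramp so the consonant-vowel join is not a click
    join = min(int(0.01 * fs), n - v_start)
    out[v_start:v_start + join] *= np.linspace(0, 1, join)

    # consonant: noise burst (stops) or sustained noise
    ci = CONSONANTS.index(c) if c in CONSONANTS else 0
    center = 400 + 450 * ci
    lo, hi = max(80.0, center - 250), min(fs / 2 - 100, center + 250)
    noise = rng.standard_normal(v_start)
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    cons = signal.sosfilt(sos, noise)
    if c in _STOPS:
        burst = int(0.03 * fs)
        cons[burst:] *= np.exp(-np.arange(len(cons) - burst) / (0.01 * fs))
    out[:v_start] += 0.8 * cons / (np.max(np.abs(cons)) + 1e-12)

    ramp = max(1, int(ramp_fraction * n))
    win = np.ones(n)
    phase = np.linspace(0, np.pi / 2, ramp)
    win[:ramp] = np.sin(phase) ** 2
    win[-ramp:] = np.cos(phase) ** 2
    out *= win
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 10 ** (level_dbfs / 20) / peak
    return out


def _word_sequences(spec: StimulusSpec, lexicon: Lexicon,
                    word_pool_size: int) -> list[list[int]]:
    """Per-sequence word choices (entry indices), shared across the words /
    random-syllables pair so the shuffled streams are true permutations."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    order = np.argsort([-e.frequency for e in lexicon.entries], kind="stable")
    pool = list(order[:min(word_pool_size, len(lexicon.entries))])
    n_words = spec.n_syllables // 2
    return [list(rng.choice(pool, size=n_words, replace=True))
            for _ in range(spec.n_sequences)]


def _entry_syllables(lexicon: Lexicon, idx: int) -> list[str]:
    p = lexicon.entries[idx].phonemes
    return [p[0] + p[1], p[2] + p[3]]


def make_streams(spec: StimulusSpec, lexicon: Lexicon,
                 word_pool_size: int = 10,
                 sentence_len: int = 4) -> list[Stream]:
    """Synthesize the isochronous streams of one condition.

    words — words sampled from the high-frequency pool, concatenated;
    random_syllables — the same syllable multiset per sequence, shuffled
    (consecutive syllable pairs form pseudo-words for cohort annotation);
    sentences — words arranged into fixed-length templates (word classes
    assigned round-robin over the pool);
    word_list — the sentences' words with the template order broken.
    """
    if spec.condition not in ("words", "random_syllables", "sentences",
                              "word_list"):
        raise ValueError(f"unknown condition {spec.condition!r}")
    dur = spec.syllable_ms / 1000.0
    word_seqs = _word_sequences(spec, lexicon, word_pool_size)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 29]))
    streams = []
    for seq_words in word_seqs:
        if spec.condition in ("sentences", "word_list"):
            order = np.argsort([-e.frequency for e in lexicon.entries],
                               kind="stable")
            pool = list(order[:min(word_pool_size, len(lexicon.entries))])
            classes = [pool[i::sentence_len] for i in range(sentence_len)]
            n_sent = len(seq_words) // sentence_len
            seq_words = [int(rng.choice(classes[k % sentence_len]))
                         for _ in range(n_sent) for k in range(sentence_len)]
            if spec.condition == "word_list":
                perm = rng.permutation(len(seq_words))
                seq_words = [seq_words[i] for i in perm]
        syllables = [s for w in seq_words for s in _entry_syllables(lexicon, w)]
        words = [lexicon.entries[w].form for w in seq_words]
        if spec.condition == "random_syllables":
            perm = rng.permutation(len(syllables))
            syllables = [syllables[i] for i in perm]
            words = [syllables[i] + syllables[i + 1]
                     for i in range(0, len(syllables), 2)]
        audio = np.concatenate([
            syllable_token(s, dur, spec.sample_rate, spec.ramp_fraction,
                           spec.level_dbfs) for s in syllables])
        rows = []
        for i, syl in enumerate(syllables):
            t0 = i * dur
            wi = i // 2
            if i % 2 == 0:
                rows.append((t0, WORD_TIER, words[wi], wi))
            rows.append((t0, PHONEME_TIER, syl[0], wi))
            rows.append((t0 + vowel_onset_fraction(syl[0]) * dur,
                         PHONEME_TIER, syl[1], wi))
        events = pd.DataFrame(rows, columns=["onset_s", "tier", "label",
                                             "word_index"])
        streams.append(Stream(audio, spec.sample_rate, events, syllables,
                              words))
    return streams


# ---------------------------------------------------------------------------
# ground truth and response simulation
# ---------------------------------------------------------------------------

def gamma_kernel(lags_ms: np.ndarray, peak_ms: float, amplitude: float,
                 shape: float = 3.0) -> np.ndarray:
    """Gamma-density bump on the lag axis, maximum equal to ``amplitude``,
    zero at negative lags."""
    lags = np.asarray(lags_ms, dtype=float)
    scale = peak_ms / (shape - 1)
    x = np.where(lags > 0, lags / scale, 0.0)
    k = np.where(lags > 0, x ** (shape - 1) * np.exp(-x), 0.0)
    m = k.max()
    return amplitude * k / m if m > 0 else k


@dataclass
class GroundTruth:
    """Generative TRFs and effect structure for a simulated experiment."""
    kernels: dict[str, np.ndarray]   # family group -> kernel on lags_ms
    lags_ms: np.ndarray
    #: condition -> family -> (factor, lag window in ms or None for all lags)
    modulation: dict[str, dict[str, tuple[float, tuple | None]]]
    snr: float = 0.5
    subject_jitter_sd: float = 0.1
    n_subjects: int = 15
    n_sources: int = 2
    seed: int = 0

    def condition_kernel(self, family: str, condition: str) -> np.ndarray:
        k = self.kernels[family].copy()
        factor, window = self.modulation.get(condition, {}).get(
            family, (1.0, None))
        if window is None:
            k *= factor
        else:
            sel = (self.lags_ms >= window[0]) & (self.lags_ms <= window[1])
            k[sel] *= factor
        return k


#: Target standard deviation of each family's summed drive, relative to the
#: phoneme family (the dominant late component); the acoustic-edge family
#: carries most of the early acoustic response, the gammatone envelope a
#: weaker sustained one.
FAMILY_DRIVE_SD = {"gammatone": 0.4, "acoustic_edges": 0.7, "phoneme": 1.0,
                   "word": 0.5}


def default_truth(modulation: dict, lags_ms: np.ndarray | None = None,
                  include_word: bool = False, snr: float = 0.5,
                  subject_jitter_sd: float = 0.1, n_subjects: int = 15,
                  n_sources: int = 2, seed: int = 0) -> GroundTruth:
    """Gamma-bump kernels per feature family: acoustic families peak near
    80-100 ms, phoneme (and word) features near 400 ms.

    Kernels are returned with unit peak amplitude; :func:`scale_truth_kernels`
    (called by :func:`make_experiment`) rescales each family so its summed
    drive reaches the FAMILY_DRIVE_SD proportions on a reference stimulus set.
    """
    if lags_ms is None:
        lags_ms = lag_axis_ms()
    kernels = {
        "gammatone": gamma_kernel(lags_ms, 80.0, 1.0),
        "acoustic_edges": gamma_kernel(lags_ms, 100.0, 1.0),
        "phoneme": gamma_kernel(lags_ms, 400.0, 1.0, shape=4.0),
    }
    if include_word:
        kernels["word"] = gamma_kernel(lags_ms, 450.0, 1.0, shape=4.0)
    return GroundTruth(kernels, np.asarray(lags_ms, float), modulation,
                       snr=snr, subject_jitter_sd=subject_jitter_sd,
                       n_subjects=n_subjects, n_sources=n_sources, seed=seed)


def scale_truth_kernels(truth: GroundTruth, reference: PredictorSet) -> None:
    """Rescale each family kernel (in place) so the family's summed drive on
    the reference predictors has the FAMILY_DRIVE_SD standard deviation.

    The same scaled kernel is then used for every condition, so condition
    effects remain exactly the modulation factors."""
    lag0 = int(round(truth.lags_ms[0] * reference.rate / 1000))
    for fam, kern in truth.kernels.items():
        drive = np.zeros(reference.n_samples)
        for c in reference.channel_indices(fam):
            drive += _trial_convolve(reference.data[c], kern,
                                     reference.trials, lag0)
        sd = float(np.std(drive[reference.valid_mask]))
        if sd > 0:
            truth.kernels[fam] = kern * (FAMILY_DRIVE_SD[fam] / sd)


def _trial_convolve(x: np.ndarray, kernel: np.ndarray,
                    trials: list[tuple[int, int]],
                    lag0_samples: int) -> np.ndarray:
    """Per-trial y(t) = sum_k kernel[k] x(t - (k + lag0)), zero outside."""
    out = np.zeros_like(x, dtype=float)
    for (a, b) in trials:
        full = np.convolve(x[a:b], kernel, mode="full")
        n = b - a
        idx = np.arange(n) - lag0_samples
        valid = (idx >= 0) & (idx < len(full))
        out[a:b][valid] = full[idx[valid]]
    return out


def simulate_responses(pset: PredictorSet, truth: GroundTruth, condition: str,
                       rng: np.random.Generator | None = None,
                       return_details: bool = False):
    """Simulate per-subject, per-source responses from normalized predictors.

    y = sum_f jitter_sf * gain_src * (beta_f,condition * x_f) + noise, with
    noise sd set per source so that var(signal)/var(noise) = truth.snr
    (noiseless when snr is None or 0). All randomness comes from truth.seed
    unless an explicit generator is passed.
    """
    for fam in truth.kernels:
        if pset.channel_indices(fam).size == 0:
            raise ValueError(f"truth family {fam!r} not in predictors")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [truth.seed, zlib.crc32(condition.encode()) & 0x7FFFFFFF]))
    lag0 = int(round(truth.lags_ms[0] * pset.rate / 1000))
    contribs = {}
    for fam in truth.kernels:
        kern = truth.condition_kernel(fam, condition)
        idx = pset.channel_indices(fam)
        sig = np.zeros(pset.n_samples)
        for c in idx:
            sig += _trial_convolve(pset.data[c], kern, pset.trials, lag0)
        contribs[fam] = sig
    responses = []
    factors = []
    fams = sorted(contribs)
    for subj in range(truth.n_subjects):
        # subject traits (amplitude jitter, source gains) are drawn from a
        # condition-independent stream: the same subject keeps the same gains
        # across paired conditions
        srng = np.random.default_rng(np.random.SeedSequence(
            [truth.seed, 7, subj]))
        jitter = {f: max(0.1, 1.0 + srng.normal(0, truth.subject_jitter_sd))
                  for f in fams}
        gains = srng.uniform(0.7, 1.3, truth.n_sources)
        data = np.zeros((truth.n_sources, pset.n_samples))
        for s in range(truth.n_sources):
            sig = gains[s] * sum(jitter[f] * contribs[f] for f in fams)
            data[s] = sig
            if truth.snr:
                sd = float(np.std(sig[pset.valid_mask])) / np.sqrt(truth.snr)
                data[s] = sig + rng.normal(0, sd, pset.n_samples)
        responses.append(SourceResponse(data, pset.rate, list(pset.trials),
                                        subject=f"S{subj:02d}",
                                        valid_mask=pset.valid_mask.copy()))
        factors.append({"jitter": jitter, "gains": gains})
    if return_details:
        return responses, {"contribs": contribs, "factors": factors}
    return responses


# ---------------------------------------------------------------------------
# full experiment bundles
# ---------------------------------------------------------------------------

PRESETS = {
    "words_vs_syllables": {
        "conditions": {"words": "words", "random_syllables": "random_syllables"},
        "modulation": {"words": {"phoneme": (1.5, None)}},
        "include_word": False,
    },
    "sentences_vs_wordlist": {
        "conditions": {"sentences": "sentences", "word_list": "word_list"},
        "modulation": {"sentences": {"phoneme": (1.4, None)}},
        "include_word": True,
    },
    "familiarity": {
        # same stimulus statistics; the "unfamiliar" language shows enhanced
        # early acoustic-edge encoding (the edge kernel is confined to early
        # lags by construction, so the family factor is an early effect)
        "conditions": {"native": "words", "unfamiliar": "words"},
        "modulation": {"unfamiliar": {"acoustic_edges": (1.3, None)}},
        "include_word": False,
    },
    "null": {
        # no condition effects at all: for calibration checks
        "conditions": {"a": "words", "b": "words"},
        "modulation": {},
        "include_word": False,
    },
}


@dataclass
class ConditionData:
    streams: list[Stream]
    pset: PredictorSet           # normalized + padded
    design: LagDesign
    responses: list[SourceResponse]   # normalized + padded
    pset_raw: PredictorSet | None = None       # physical units, unpadded
    raw_responses: list[SourceResponse] | None = None   # unpadded, raw units
    drives: dict | None = None   # family -> unit-gain generative drive
    factors: list | None = None  # per-subject {"jitter", "gains"}


@dataclass
class Experiment:
    preset: str
    seed: int
    lexicon: Lexicon
    truth: GroundTruth
    conditions: dict[str, ConditionData]
    manifest: dict = field(default_factory=dict)


def build_condition_predictors(streams: list[Stream], lexicon: Lexicon,
                               rate: float = 100.0,
                               include_word: bool = False,
                               word_feature_rng: np.random.Generator | None = None,
                               fallback: str = "restart") -> PredictorSet:
    """Gammatone + edge + phoneme (and optionally word) channels per stream.

    Cohort annotation uses the ``restart`` fallback by default: in pseudoword
    streams each out-of-lexicon continuation re-enters the lexicon as if
    word-initial, so surprisal/entropy keep lexicon-driven variation (and a
    scale comparable to real words) instead of collapsing to a constant.
    """
    names = ([f"gammatone_{b}" for b in range(8)]
             + [f"edge_{b}" for b in range(8)]
             + ["phoneme_onset", "phoneme_surprisal", "phoneme_entropy"])
    families = (["gammatone"] * 8 + ["acoustic_edges"] * 8
                + ["phoneme_onset", "phoneme_surprisal", "phoneme_entropy"])
    if include_word:
        names += ["word_onset", "word_surprisal", "word_entropy"]
        families += ["word_onset", "word_surprisal", "word_entropy"]
    mats = []
    for stream in streams:
        env = gammatone_spectrogram(stream.audio, stream.fs, out_rate=rate)
        onset = onset_spectrogram(env)
        n = env.n_frames
        ann = annotate_events(stream.events, lexicon, fallback=fallback)
        rows = [env.data, onset.data,
                events_to_impulses(ann, rate, n)[None],
                events_to_impulses(ann, rate, n, "surprisal_bits")[None],
                events_to_impulses(ann, rate, n, "entropy_bits")[None]]
        if include_word:
            wev = ann[ann["tier"] == WORD_TIER].copy()
            if word_feature_rng is None:
                word_feature_rng = np.random.default_rng(0)
            wev["word_surprisal"] = word_feature_rng.uniform(2.0, 6.0, len(wev))
            wev["word_entropy"] = word_feature_rng.uniform(1.0, 4.0, len(wev))
            rows += [events_to_impulses(wev, rate, n, tier=WORD_TIER)[None],
                     events_to_impulses(wev, rate, n, "word_surprisal",
                                        tier=WORD_TIER)[None],
                     events_to_impulses(wev, rate, n, "word_entropy",
                                        tier=WORD_TIER)[None]]
        mats.append(np.concatenate(rows, axis=0))
    return build_predictor_set(mats, names, families, rate)


def make_experiment(preset: str, seed: int = 0, n_subjects: int | None = None,
                    n_sources: int | None = None,
                    n_sequences: int | None = None, snr: float | None = 0.5,
                    syllable_ms: float = 250.0, rate: float = 100.0,
                    fit_lags=(-50.0, 700.0),
                    kernel_scale: dict | None = None) -> Experiment:
    """Generate a full synthetic contrast: lexicon, streams, predictors,
    ground truth and simulated responses, ready for fitting.

    ``kernel_scale`` rescales a family's ground-truth kernel (e.g.
    ``{"phoneme": 0.0}`` makes the phoneme features non-generative, for
    specificity checks)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    lexicon = make_toy_lexicon(seed=seed)
    truth = default_truth(cfg["modulation"],
                          lags_ms=lag_axis_ms(*fit_lags, rate),
                          include_word=cfg["include_word"],
                          snr=0.5 if snr is None else snr, seed=seed)
    if n_subjects is not None:
        truth.n_subjects = n_subjects
    if n_sources is not None:
        truth.n_sources = n_sources
    raw: dict[str, tuple] = {}
    for ci, (name, stim_condition) in enumerate(cfg["conditions"].items()):
        # one stimulus seed for all conditions of a preset: the paired
        # conditions share word choices, so shuffled streams are true
        # permutations of their word-stream counterparts
        spec = StimulusSpec(condition=stim_condition, syllable_ms=syllable_ms,
                            seed=seed)
        if n_sequences is not None:
            spec.n_sequences = n_sequences
        streams = make_streams(spec, lexicon)
        wf_rng = np.random.default_rng(np.random.SeedSequence([seed, 43, ci]))
        raw[name] = (streams, build_condition_predictors(
            streams, lexicon, rate=rate, include_word=cfg["include_word"],
            word_feature_rng=wf_rng))
    # the generative TRFs act on *standardized* features (per condition):
    # neural gain adapts to the stimulus distribution, so condition effects
    # are exactly the injected modulation factors rather than by-products of
    # raw feature scales (pseudoword streams have intrinsically larger cohort
    # values). Kernels are scaled once, on the first condition, and shared.
    scale_truth_kernels(truth, normalize(next(iter(raw.values()))[1]))
    if kernel_scale:
        for fam, scale in kernel_scale.items():
            truth.kernels[fam] = truth.kernels[fam] * scale
    conditions = {}
    for name, (streams, pset_raw) in raw.items():
        # pad the predictors first and simulate on the padded grid: the
        # response to late-trial stimuli rings into the post-offset padding
        # (that is what the padding is for); truncating it at the offset
        # would contradict the forward model in the padded rows
        pset = normalize(pset_raw)
        pset_p, _ = pad_trials(pset, [])
        responses, details = simulate_responses(pset_p, truth, name,
                                                return_details=True)
        responses_p = [normalize_response(r) for r in responses]
        design = lag_expand(pset_p, *fit_lags)
        conditions[name] = ConditionData(
            streams, pset_p, design, responses_p, pset_raw=pset_raw,
            raw_responses=responses, drives=details["contribs"],
            factors=details["factors"])
    manifest = {
        "preset": preset, "seed": seed,
        "n_subjects": truth.n_subjects, "n_sources": truth.n_sources,
        "snr": truth.snr, "subject_jitter_sd": truth.subject_jitter_sd,
        "syllable_ms": syllable_ms, "rate": rate,
        "n_sequences": next(iter(conditions.values())).streams.__len__(),
        "modulation": {c: {f: [v[0], list(v[1]) if v[1] else None]
                           for f, v in mods.items()}
                       for c, mods in cfg["modulation"].items()},
        "kernel_peaks_ms": {"gammatone": 80.0, "acoustic_edges": 100.0,
                            "phoneme": 400.0},
    }
    return Experiment(preset, seed, lexicon, truth, conditions, manifest)
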