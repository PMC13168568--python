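"""Trial-structured predictor matrices and the lagged Hamming-basis design.

Feature channels live on a common 100 Hz grid, grouped into families
(gammatone bands, acoustic edges, phoneme onset/surprisal/entropy, word
onset/surprisal/entropy). The standard preparation before TRF estimation is

1. impulse coding of event features (value placed at floor(onset * rate)),
2. per-channel z-scoring (statistics computed over unpadded samples only),
3. zero padding of every trial from 50 ms before onset to 700 ms after
   offset, to absorb edge artifacts, and
4. expansion into lagged regressors: each channel is convolved with a 50 ms
   Hamming basis window centered on each lag of the [-50, 700) ms axis, which
   at 100 Hz yields T = 75 lag points per channel. Regressors never mix
   samples across trial boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PredictorSet", "SourceResponse", "LagDesign", "FAMILY_GROUPS",
    "events_to_impulses", "build_predictor_set", "normalize",
    "normalize_response", "pad_trials", "lag_expand", "lag_axis_ms",
]

#: Macro feature families used for ablation: a group maps to the channel
#: families it removes.
FAMILY_GROUPS = {
    "gammatone": ("gammatone",),
    "acoustic_edges": ("acoustic_edges",),
    "phoneme": ("phoneme_onset", "phoneme_surprisal", "phoneme_entropy"),
    "word": ("word_onset", "word_surprisal", "word_entropy"),
}


@dataclass
class PredictorSet:
    data: np.ndarray                 # (n_channels, n_samples)
    names: list[str]
    families: list[str]
    rate: float
    trials: list[tuple[int, int]]    # [start, stop) sample ranges
    norm_means: np.ndarray | None = None
    norm_sds: np.ndarray | None = None
    padded: bool = False
    valid_mask: np.ndarray | None = None   # True where unpadded

    def __post_init__(self):
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[1], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_indices(self, group: str) -> np.ndarray:
        fams = FAMILY_GROUPS.get(group, (group,))
        return np.array([i for i, f in enumerate(self.families) if f in fams],
                        dtype=int)


@dataclass
class SourceResponse:
    """Multi-source neural time series sharing the predictor grid."""
    data: np.ndarray                 # (n_sources, n_samples)
    rate: float
    trials: list[tuple[int, int]]
    subject: str | None = None
    norm_means: np.ndarray | None = None
    norm_sds: np.ndarray | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[1], dtype=bool)

    @property
    def n_sources(self) -> int:
        return self.data.shape[0]


def events_to_impulses(events: pd.DataFrame, rate: float, n_frames: int,
                       value_field: str | None = None,
                       tier: str = "phoneme") -> np.ndarray:
    """Impulse-code one event feature onto a frame grid.

    Each event of ``tier`` contributes its ``value_field`` value (1.0 for
    onset indicators when ``value_field`` is None) at frame
    ``floor(onset_s * rate)``; events sharing a frame sum. An event outside
    the grid is fatal.
    """
    channel = np.zeros(n_frames)
    sel = events[events["tier"] == tier] if "tier" in events.columns else events
    for _, row in sel.iterrows():
        frame = int(np.floor(float(row["onset_s"]) * rate))
        if not (0 <= frame < n_frames):
            raise ValueError(
                f"event at {row['onset_s']} s (label {row.get('label')!r}) "
                f"falls outside the {n_frames}-frame grid at {rate} Hz")
        value = 1.0 if value_field is None else float(row[value_field])
        channel[frame] += value
    return channel


def build_predictor_set(trial_matrices: list[np.ndarray], names: list[str],
                        families: list[str], rate: float) -> PredictorSet:
    """Concatenate per-trial (n_channels, n_i) matrices into one PredictorSet."""
    if not trial_matrices:
        raise ValueError("no trials")
    n_ch = trial_matrices[0].shape[0]
    if not (len(names) == len(families) == n_ch):
        raise ValueError("names/families/channel-count mismatch")
    trials, start = [], 0
    for m in trial_matrices:
        if m.shape[0] != n_ch:
            raise ValueError("inconsistent channel count across trials")
        trials.append((start, start + m.shape[1]))
        start += m.shape[1]
    return PredictorSet(np.concatenate(trial_matrices, axis=1),
                        list(names), list(families), rate, trials)


def _zscore(data: np.ndarray, mask: np.ndarray, what: list[str]):
    means = data[:, mask].mean(axis=1)
    sds = data[:, mask].std(axis=1)
    for i, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"zero-variance channel {what[i]!r}; "
                             "degenerate predictor or response")
    return (data - means[:, None]) / sds[:, None], means, sds


def normalize(pset: PredictorSet) -> PredictorSet:
    """Per-channel z-scoring; (mean, sd) computed over unpadded samples and
    recorded for inverse transforms."""
    data, means, sds = _zscore(pset.data, pset.valid_mask, pset.names)
    return replace(pset, data=data, norm_means=means, norm_sds=sds)


def normalize_response(resp: SourceResponse) -> SourceResponse:
    names = [f"source_{i}" for i in range(resp.n_sources)]
    data, means, sds = _zscore(resp.data, resp.valid_mask, names)
    return replace(resp, data=data, norm_means=means, norm_sds=sds)


def _pad_counts(rate: float, pre_ms: float = 50.0,
                post_ms: float = 700.0) -> tuple[int, int]:
    return int(round(pre_ms / 1000 * rate)), int(round(post_ms / 1000 * rate))


def pad_trials(pset: PredictorSet, response: SourceResponse | list,
               pre_ms: float = 50.0, post_ms: float = 700.0):
    """Zero pad every trial from ``pre_ms`` before onset to ``post_ms`` after
    offset in predictors and response(s) alike, updating trial boundaries."""
    responses = response if isinstance(response, list) else [response]
    for r in responses:
        if r.data.shape[1] != pset.n_samples or r.trials != pset.trials:
            raise ValueError("response grid/trials misaligned with predictors")
    pre, post = _pad_counts(pset.rate, pre_ms, post_ms)
    new_trials, pieces_mask = [], []
    start = 0
    for (a, b) in pset.trials:
        if b <= a:
            raise ValueError("zero-length trial")
        n = b - a + pre + post
        new_trials.append((start, start + n))
        mask = np.zeros(n, dtype=bool)
        mask[pre:pre + (b - a)] = True
        pieces_mask.append(mask)
        start += n

    def _pad(data, old_mask):
        cols = []
        for (a, b), m in zip(pset.trials, pieces_mask):
            block = np.zeros((data.shape[0], len(m)))
            block[:, m] = data[:, a:b]
            cols.append(block)
        return np.concatenate(cols, axis=1)

    mask = np.concatenate(pieces_mask)
    new_pset = replace(pset, data=_pad(pset.data, None), trials=new_trials,
                       padded=True, valid_mask=mask)
    new_responses = [replace(r, data=_pad(r.data, None), trials=new_trials,
                             valid_mask=mask) for r in responses]
    if isinstance(response, list):
        return new_pset, new_responses
    return new_pset, new_responses[0]


def lag_axis_ms(start_ms: float = -50.0, stop_ms: float = 700.0,
                rate: float = 100.0) -> np.ndarray:
    """Lag times in ms, left-closed right-open [start, stop) at the grid step.

    At 100 Hz the default [-50, 700) window yields exactly 75 lag points —
    the only convention consistent with a printed lag count of T = 75 for
    "between -50 ms and 700 ms".
    """
    step = 1000.0 / rate
    return np.arange(start_ms, stop_ms - step / 2, step)


@dataclass
class LagDesign:
    """Lag-expanded design: one regressor per (channel, lag), channel-major."""
    X: np.ndarray                    # (n_samples, n_channels * n_lags)
    lags_ms: np.ndarray
    channel_names: list[str]
    channel_families: list[str]
    trials: list[tuple[int, int]]
    rate: float
    valid_mask: np.ndarray
    basis: np.ndarray = field(default_factory=lambda: np.array([]))
    #: per-channel sds recorded at normalization (for raw-unit kernels)
    channel_sds: np.ndarray | None = None

    @property
    def n_lags(self) -> int:
        return len(self.lags_ms)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def columns_for_channels(self, channels: np.ndarray) -> np.ndarray:
        K = self.n_lags
        return (np.asarray(channels)[:, None] * K + np.arange(K)).ravel()


def hamming_basis(width_ms: float = 50.0, rate: float = 100.0) -> np.ndarray:
    """Hamming basis window, normalized to integrate (sum) to 1."""
    n = int(round(width_ms / 1000 * rate))
    n += 1 - n % 2  # odd length so 'same' convolution is centered
    w = np.hamming(n)
    return w / w.sum()


def lag_expand(pset: PredictorSet, start_ms: float = -50.0,
               stop_ms: float = 700.0, basis_ms: float = 50.0,
               basis_alignment: str = "centered") -> LagDesign:
    """Expand channels into per-lag regressors on the Hamming basis.

    For channel x and lag tau, the regressor is (x * w)(t - tau) with w the
    basis window, computed within each trial (no mixing across boundaries).
    ``basis_alignment`` may be "centered" (default) or "left" (window
    left-aligned to each lag).
    """
    if basis_alignment not in ("centered", "left"):
        raise ValueError(f"unknown basis alignment {basis_alignment!r}")
    lags = lag_axis_ms(start_ms, stop_ms, pset.rate)
    lag_samp = np.round(lags * pset.rate / 1000).astype(int)
    if basis_alignment == "left":
        w = hamming_basis(basis_ms, pset.rate)
        lag_samp = lag_samp + (len(w) // 2)
    w = hamming_basis(basis_ms, pset.rate)
    C, K = pset.data.shape[0], len(lags)
    X = np.zeros((pset.n_samples, C * K))
    for (a, b) in pset.trials:
        n = b - a
        for c in range(C):
            s = np.convolve(pset.data[c, a:b], w, mode="same")
            for k, L in enumerate(lag_samp):
                lo, hi = max(0, L), min(n, n + L)
                if hi > lo:   # lags longer than the trial leave zeros
                    X[a + lo:a + hi, c * K + k] = s[lo - L:hi - L]
    return LagDesign(X, lags, list(pset.names), list(pset.families),
                     list(pset.trials), pset.rate, pset.valid_mask.copy(), w,
                     channel_sds=None if pset.norm_sds is None
                     else pset.norm_sds.copy())
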