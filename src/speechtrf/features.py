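"""Gammatone spectrogram and acoustic-edge (onset) features.

An 8-band gammatone filterbank with center frequencies equally spaced on the
ERB-number scale between 20 and 5000 Hz yields a cochlea-like auditory
spectrogram of the speech signal. Acoustic edges — sudden increases of the
per-band envelope, the cue that phoneme onsets ride on — are modeled as the
half-wave rectified first derivative of that envelope.

Envelope extraction per band is rectify-then-low-pass (4th-order Butterworth,
40 Hz by default) followed by polyphase resampling to the 100 Hz predictor
grid; amplitudes are linear (no power or log compression). Frame timestamps
are left edges: frame k covers [k, k+1)/rate seconds.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "BandedEnvelope", "OnsetSpectrogram", "erb_number", "erb_number_inverse",
    "erb_centers", "gammatone_spectrogram", "onset_spectrogram", "read_wav",
    "write_feature_tsv",
]

# Glasberg & Moore ERB-number scale constants
_ERB_A = 21.4
_ERB_B = 0.00437


@dataclass
class BandedEnvelope:
    """Per-band non-negative envelope amplitudes on a uniform frame grid."""
    center_hz: np.ndarray      # (n_bands,), strictly increasing
    data: np.ndarray           # (n_bands, n_frames), >= 0
    rate: float                # frames per second

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


class OnsetSpectrogram(BandedEnvelope):
    """Per-band non-negative onset (acoustic-edge) strength."""


def erb_number(f_hz):
    """ERB-number (Cam) of frequency ``f_hz``: 21.4 * log10(1 + 0.00437 f)."""
    return _ERB_A * np.log10(1.0 + _ERB_B * np.asarray(f_hz, dtype=float))


def erb_number_inverse(erb):
    return (10.0 ** (np.asarray(erb, dtype=float) / _ERB_A) - 1.0) / _ERB_B


def erb_centers(fmin: float, fmax: float, n: int) -> np.ndarray:
    """``n`` frequencies equally spaced on the ERB-number scale, endpoints
    included."""
    if not (0 < fmin < fmax):
        raise ValueError(f"need 0 < fmin < fmax, got ({fmin}, {fmax})")
    if n < 2:
        raise ValueError("need at least 2 bands")
    return erb_number_inverse(np.linspace(erb_number(fmin), erb_number(fmax), n))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float samples in [-1, 1]; stereo is averaged to mono
    with a warning."""
    fs, x = wavfile.read(path)
    if x.dtype.kind == "i":
        x = x.astype(float) / float(np.iinfo(x.dtype).max)
    elif x.dtype.kind == "u":
        info = np.iinfo(x.dtype)
        x = (x.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        x = x.astype(float)
    if x.ndim == 2:
        warnings.warn("stereo input averaged to mono")
        x = x.mean(axis=1)
    return x, int(fs)


def _resample_to(x: np.ndarray, fs: float, out_rate: float,
                 n_out: int) -> np.ndarray:
    ratio = Fraction(out_rate).limit_denominator(10 ** 6) / \
        Fraction(fs).limit_denominator(10 ** 6)
    y = signal.resample_poly(x, ratio.numerator, ratio.denominator)
    if len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)))
    return y[:n_out]


def gammatone_spectrogram(wave: np.ndarray, fs: float, n_bands: int = 8,
                          fmin: float = 20.0, fmax: float = 5000.0,
                          out_rate: float = 100.0,
                          env_lowpass_hz: float = 40.0) -> BandedEnvelope:
    """Auditory spectrogram: 4th-order gammatone filterbank at ERB-spaced
    centers, rectified + low-passed envelopes, resampled to ``out_rate``.

    Output length is ``ceil(duration * out_rate)``. Silence maps to zeros;
    a sample rate below 2*fmax is an error.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.ndim == 2:
        warnings.warn("stereo input averaged to mono")
        wave = wave.mean(axis=1)
    if wave.size == 0:
        raise ValueError("empty audio")
    if fs < 2 * fmax:
        raise ValueError(
            f"sample rate {fs} Hz too low for fmax={fmax} Hz; need >= {2 * fmax}")
    centers = erb_centers(fmin, fmax, n_bands)
    n_out = math.ceil(len(wave) / fs * out_rate)
    data = np.empty((n_bands, n_out))
    for b, fc in enumerate(centers):
        # low-frequency bands are filtered at a decimated rate and in
        # second-order sections: the 8th-order direct-form gammatone is
        # ill-conditioned (or outright unstable) when fc/fs is very small
        fs_b, sos = _stable_gammatone_sos(fc, fs)
        x = wave if fs_b == fs else _resample_to(
            wave, fs, fs_b, math.ceil(len(wave) / fs * fs_b))
        band = signal.sosfilt(sos, x)
        sos_lp = signal.butter(4, env_lowpass_hz, fs=fs_b, output="sos")
        env = signal.sosfilt(sos_lp, np.maximum(band, 0.0))
        data[b] = np.maximum(_resample_to(env, fs_b, out_rate, n_out), 0.0)
    return BandedEnvelope(centers, data, out_rate)


def _stable_gammatone_sos(fc: float, fs: float) -> tuple[float, np.ndarray]:
    """Gammatone filter in second-order sections at the highest rate
    fs / 2**k no greater than needed for good conditioning (~16 fc)."""
    fs_b = float(fs)
    while fs_b / 2 >= max(1000.0, 16.0 * fc):
        fs_b /= 2.0
    num, den = signal.gammatone(fc, "iir", fs=fs_b)
    return fs_b, signal.tf2sos(num, den)


def onset_spectrogram(env: BandedEnvelope) -> OnsetSpectrogram:
    """Acoustic edges: per-band half-wave rectified envelope derivative.

    First difference scaled by the frame rate, negative values clipped to 0,
    first frame defined as 0. A constant envelope therefore maps to zeros,
    and offsets (envelope decreases) are rejected.
    """
    d = np.diff(env.data, axis=1) * env.rate
    onset = np.concatenate([np.zeros((env.n_bands, 1)), np.maximum(d, 0.0)],
                           axis=1)
    return OnsetSpectrogram(env.center_hz.copy(), onset, env.rate)


def write_feature_tsv(env: BandedEnvelope, path) -> None:
    cols = {f"band_{fc:.0f}Hz": env.data[b] for b, fc in enumerate(env.center_hz)}
    df = pd.DataFrame(cols)
    df.insert(0, "time_s", np.arange(env.n_frames) / env.rate)
    df.to_csv(path, sep="\t", index=False)
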