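"""Group-level inference on TRF results.

* one-sample t-tests of source-averaged accuracy improvements against zero;
* paired cluster-based permutation tests across lag time on TRF weight
  time courses (per-lag paired t, suprathreshold runs, cluster mass, maximum
  cluster-mass sign-flip null, 30,000 permutations by default);
* peak-latency extraction in early (-50..100 ms), mid (100..350 ms) and late
  (350..700 ms) windows.

The first and last 20 ms of the lag axis are excluded from all statistics to
avoid estimation edge artifacts. Cluster p-values use the add-one convention
p = (1 + #{null >= observed}) / (1 + n_permutations), so p >= 1/(n+1) > 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .boosting import TRFModel

__all__ = [
    "Cluster", "ClusterResult", "PEAK_WINDOWS_MS", "edge_mask",
    "improvement_ttest", "cluster_permutation", "peak_latency",
    "weight_timecourse", "clusters_to_frame",
]

PEAK_WINDOWS_MS = {"early": (-50.0, 100.0), "mid": (100.0, 350.0),
                   "late": (350.0, 700.0)}


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    threshold: float
    seed: int | None
    lags_ms: np.ndarray
    t_obs: np.ndarray            # on the masked lag axis
    mask: np.ndarray             # which lags entered the analysis

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def edge_mask(lags_ms: np.ndarray, edge_ms: float = 20.0) -> np.ndarray:
    """True for lags at least ``edge_ms`` inside both ends of the lag axis."""
    lags_ms = np.asarray(lags_ms, dtype=float)
    return (lags_ms >= lags_ms[0] + edge_ms) & (lags_ms <= lags_ms[-1] - edge_ms)


def improvement_ttest(improvements) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of per-subject values against zero."""
    x = np.asarray(improvements, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 subjects")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance across subjects")
    res = sps.ttest_1samp(x, 0.0)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def _paired_t(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _clusters_from_t(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Contiguous same-sign suprathreshold runs: (start, stop) index, mass."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * t > thr
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8),
                                                       [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            out.append((int(a), int(b), float(t[a:b].sum())))
    out.sort()
    return out


def _max_cluster_mass(t: np.ndarray, thr: float) -> float:
    cl = _clusters_from_t(t, thr)
    return max((abs(m) for _, _, m in cl), default=0.0)


def cluster_permutation(a: np.ndarray, b: np.ndarray, lags_ms: np.ndarray,
                        n_permutations: int = 30_000,
                        cluster_alpha: float = 0.05,
                        seed: int | None = None, edge_ms: float = 20.0,
                        two_sided: bool = True) -> ClusterResult:
    """Paired cluster permutation test of condition a vs b across lag time.

    ``a`` and ``b`` are (n_subjects, n_lags) weight time courses with the
    subjects paired across conditions. The cluster-forming threshold is the
    two-sided per-lag paired-t critical value at ``cluster_alpha``; the null
    distribution is the maximum cluster |mass| over random sign flips of the
    subject differences (both signs pooled when ``two_sided``).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("conditions are not paired (shape mismatch)")
    if a.shape[1] != len(lags_ms):
        raise ValueError("lag axis mismatch")
    mask = edge_mask(lags_ms, edge_ms)
    lags = np.asarray(lags_ms, float)[mask]
    d = (a - b)[:, mask]
    n = d.shape[0]
    thr = float(sps.t.ppf(1 - cluster_alpha / 2, n - 1))
    t_obs = _paired_t(d)
    observed = _clusters_from_t(t_obs, thr)
    if not two_sided:
        observed = [(i, j, m) for i, j, m in observed if m > 0]

    clusters: list[Cluster] = []
    if observed:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        M = signs @ d / n                              # (P, L) flipped means
        ssq = np.sum(d * d, axis=0)                    # invariant to flips
        var = (ssq / n - M * M) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(var > 0, M / np.sqrt(var / n), 0.0)
        null = np.array([_max_cluster_mass(T[i], thr)
                         for i in range(n_permutations)])
        for i, j, m in observed:
            # tolerance so sign patterns that reproduce the observed data
            # (e.g. the identity) count as ties despite float noise
            crit = abs(m) * (1 - 1e-12) - 1e-9
            p = (1 + int(np.sum(null >= crit))) / (1 + n_permutations)
            clusters.append(Cluster(lags[i], lags[j - 1], m, p))
    return ClusterResult(clusters, n_permutations, thr, seed, lags, t_obs, mask)


def peak_latency(weights: np.ndarray, lags_ms: np.ndarray, window: str,
                 edge_ms: float = 20.0) -> float:
    """Lag (ms) of the maximum weight within a named window; ties resolve to
    the earliest lag; the 20 ms edge mask is respected."""
    lo, hi = PEAK_WINDOWS_MS[window]
    lags = np.asarray(lags_ms, float)
    sel = edge_mask(lags, edge_ms) & (lags >= lo) & (lags <= hi)
    if not sel.any():
        raise ValueError(f"window {window!r} is empty after edge masking")
    w = np.asarray(weights, float)[sel]
    return float(lags[sel][int(np.argmax(w))])


def weight_timecourse(models: list[TRFModel], family: str | None = None,
                      aggregate: str = "mean",
                      units: str = "response") -> np.ndarray:
    """Per-subject TRF weight time courses, (n_subjects, n_lags).

    For each subject the per-fold-mean kernel is rectified (|weights|) and
    aggregated over sources and over the channels of ``family`` (all channels
    when None). ``aggregate`` is "mean" (default, scale-invariant across
    source counts) or "sum". ``units``: "response" (default) rescales each
    source's kernel by its recorded response sd, making amplitudes
    comparable across conditions that were z-scored separately; "raw"
    additionally divides by the per-channel predictor sds; "normalized" uses
    the fitted coefficients as is.
    """
    from .predictors import FAMILY_GROUPS
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if units not in ("response", "raw", "normalized"):
        raise ValueError(f"unknown units {units!r}")
    rows = []
    for m in models:
        if units == "raw":
            kern = m.raw_kernel
        elif units == "response" and m.response_sds is not None:
            kern = m.mean_kernel * m.response_sds[:, None, None]
        else:
            kern = m.mean_kernel                  # (S, C, K)
        if family is not None:
            fams = FAMILY_GROUPS.get(family, (family,))
            idx = [i for i, f in enumerate(m.channel_families) if f in fams]
            if not idx:
                raise ValueError(f"family {family!r} not in model")
            kern = kern[:, idx, :]
        w = np.abs(kern)
        agg = w.mean(axis=(0, 1)) if aggregate == "mean" else w.sum(axis=(0, 1))
        rows.append(agg)
    return np.array(rows)


def clusters_to_frame(result: ClusterResult) -> pd.DataFrame:
    """Cluster report in tidy form (TSV-ready)."""
    return pd.DataFrame(
        [{"cluster_start_ms": c.start_ms, "cluster_end_ms": c.end_ms,
          "mass": c.mass, "p": c.p, "n_permutations": result.n_permutations,
          "seed": result.seed, "threshold": result.threshold}
         for c in result.clusters])
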