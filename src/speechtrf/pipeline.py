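"""Config-driven orchestration: run the full analysis end to end.

Ties the stages together — synthetic experiment generation, feature and
predictor assembly, boosted TRF fitting with ablations, and group statistics
— and handles on-disk bundles (WAV + TextGrid + TSV + npz + YAML manifest) so
runs are reproducible from their manifest alone.
"""
from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import textgrid as tg
from .boosting import (AblationResult, BlockGrams, TRFModel, ablate_group,
                       accuracy_table, fit_trf_group)
from .lexicon import PHONEME_TIER, WORD_TIER
from .predictors import PredictorSet, SourceResponse, lag_expand
from .stats import (PEAK_WINDOWS_MS, cluster_permutation,
                    improvement_ttest, peak_latency, weight_timecourse)
from .synth import Experiment

logger = logging.getLogger("speechtrf")

__all__ = [
    "RunConfig", "ExperimentFit", "fit_experiment", "experiment_stats",
    "write_bundle", "read_bundle", "save_fit", "load_fit",
]


@dataclass
class RunConfig:
    """All tunable parameters of a run; fully serializable to YAML.

    Defaults follow the standard analysis: 100 Hz grid, 8 bands over
    20-5000 Hz, [-50, 700) ms lags on a 50 ms Hamming basis, fivefold
    cross-validation, 30,000 permutations, 20 ms edge masks.
    """
    rate: float = 100.0
    n_bands: int = 8
    fmin: float = 20.0
    fmax: float = 5000.0
    lag_start_ms: float = -50.0
    lag_stop_ms: float = 700.0
    basis_ms: float = 50.0
    folds: int = 5
    step: float = 0.005
    patience: int = 10
    max_iter: int = 10000
    check_every: int = 20
    n_permutations: int = 30000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    edge_mask_ms: float = 20.0
    ablate_families: tuple = ("acoustic_edges", "phoneme")
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in dataclasses.asdict(self).items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ablate_families" in raw:
            raw["ablate_families"] = tuple(raw["ablate_families"])
        return cls(**raw)


@dataclass
class ExperimentFit:
    models: dict[str, list[TRFModel]]
    ablations: dict[str, dict[str, list[AblationResult]]]
    config: RunConfig = field(default_factory=RunConfig)


def fit_experiment(exp: Experiment, config: RunConfig | None = None,
                   ablate: bool = True) -> ExperimentFit:
    """Fit the full TRF model (and each ablated model) for every subject and
    condition of a synthetic experiment."""
    config = config or RunConfig()
    models, ablations = {}, {}
    for name, cond in exp.conditions.items():
        t0 = time.perf_counter()
        grams = BlockGrams(cond.design, config.folds)
        models[name] = fit_trf_group(
            cond.design, cond.responses, folds=config.folds, step=config.step,
            patience=config.patience, max_iter=config.max_iter,
            check_every=config.check_every, grams=grams, keep_logs=False)
        ablations[name] = {}
        if ablate:
            for fam in config.ablate_families:
                ablations[name][fam] = ablate_group(
                    cond.design, cond.responses, fam, models[name],
                    grams=grams, patience=config.patience,
                    max_iter=config.max_iter,
                    check_every=config.check_every)
        logger.info("fit condition %s (%d subjects) in %.1f s", name,
                    len(cond.responses), time.perf_counter() - t0)
    return ExperimentFit(models, ablations, config)


def experiment_stats(fit: ExperimentFit, cond_a: str, cond_b: str,
                     family: str, config: RunConfig | None = None,
                     seed: int | None = None):
    """Group statistics for one paired contrast on one feature family.

    Returns a dict with the improvement t-tests per condition, the cluster
    permutation result on the weight time courses (a minus b), and a tidy
    per-subject peak-latency table.
    """
    config = config or fit.config
    lags = fit.models[cond_a][0].lags_ms
    w_a = weight_timecourse(fit.models[cond_a], family)
    w_b = weight_timecourse(fit.models[cond_b], family)
    clusters = cluster_permutation(
        w_a, w_b, lags, n_permutations=config.n_permutations,
        cluster_alpha=config.cluster_alpha, seed=seed,
        edge_ms=config.edge_mask_ms)
    ttests = {}
    for cond in (cond_a, cond_b):
        if family in fit.ablations.get(cond, {}):
            imp = [r.improvement.mean()
                   for r in fit.ablations[cond][family]]
            ttests[cond] = improvement_ttest(imp)
    rows = []
    for cond, w in ((cond_a, w_a), (cond_b, w_b)):
        for si, tc in enumerate(w):
            row = {"subject": fit.models[cond][si].subject,
                   "condition": cond, "feature_family": family}
            for win in PEAK_WINDOWS_MS:
                row[f"peak_latency_{win}"] = peak_latency(
                    tc, lags, win, edge_ms=config.edge_mask_ms)
            rows.append(row)
    return {"clusters": clusters, "ttests": ttests,
            "peaks": pd.DataFrame(rows),
            "timecourses": {cond_a: w_a, cond_b: w_b}, "lags_ms": lags}


def _residualized_family_problem(exp, cond: str, family: str,
                                 config: RunConfig):
    """Family-only design and residualized responses for recovery checks.

    The other families' known generative contributions are subtracted from
    each response (ground-truth residualization). This is what makes the
    family kernel identifiable: with isochronous streams and one fixed token
    per syllable identity, the phoneme features are linearly decodable from
    the acoustic channels, so full-model attribution between families is not
    unique (see docs/methods.md).
    """
    from dataclasses import replace
    from .predictors import normalize_response
    cd = exp.conditions[cond]
    resid = []
    for r, fac in zip(cd.raw_responses, cd.factors):
        data = r.data.copy()
        nuis = sum(fac["jitter"][f] * cd.drives[f]
                   for f in cd.drives if f != family)
        for s in range(r.n_sources):
            data[s] = data[s] - fac["gains"][s] * nuis
        resid.append(normalize_response(replace(r, data=data)))
    return cd.design, resid, cd.pset.channel_indices(family)


def residualized_family_models(exp, cond: str, family: str = "phoneme",
                               config: RunConfig | None = None
                               ) -> list[TRFModel]:
    """Boosted family-only TRFs on ground-truth-residualized responses.

    Their weight time courses give an identifiable per-subject readout of
    one family's encoding strength, suitable for cross-condition cluster
    tests on synthetic data."""
    config = config or RunConfig()
    design, resid_p, channels = _residualized_family_problem(
        exp, cond, family, config)
    return fit_trf_group(design, resid_p, folds=config.folds,
                         step=config.step, patience=config.patience,
                         max_iter=config.max_iter,
                         check_every=config.check_every,
                         channels=channels, keep_logs=False)


def family_amplitude(exp, cond: str, family: str = "phoneme",
                     config: RunConfig | None = None) -> np.ndarray:
    """Per-subject amplitude of one family's kernel, recovered end to end.

    Exact least squares on the residualized family-only design (unbiased:
    boosting's early stopping shrinks amplitudes differentially with
    condition SNR, which would bias cross-condition amplitude ratios). The
    amplitude is the projection of the summed family kernels (response
    units) onto the true kernel shape; both sides are centered across lags
    so the DC offset that absorbs the feature means drops out.
    """
    config = config or RunConfig()
    design, resid_p, channels = _residualized_family_problem(
        exp, cond, family, config)
    cols = design.columns_for_channels(channels)
    X = design.X[:, cols]
    G = X.T @ X + 1e-8 * np.trace(X.T @ X) / X.shape[1] * np.eye(X.shape[1])
    K = design.n_lags
    kappa = exp.truth.kernels[family]
    kappa = kappa - kappa.mean()
    kn = float(kappa @ kappa)
    amps = []
    for r, fac in zip(resid_p, exp.conditions[cond].factors):
        per_source = []
        for s in range(r.n_sources):
            b = np.linalg.solve(G, X.T @ r.data[s]).reshape(len(channels), K)
            kern = b * r.norm_sds[s]
            per_source.append(
                sum((kern[c] - kern[c].mean()) @ kappa / kn
                    for c in range(len(channels))) / fac["gains"][s])
        amps.append(np.mean(per_source))
    return np.array(amps)


# ---------------------------------------------------------------------------
# on-disk bundles
# ---------------------------------------------------------------------------

def _events_to_textgrid(events: pd.DataFrame, path, xmax: float) -> None:
    tiers = []
    for tier_name in (PHONEME_TIER, WORD_TIER):
        sel = events[events["tier"] == tier_name].sort_values("onset_s")
        onsets = list(sel["onset_s"]) + [xmax]
        ivs = [tg.Interval(onsets[i], onsets[i + 1], str(lbl))
               for i, lbl in enumerate(sel["label"])]
        tiers.append(tg.IntervalTier(tier_name, 0.0, xmax, ivs))
    tg.write_textgrid(path, tiers, 0.0, xmax)


def write_bundle(exp: Experiment, outdir) -> Path:
    """Write an experiment to disk: manifest, lexicon, audio, events,
    predictor and response containers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(exp.manifest, fh)
    with open(outdir / "lexicon.tsv", "w", encoding="utf-8") as fh:
        fh.write("# word\tfrequency\tphonemes\n")
        for e in exp.lexicon.entries:
            fh.write(f"{e.form}\t{e.frequency}\t{' '.join(e.phonemes)}\n")
    for name, cond in exp.conditions.items():
        cdir = outdir / name
        (cdir / "audio").mkdir(parents=True, exist_ok=True)
        all_events = []
        for i, stream in enumerate(cond.streams):
            wavfile.write(cdir / "audio" / f"seq_{i:03d}.wav", stream.fs,
                          stream.audio.astype(np.float32))
            dur = len(stream.audio) / stream.fs
            _events_to_textgrid(stream.events,
                                cdir / "audio" / f"seq_{i:03d}.TextGrid", dur)
            ev = stream.events.copy()
            ev.insert(0, "sequence", i)
            all_events.append(ev)
        pd.concat(all_events).to_csv(cdir / "events.tsv", sep="\t",
                                     index=False)
        p = cond.pset
        np.savez(cdir / "predictors.npz", data=p.data, names=p.names,
                 families=p.families, rate=p.rate,
                 trials=np.array(p.trials), norm_means=p.norm_means,
                 norm_sds=p.norm_sds, valid_mask=p.valid_mask,
                 padded=p.padded)
        resp = np.stack([r.data for r in cond.responses])
        sds = np.stack([r.norm_sds for r in cond.responses])
        np.savez(cdir / "responses.npz", data=resp, sds=sds,
                 subjects=[r.subject for r in cond.responses])
    return outdir


def read_bundle(bundledir):
    """Load a bundle's predictors and responses per condition."""
    bundledir = Path(bundledir)
    with open(bundledir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    conditions = {}
    for cdir in sorted(d for d in bundledir.iterdir() if d.is_dir()):
        pz = cdir / "predictors.npz"
        if not pz.exists():
            continue
        p = np.load(pz, allow_pickle=False)
        trials = [tuple(t) for t in p["trials"]]
        pset = PredictorSet(p["data"], [str(n) for n in p["names"]],
                            [str(f) for f in p["families"]], float(p["rate"]),
                            trials, p["norm_means"], p["norm_sds"],
                            bool(p["padded"]), p["valid_mask"])
        r = np.load(cdir / "responses.npz", allow_pickle=False)
        responses = [SourceResponse(r["data"][i], pset.rate, trials,
                                    subject=str(r["subjects"][i]),
                                    norm_sds=r["sds"][i],
                                    valid_mask=pset.valid_mask.copy())
                     for i in range(r["data"].shape[0])]
        conditions[cdir.name] = (pset, responses)
    return manifest, conditions


def save_fit(fit: ExperimentFit, outdir) -> Path:
    """Persist fitted kernels and tidy accuracy tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, models in fit.models.items():
        m0 = models[0]
        np.savez(outdir / f"kernels_{name}.npz",
                 kernels=np.stack([m.mean_kernel for m in models]),
                 accuracies=np.stack([m.accuracies for m in models]),
                 response_sds=np.stack([m.response_sds for m in models]),
                 lags_ms=m0.lags_ms, channel_names=m0.channel_names,
                 channel_families=m0.channel_families,
                 subjects=[m.subject for m in models], step=m0.step)
        table = accuracy_table(models, fit.ablations.get(name))
        table.insert(0, "condition", name)
        table.to_csv(outdir / f"accuracies_{name}.tsv", sep="\t", index=False)
    with open(outdir / "fit_config.yaml", "w") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in dataclasses.asdict(fit.config).items()},
                       fh)
    return outdir


def load_fit(fitdir) -> ExperimentFit:
    fitdir = Path(fitdir)
    config = RunConfig.from_yaml(fitdir / "fit_config.yaml")
    models, ablations = {}, {}
    for path in sorted(fitdir.glob("kernels_*.npz")):
        name = path.stem[len("kernels_"):]
        z = np.load(path, allow_pickle=False)
        models[name] = []
        for i in range(z["kernels"].shape[0]):
            models[name].append(TRFModel(
                z["kernels"][i][None], z["accuracies"][i], z["lags_ms"],
                [str(n) for n in z["channel_names"]],
                [str(f) for f in z["channel_families"]],
                [[0]], [0], float(z["step"]), subject=str(z["subjects"][i]),
                response_sds=z["response_sds"][i]))
        tab = pd.read_csv(fitdir / f"accuracies_{name}.tsv", sep="\t")
        ablations[name] = {}
        for fam, sub in tab[tab["model"] != "full"].groupby("feature_family"):
            results = []
            full = tab[tab["model"] == "full"]
            for subj, rows in sub.groupby("subject", sort=False):
                fa = full[full["subject"] == subj].sort_values("source")
                rr = rows.sort_values("source")
                results.append(AblationResult(
                    str(fam), fa["accuracy"].to_numpy(),
                    rr["accuracy"].to_numpy(), subject=str(subj)))
            ablations[name][str(fam)] = results
    return ExperimentFit(models, ablations, config)
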