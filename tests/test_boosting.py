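"""Boosted TRF estimation: convergence, cross-validation hygiene, ablation."""
import numpy as np
import pytest
from scipy.ndimage import uniform_filter1d

import speechtrf as st
from speechtrf.boosting import _boost
from speechtrf.predictors import SourceResponse


def smooth_noise_design(rng, n_channels=3, n_trials=6, n_frames=500,
                        families=None, lag_window=(-50.0, 700.0)):
    """Well-conditioned design: smoothed white-noise channels."""
    families = families or (["gammatone", "acoustic_edges", "phoneme_onset"]
                            * n_channels)[:n_channels]
    mats = [uniform_filter1d(rng.standard_normal((n_channels, n_frames)),
                             5, axis=1) for _ in range(n_trials)]
    pset = st.build_predictor_set(mats, [f"c{i}" for i in range(n_channels)],
                                  families, 100.0)
    pset = st.normalize(pset)
    dummy = SourceResponse(np.zeros((1, pset.n_samples)), 100.0,
                           list(pset.trials))
    pset, resp = st.pad_trials(pset, dummy)
    return st.lag_expand(pset, *lag_window), resp


def realizable_response(design, rng, n_nonzero=8, scale=0.05):
    b = np.zeros(design.X.shape[1])
    idx = rng.choice(len(b), n_nonzero, replace=False)
    b[idx] = scale * rng.choice([-1.0, 1.0, 2.0], n_nonzero)
    return design.X @ b, b


# --- the Gram-based inner loop against a naive residual reference -----------

def naive_boost(X_tr, y_tr, X_va, y_va, step, patience, max_iter,
                check_every=20):
    """Reference implementation: explicit residual recomputation per step."""
    p = X_tr.shape[1]
    b = np.zeros(p)
    best = (float(y_va @ y_va), b.copy())
    best_it = 0
    col_ss = np.sum(X_tr ** 2, axis=0)
    for it in range(1, max_iter + 1):
        r = y_tr - X_tr @ b
        g = X_tr.T @ r
        gain = 2 * step * np.abs(g) - step ** 2 * col_ss
        j = int(np.argmax(gain))
        if gain[j] <= 0:
            break
        b[j] += step if g[j] >= 0 else -step
        e_va = float(np.sum((y_va - X_va @ b) ** 2))
        if e_va < best[0]:
            best = (e_va, b.copy())
            best_it = it
        elif it - best_it > patience * check_every:
            break
    return best[1]


def test_gram_boost_equals_naive_reference(rng):
    X = rng.standard_normal((120, 30))
    y = X @ (0.1 * rng.standard_normal(30) * (rng.random(30) < 0.3))
    y += 0.05 * rng.standard_normal(120)
    X_tr, y_tr, X_va, y_va = X[:80], y[:80], X[80:], y[80:]
    b_ref = naive_boost(X_tr, y_tr, X_va, y_va, 0.01, 2, 500, check_every=5)
    b_gram, _ = _boost(X_tr.T @ X_tr, X_tr.T @ y_tr, y_tr @ y_tr,
                       X_va.T @ X_va, X_va.T @ y_va, y_va @ y_va,
                       0.01, 2, 500, check_every=5)
    np.testing.assert_allclose(b_gram, b_ref, atol=1e-10)


# --- convergence and recovery ------------------------------------------------

def test_noiseless_realizable_target_recovered(rng):
    design, resp = smooth_noise_design(rng)
    y, b_true = realizable_response(design, rng)
    resp.data[0] = y
    model = st.fit_trf(design, resp)
    assert model.accuracies.min() >= 0.99
    est = model.mean_kernel[0].reshape(-1)
    assert np.corrcoef(est, b_true)[0, 1] >= 0.99


def test_pure_noise_response_has_no_skill(rng):
    """Held-out accuracy on predictor-independent noise stays at chance."""
    design, resp = smooth_noise_design(rng, n_trials=5, n_frames=300)
    accs = []
    for _ in range(20):
        resp.data[0] = rng.standard_normal(resp.data.shape[1])
        model = st.fit_trf(design, resp, keep_logs=False)
        accs.append(model.accuracies.mean())
    assert np.mean(accs) <= 0.02


def test_boosting_error_close_to_least_squares_oracle(rng):
    """Small full-rank instance: held-out error within 10% of the exact
    normal-equations solution fit on the same training data."""
    design, resp = smooth_noise_design(rng, n_channels=2, n_trials=5,
                                       n_frames=100, lag_window=(0.0, 100.0))
    assert design.n_lags == 10
    y, _ = realizable_response(design, rng, n_nonzero=6, scale=0.1)
    y += 0.1 * rng.standard_normal(len(y))
    resp.data[0] = y
    model = st.fit_trf(design, resp)
    X = design.X
    err_boost, err_ols = [], []
    for f, blk in enumerate(model.fold_trials):
        te = np.concatenate([np.arange(*design.trials[t]) for t in blk])
        tr = np.setdiff1d(np.arange(X.shape[0]), te)
        b_ols = np.linalg.lstsq(X[tr], y[tr], rcond=None)[0]
        b_boost = model.kernels[f, 0].reshape(-1)
        err_boost.append(np.sum((y[te] - X[te] @ b_boost) ** 2))
        err_ols.append(np.sum((y[te] - X[te] @ b_ols) ** 2))
    assert np.sum(err_boost) <= 1.10 * np.sum(err_ols)


def white_noise_design(rng, n_channels=3, n_trials=6, n_frames=500):
    mats = [rng.standard_normal((n_channels, n_frames))
            for _ in range(n_trials)]
    fams = ["gammatone", "acoustic_edges", "phoneme_onset"][:n_channels]
    pset = st.build_predictor_set(mats, [f"c{i}" for i in range(n_channels)],
                                  fams, 100.0)
    pset = st.normalize(pset)
    dummy = SourceResponse(np.zeros((1, pset.n_samples)), 100.0,
                           list(pset.trials))
    pset, resp = st.pad_trials(pset, dummy)
    return st.lag_expand(pset), resp


def test_kernel_recovery_under_noise():
    """Known gamma-shaped kernels on three feature channels, SNR 0.5: the
    time-domain kernel correlates with the truth at >= 0.8 on average over
    20 seeded simulations."""
    from speechtrf.predictors import hamming_basis
    w = hamming_basis()

    def expand(k):
        return np.apply_along_axis(
            lambda v: np.convolve(v, w, mode="same"), -1, k)

    corrs = []
    for sim in range(20):
        r = np.random.default_rng(1000 + sim)
        design, resp = white_noise_design(r)
        lags = design.lags_ms
        truth = np.stack([st.gamma_kernel(lags, 80, 0.3),
                          st.gamma_kernel(lags, 100, 0.4),
                          st.gamma_kernel(lags, 400, 0.5, shape=4.0)])
        y = design.X @ truth.reshape(-1)
        y = y + r.standard_normal(len(y)) * y.std() / np.sqrt(0.5)
        resp.data[0] = y
        model = st.fit_trf(design, resp, keep_logs=False)
        corrs.append(np.corrcoef(model.time_kernel[0].reshape(-1),
                                 expand(truth).reshape(-1))[0, 1])
    assert np.mean(corrs) >= 0.8


# --- predict and accuracy -----------------------------------------------------

def _kernel_model(design, kern):
    from speechtrf.boosting import TRFModel
    return TRFModel(kern, np.zeros(kern.shape[:2]), design.lags_ms,
                    design.channel_names, design.channel_families,
                    [[0]], [0], 0.005)


def test_predict_zero_kernels_zero_output(rng):
    design, _ = smooth_noise_design(rng, n_trials=1, n_frames=100)
    model = _kernel_model(design, np.zeros((1, 1, 3, design.n_lags)))
    assert not st.predict(model, design).any()


def test_predict_matches_double_loop_oracle(rng):
    """Forward prediction equals the brute-force double sum over channels
    and lags on a 300-frame signal."""
    design, _ = smooth_noise_design(rng, n_channels=2, n_trials=1,
                                    n_frames=300)
    K = design.n_lags
    kern = 0.1 * rng.standard_normal((1, 1, 2, K))
    model = _kernel_model(design, kern)
    got = st.predict(model, design)[0]
    expected = np.zeros(design.X.shape[0])
    for c in range(2):
        for k in range(K):
            expected += kern[0, 0, c, k] * design.X[:, c * K + k]
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_single_unit_coefficient_predicts_basis_regressor(rng):
    design, _ = smooth_noise_design(rng, n_channels=2, n_trials=1,
                                    n_frames=120)
    K = design.n_lags
    kern = np.zeros((1, 1, 2, K))
    k0 = int(np.flatnonzero(design.lags_ms == 0.0)[0])
    kern[0, 0, 1, k0] = 1.0
    model = _kernel_model(design, kern)
    np.testing.assert_allclose(st.predict(model, design)[0],
                               design.X[:, K + k0], atol=1e-12)


def test_variance_explained_examples(rng):
    y = rng.standard_normal(500)
    assert st.variance_explained(y, y) == 1.0
    yc = y - y.mean()
    assert st.variance_explained(np.zeros(500), yc) == pytest.approx(0.0)
    # actual = signal + equal-variance noise, predicted = signal -> 0.5
    n = 10_000
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    got = st.variance_explained(x, x + e)
    assert got == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError, match="zero-variance"):
        st.variance_explained(np.zeros(5), np.ones(5))


# --- invariants ---------------------------------------------------------------

def test_training_error_nonincreasing_and_early_stopping(rng):
    design, resp = smooth_noise_design(rng, n_trials=5, n_frames=200)
    y, _ = realizable_response(design, rng)
    resp.data[0] = y + 0.3 * rng.standard_normal(len(y))
    model = st.fit_trf(design, resp)
    for fold_logs in model.logs:
        for log in fold_logs:
            assert np.all(np.diff(log.train_err) <= 1e-9)
            assert log.best_iter >= 1
            # returned iteration is the minimum of the validation trajectory
            assert log.val_err[log.best_iter - 1] == log.val_err.min()


def test_fold_hygiene():
    from speechtrf.boosting import _fold_blocks
    blocks = _fold_blocks(11, 5)
    flat = [t for b in blocks for t in b]
    assert sorted(flat) == list(range(11))
    # validation rotates among non-test blocks
    for f in range(5):
        val = (f + 1) % 5
        assert val != f


def test_fit_is_deterministic(rng):
    design, resp = smooth_noise_design(rng, n_trials=5, n_frames=200)
    y, _ = realizable_response(design, rng)
    resp.data[0] = y + 0.5 * rng.standard_normal(len(y))
    m1 = st.fit_trf(design, resp)
    m2 = st.fit_trf(design, resp)
    assert np.array_equal(m1.kernels, m2.kernels)
    for a, b in zip(m1.logs, m2.logs):
        for la, lb in zip(a, b):
            assert np.array_equal(la.train_err, lb.train_err)
            assert np.array_equal(la.val_err, lb.val_err)


def test_too_few_trials_fatal(rng):
    design, resp = smooth_noise_design(rng, n_trials=3)
    with pytest.raises(ValueError, match="folds"):
        st.fit_trf(design, resp, folds=5)


def test_nonfinite_response_fatal(rng):
    design, resp = smooth_noise_design(rng, n_trials=5, n_frames=100)
    resp.data[0, 10] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        st.fit_trf(design, resp)


# --- ablation ----------------------------------------------------------------

def test_ablation_attributes_only_generative_families(rng):
    """Response generated from the acoustic family only: ablating the phoneme
    family changes nothing (|mean| <= 0.01); ablating the generative acoustic
    family hurts in >= 95% of simulations (SNR 1)."""
    phoneme_imp, acoustic_imp = [], []
    for sim in range(20):
        r = np.random.default_rng(2000 + sim)
        design, resp = smooth_noise_design(
            r, n_channels=4, n_trials=5, n_frames=300,
            families=["gammatone", "gammatone", "phoneme_surprisal",
                      "phoneme_entropy"])
        lags = design.lags_ms
        truth = np.zeros((4, design.n_lags))
        truth[0] = st.gamma_kernel(lags, 80, 0.4)
        truth[1] = st.gamma_kernel(lags, 120, 0.3)
        y = design.X @ truth.reshape(-1)
        y = y + r.standard_normal(len(y)) * y.std()   # SNR 1
        resp.data[0] = y
        full = st.fit_trf(design, resp, keep_logs=False)
        phoneme_imp.append(
            st.ablate(design, resp, "phoneme", full).improvement[0])
        acoustic_imp.append(
            st.ablate(design, resp, "gammatone", full).improvement[0])
    assert abs(np.mean(phoneme_imp)) <= 0.01
    assert np.mean(np.array(acoustic_imp) > 0) >= 0.95


def test_ablating_missing_family_fatal(rng):
    design, resp = smooth_noise_design(rng, n_trials=5, n_frames=100)
    resp.data[0] = rng.standard_normal(resp.data.shape[1])
    model = st.fit_trf(design, resp, keep_logs=False)
    with pytest.raises(ValueError, match="word"):
        st.ablate(design, resp, "word", model)


def test_ablation_improvement_is_full_minus_reduced():
    res = st.AblationResult("phoneme", np.array([0.4, 0.3]),
                            np.array([0.25, 0.31]))
    np.testing.assert_allclose(res.improvement, [0.15, -0.01])
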