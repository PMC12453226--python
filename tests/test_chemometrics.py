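import numpy as np
import pytest

from digestmark.chemometrics import (
    CalibrationConfig,
    classify_r2,
    classify_rpd,
    calibrate_trait,
    fit_mpls,
    fit_pls1,
    fit_stats,
    gh_outliers,
    gh_scores,
    kfold_cv,
    matched_split,
    t_outlier_iterations,
)
from digestmark.synthetic import (
    CohortConfig,
    SpectraConfig,
    make_synthetic_trait,
    simulate_cohort,
    simulate_spectra,
)


def _linear_data(rng, n=25, p=8, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def test_pls1_saturates_to_ols(rng):
    """At full rank with n > p, PLS1 predictions equal ordinary least squares."""
    X, y = _linear_data(rng, n=30, p=6, noise=0.3)
    model = fit_pls1(X, y, k=6)
    A = np.column_stack([X, np.ones(30)])
    coef = np.linalg.lstsq(A, y, rcond=None)[0]
    np.testing.assert_allclose(model.predict(X), A @ coef, atol=1e-8)


def test_pls1_single_factor_weight_is_covariance_direction(rng):
    X = rng.normal(size=(40, 5))
    X[:, 3] *= 5.0
    y = X[:, 3] + 0.01 * rng.normal(size=40)
    model = fit_pls1(X, y, k=1)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    cov = Xc.T @ yc
    w = model.weights[0]
    np.testing.assert_allclose(w, cov / np.linalg.norm(cov), atol=1e-12)


def test_pls1_permutation_invariance(rng):
    X, y = _linear_data(rng, n=20, p=5, noise=0.2)
    model = fit_pls1(X, y, k=3)
    perm = rng.permutation(20)
    model_p = fit_pls1(X[perm], y[perm], k=3)
    np.testing.assert_allclose(model.regression_vector(),
                               model_p.regression_vector(), atol=1e-10)


def test_pls1_matches_sklearn_oracle(rng):
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X, y = _linear_data(rng, n=30, p=10, noise=0.5)
    for k in (1, 2, 4):
        ours = fit_pls1(X, y, k)
        ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.predict(X), ref.predict(X).ravel(), atol=1e-8
        )


def test_mpls_first_factor_equals_pls1(rng):
    """No scaling has been applied before the first factor, so the k=1
    modified and plain fits coincide exactly."""
    X, y = _linear_data(rng, n=25, p=6, noise=0.4)
    np.testing.assert_allclose(
        fit_mpls(X, y, 1).predict(X), fit_pls1(X, y, 1).predict(X), atol=1e-12
    )


def test_mpls_stores_exact_scalings(rng):
    """Prediction on the training set reproduces the internally fitted values:
    the per-factor residual standardisations are fully recorded."""
    X, y = _linear_data(rng, n=30, p=8, noise=0.5)
    model = fit_mpls(X, y, 4)
    resid = y - model.predict(X)
    sec_direct = np.sqrt(resid @ resid / (30 - 4 - 1))
    assert model.sec == pytest.approx(sec_direct, rel=1e-10)
    assert model.x_scales.shape == (4, 8)
    assert not np.allclose(model.x_scales, 1.0)  # scaling actually happened


def test_mpls_recovers_low_rank_signal(rng):
    """Noiseless y spanned by 3 latent spectral directions: k = 3 fits it."""
    n, p = 60, 30
    scores = rng.normal(size=(n, 3))
    load = rng.normal(size=(3, p))
    X = scores @ load
    y = scores @ np.array([1.0, -2.0, 0.5])
    model = fit_mpls(X, y, 3)
    r2 = np.corrcoef(model.predict(X), y)[0, 1] ** 2
    assert r2 >= 0.999


def test_sec_non_increasing_in_k(rng):
    X, y = _linear_data(rng, n=40, p=10, noise=1.0)
    rmse = []
    for k in range(1, 8):
        model = fit_mpls(X, y, k)
        resid = y - model.predict(X)
        rmse.append(float(np.sqrt(resid @ resid)))
    assert all(b <= a + 1e-9 for a, b in zip(rmse, rmse[1:]))


def test_pls_zero_variance_y_errors(rng):
    X = rng.normal(size=(20, 5))
    with pytest.raises(ValueError, match="variance"):
        fit_pls1(X, np.full(20, 3.0), 2)


# ---------------------------------------------------------------------------
# outliers


def test_gh_mean_spectrum_is_central(rng):
    X = rng.normal(size=(100, 40))
    X[0] = X[1:].mean(axis=0)
    gh, _ = gh_scores(X, k=5)
    assert gh[0] < 0.2


def test_gh_duplicated_sample_identical(rng):
    X = rng.normal(size=(50, 30))
    X[7] = X[3]
    gh, _ = gh_scores(X, k=5)
    assert gh[7] == pytest.approx(gh[3], rel=1e-10)


def test_gh_flags_scaled_outlier_and_matches_direct_mahalanobis(rng):
    X = rng.normal(size=(100, 40))
    X[13] *= 10.0
    keep, report = gh_outliers(X, k=5, threshold=3.0)
    assert 13 in set(report["index"])
    # direct Mahalanobis oracle in the same score space
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    T = U[:, :5] * S[:5]
    cov = np.diag(S[:5] ** 2 / (99))
    m2 = np.einsum("ij,jk,ik->i", T, np.linalg.inv(cov), T)
    np.testing.assert_allclose(gh_scores(X, 5)[0], m2 / 5, rtol=1e-8)


def test_gh_clean_data_mostly_kept(rng):
    X = rng.normal(size=(100, 40))
    keep, report = gh_outliers(X, k=5, threshold=3.0)
    assert len(report) <= 3


def test_t_culling_clean_noiseless_data(rng):
    X = rng.normal(size=(40, 6))
    y = X @ rng.normal(size=6)  # exactly linear
    kept, report, iters = t_outlier_iterations(X, y, n_factors=6)
    assert len(report) == 0
    assert iters == 1
    assert kept.size == 40


def test_t_culling_removes_corrupted_sample(rng):
    X = rng.normal(size=(60, 6))
    y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=60)
    y[11] += 10 * y.std()
    kept, report, iters = t_outlier_iterations(X, y, n_factors=6)
    assert 11 not in set(kept)
    assert iters <= 3
    assert (report["iteration"] <= 3).all()


# ---------------------------------------------------------------------------
# cross-validation and splitting


def test_kfold_each_sample_predicted_once(rng):
    X, y = _linear_data(rng, n=45, p=8, noise=0.5)
    cv = kfold_cv(X, y, max_lf=5, k_folds=5, seed=1)
    assert np.all(np.isfinite(cv.predictions))
    assert cv.predictions.shape == (45,)


def test_kfold_noiseless_low_rank_selects_true_complexity(rng):
    n, p = 60, 20
    scores = rng.normal(size=(n, 3))
    X = scores @ rng.normal(size=(3, p))
    y = scores @ np.array([2.0, -1.0, 0.7])
    cv = kfold_cv(X, y, max_lf=8, k_folds=5, seed=0)
    assert cv.chosen_lf <= 4
    assert cv.r2_crv >= 0.99


def test_kfold_seed_policy_reproducible(rng):
    """Fold assignment is fully determined by the seed, so repeated runs on
    one dataset (and on its duplicated copy) reproduce their own choice of
    complexity exactly, and both find the 3-factor structure."""
    n, p = 30, 12
    scores = rng.normal(size=(n, 3))
    X = scores @ rng.normal(size=(3, p))
    y = scores @ np.array([1.0, 0.5, -0.8]) + 0.05 * rng.normal(size=n)
    cv1 = kfold_cv(X, y, max_lf=6, k_folds=5, seed=2)
    assert cv1.chosen_lf == kfold_cv(X, y, max_lf=6, k_folds=5, seed=2).chosen_lf
    assert cv1.chosen_lf == 3 and cv1.r2_crv >= 0.99
    X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
    cv2 = kfold_cv(X2, y2, max_lf=6, k_folds=5, seed=2)
    assert cv2.chosen_lf == kfold_cv(X2, y2, max_lf=6, k_folds=5, seed=2).chosen_lf
    assert cv2.chosen_lf >= 3 and cv2.r2_crv >= 0.99


def test_kfold_ties_break_to_smaller_lf():
    rmse = np.array([1.0, 0.5, 0.5, 0.7])
    assert int(np.argmin(rmse)) + 1 == 2  # argmin picks the first optimum


def test_matched_split_sizes_and_quality(rng):
    y = rng.normal(size=180)
    cal, val = matched_split(y, fraction=0.75, n_candidates=100, seed=5)
    assert cal.size == 135 and val.size == 45
    assert np.intersect1d(cal, val).size == 0
    sd = y.std(ddof=1)
    chosen_gap = abs(y[cal].mean() - y[val].mean()) / sd + \
        abs(y[cal].std(ddof=1) - y[val].std(ddof=1)) / sd
    # argmin property: the chosen split beats the median random candidate
    gaps = []
    rng2 = np.random.default_rng(99)
    for _ in range(100):
        perm = rng2.permutation(180)
        c, v = perm[:135], perm[135:]
        gaps.append(abs(y[c].mean() - y[v].mean()) / sd
                    + abs(y[c].std(ddof=1) - y[v].std(ddof=1)) / sd)
    assert chosen_gap <= np.median(gaps)
    # reproducibility
    cal2, val2 = matched_split(y, fraction=0.75, n_candidates=100, seed=5)
    np.testing.assert_array_equal(cal, cal2)


# ---------------------------------------------------------------------------
# fit statistics and bands


def test_fit_stats_perfect_prediction():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    s = fit_stats(y, y)
    assert s["bias"] == 0 and s["se"] == 0 and s["r2"] == pytest.approx(1.0)
    assert s["rpd"] == float("inf") and s["se_zero"]


def test_fit_stats_hand_computed_example():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    p = np.array([1.1, 1.9, 3.2, 3.8])
    s = fit_stats(y, p)
    assert s["bias"] == pytest.approx(0.0, abs=1e-12)
    # hand arithmetic: e = [.1,-.1,.2,-.2] -> SE = sqrt(0.1/3)
    assert s["se"] == pytest.approx(np.sqrt(0.1 / 3), abs=1e-12)
    # r^2 = (sum yp)^2/(sum y^2 sum p^2) on centred values = 4.7^2/(5*4.5)
    assert s["r2"] == pytest.approx(4.7**2 / (5.0 * 4.5), abs=1e-12)
    # RPD = sd(y)/SE = sqrt(5/3)/sqrt(0.1/3) = sqrt(50) = 7.0711
    assert s["rpd"] == pytest.approx(np.sqrt(50.0), abs=1e-10)


def test_fit_stats_constant_shift_moves_bias_only():
    rng = np.random.default_rng(1)
    y = rng.normal(size=30)
    p = y + 0.1 * rng.normal(size=30)
    s0 = fit_stats(y, p)
    s1 = fit_stats(y, p + 2.5)
    assert s1["bias"] == pytest.approx(s0["bias"] + 2.5, abs=1e-12)
    assert s1["se"] == pytest.approx(s0["se"], abs=1e-12)


@pytest.mark.parametrize(
    "r2,band",
    [(0.63, "inadequate"), (0.66, "approximate"), (0.81, "approximate"),
     (0.82, "good"), (0.90, "good"), (0.95, "excellent")],
)
def test_r2_bands(r2, band):
    assert classify_r2(r2) == band


@pytest.mark.parametrize(
    "rpd,band",
    [(0.45, "very poor"), (1.2, "poor"), (1.45, "fair"), (1.56, "fair"),
     (1.9, "good"), (2.2, "very good"), (2.6, "excellent")],
)
def test_rpd_bands(rpd, band):
    assert classify_rpd(rpd) == band


# ---------------------------------------------------------------------------
# full protocol


@pytest.fixture(scope="module")
def calibration_setup():
    recs = simulate_cohort(CohortConfig(n_sheep=10, n_goats=4, seed=21))  # 210
    cfg = SpectraConfig(seed=8)
    spectra = simulate_spectra(recs, cfg)
    X = np.stack([s.absorbance for s in spectra])
    return recs, cfg, X, cfg.wavelengths()


def test_calibrate_trait_recovers_signal(calibration_setup):
    recs, cfg, X, wl = calibration_setup
    y, target = make_synthetic_trait(recs, cfg, theoretical_r2=0.9, seed=4)
    res = calibrate_trait(X, wl, y, config=CalibrationConfig(seed=13))
    assert res.stats.r2_exv == pytest.approx(target, abs=0.12)
    assert res.stats.n_exv == round(0.25 * (210 - len(res.outliers.spectral)))


def test_calibrate_trait_shuffled_null(calibration_setup):
    recs, cfg, X, wl = calibration_setup
    y, _ = make_synthetic_trait(recs, cfg, theoretical_r2=0.9, seed=4)
    y_shuf = np.random.default_rng(0).permutation(y)
    res = calibrate_trait(X, wl, y_shuf, config=CalibrationConfig(seed=13))
    assert res.stats.r2_exv <= 0.15


def test_calibrate_trait_deterministic(calibration_setup):
    recs, cfg, X, wl = calibration_setup
    y, _ = make_synthetic_trait(recs, cfg, theoretical_r2=0.6, seed=5)
    a = calibrate_trait(X, wl, y, config=CalibrationConfig(seed=3)).stats
    b = calibrate_trait(X, wl, y, config=CalibrationConfig(seed=3)).stats
    assert a == b


def test_validation_set_untouched(calibration_setup):
    """Validation hygiene: the validation rows of X and y are bit-identical
    before and after calibration (nothing mutates them), and the validation
    indices never enter the calibration fit."""
    recs, cfg, X, wl = calibration_setup
    y, _ = make_synthetic_trait(recs, cfg, theoretical_r2=0.8, seed=6)
    X_before, y_before = X.copy(), y.copy()
    res = calibrate_trait(X, wl, y, config=CalibrationConfig(seed=7))
    np.testing.assert_array_equal(X, X_before)
    np.testing.assert_array_equal(y, y_before)
    assert res.stats.n_crv <= round(0.75 * X.shape[0])


def test_external_r2_monotone_in_signal_fraction():
    """Parameter recovery: external R2 increases with the generator's
    configured signal fraction."""
    recs = simulate_cohort(CohortConfig(n_sheep=10, n_goats=4, seed=33))
    cfg = SpectraConfig(seed=17)
    X = np.stack([s.absorbance for s in simulate_spectra(recs, cfg)])
    wl = cfg.wavelengths()
    r2s = []
    for frac in (0.3, 0.6, 0.9):
        y, _ = make_synthetic_trait(recs, cfg, theoretical_r2=frac, seed=9)
        res = calibrate_trait(X, wl, y, config=CalibrationConfig(seed=19))
        r2s.append(res.stats.r2_exv)
    assert r2s[0] < r2s[1] < r2s[2]
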