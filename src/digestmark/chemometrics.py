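"""Modified-PLS calibration, outlier culling, validation and fit statistics.

The calibration engine mirrors the WinISI-style protocol used for faecal NIR
work: spectral outlier removal on Global H (Mahalanobis distance in latent
score space, normalised by factor count), a mean/SD-matched 75/25 external
split, per-pretreatment T-statistic culling of chemistry outliers, latent
factor selection by 5-fold cross-validation, model selection on the
cross-validated R², and external validation statistics (SE, R², bias, slope,
RPD with conventional interpretation bands).

``fit_mpls`` implements the Shenk–Westerhaus modification of PLS1: after
each extracted factor the X-residual columns and the y-residuals are divided
by their standard deviations before the next factor.  All scale factors are
stored, so prediction reproduces the training fit exactly; with unit scale
factors the algorithm reduces to standard NIPALS PLS1 (``fit_pls1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pretreat import PretreatmentSpec, apply_pretreatment, default_grid

__all__ = [
    "CalibrationModel",
    "CalibrationConfig",
    "FitStats",
    "OutlierReport",
    "fit_pls1",
    "fit_mpls",
    "gh_outliers",
    "t_outlier_iterations",
    "kfold_cv",
    "matched_split",
    "fit_stats",
    "classify_r2",
    "classify_rpd",
    "calibrate_trait",
]


@dataclass
class CalibrationModel:
    """A fitted (m)PLS1 calibration on treated, centred spectra."""

    pretreatment: PretreatmentSpec
    msc_reference: np.ndarray | None
    wavelengths: np.ndarray  # treated grid
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (k, p) factor weight vectors
    loadings: np.ndarray  # (k, p) X loadings
    q: np.ndarray  # (k,) y loadings
    x_scales: np.ndarray  # (k, p) column divisors applied after each factor
    y_scales: np.ndarray  # (k,) y divisors applied after each factor
    n_factors: int
    sec: float  # standard error of calibration (n - k - 1 dof)
    n_train: int
    modified: bool = True

    def predict_components(self, x_treated) -> np.ndarray:
        """Cumulative predictions after 1..k factors; shape (n, k)."""
        X = np.atleast_2d(np.asarray(x_treated, dtype=float)) - self.x_mean
        n = X.shape[0]
        out = np.empty((n, self.n_factors))
        acc = np.full(n, self.y_mean)
        gain = 1.0
        for j in range(self.n_factors):
            t = X @ self.weights[j]
            acc = acc + gain * self.q[j] * t
            out[:, j] = acc
            X = (X - np.outer(t, self.loadings[j])) / self.x_scales[j]
            gain *= self.y_scales[j]
        return out

    def predict(self, x_treated, n_factors: int | None = None) -> np.ndarray:
        k = n_factors or self.n_factors
        return self.predict_components(x_treated)[:, k - 1]

    def regression_vector(self) -> np.ndarray:
        """b such that prediction = y_mean + (x - x_mean) @ b."""
        p = self.x_mean.size
        preds = self.predict(np.eye(p) + self.x_mean)
        return preds - self.y_mean

    def truncated(self, k: int) -> "CalibrationModel":
        """The same model cut to its first ``k`` factors."""
        return replace(
            self,
            weights=self.weights[:k],
            loadings=self.loadings[:k],
            q=self.q[:k],
            x_scales=self.x_scales[:k],
            y_scales=self.y_scales[:k],
            n_factors=k,
        )


def _fit_nipals(
    X,
    y,
    k: int,
    modified: bool,
    pretreatment: PretreatmentSpec | None = None,
    wavelengths=None,
    msc_reference=None,
) -> CalibrationModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 samples (n={n}, k={k})")
    if p < k:
        raise ValueError(f"need at least k={k} wavelengths (p={p})")
    if float(np.var(y)) == 0.0:
        raise ValueError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean

    W = np.zeros((k, p))
    P = np.zeros((k, p))
    Q = np.zeros(k)
    XS = np.ones((k, p))
    YS = np.ones(k)
    actual_k = 0
    for j in range(k):
        w = Xr.T @ yr
        norm = float(np.linalg.norm(w))
        if norm < 1e-14:
            break  # residual information exhausted
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        P[j] = Xr.T @ t / tt
        Q[j] = float(yr @ t / tt)
        W[j] = w
        Xr = Xr - np.outer(t, P[j])
        yr = yr - Q[j] * t
        if modified:
            sx = Xr.std(axis=0)
            sx[sx == 0.0] = 1.0  # zero-sd column: scale clamped to 1
            sy = float(yr.std())
            if sy == 0.0:
                sy = 1.0
            Xr /= sx
            yr /= sy
            XS[j] = sx
            YS[j] = sy
        actual_k = j + 1
    if actual_k == 0:
        raise ValueError("no usable latent factor (X carries no covariance with y)")

    model = CalibrationModel(
        pretreatment=pretreatment or PretreatmentSpec(),
        msc_reference=msc_reference,
        wavelengths=np.asarray(wavelengths, dtype=float)
        if wavelengths is not None else np.arange(p, dtype=float),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:actual_k],
        loadings=P[:actual_k],
        q=Q[:actual_k],
        x_scales=XS[:actual_k],
        y_scales=YS[:actual_k],
        n_factors=actual_k,
        sec=np.nan,
        n_train=n,
        modified=modified,
    )
    resid = y - model.predict(X)
    dof = max(n - actual_k - 1, 1)
    model.sec = float(np.sqrt(resid @ resid / dof))
    return model


def fit_pls1(X_treated, y, k: int, **kw) -> CalibrationModel:
    """Standard NIPALS PLS1 on column-centred X and centred y."""
    return _fit_nipals(X_treated, y, k, modified=False, **kw)


def fit_mpls(X_treated, y, k: int, **kw) -> CalibrationModel:
    """Modified PLS1 with per-factor standardisation of the residuals."""
    return _fit_nipals(X_treated, y, k, modified=True, **kw)


# ---------------------------------------------------------------------------
# Outlier culling


@dataclass
class OutlierReport:
    """Samples removed during calibration and why."""

    spectral: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["index", "gh"])
    )
    chemical: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["iteration", "index", "t"])
    )
    t_iterations: int = 0


def gh_scores(X, k: int | None = None) -> tuple[np.ndarray, int]:
    """Global H per sample: squared Mahalanobis distance in the score space of
    a k-factor principal decomposition of centred X, divided by k."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size and S[0] > 0 else 0
    if rank == 0:
        return np.zeros(n), 0
    k_req = k if k is not None else 10
    if k_req > rank:
        warnings.warn(
            f"score covariance singular beyond {rank} factors; reducing k "
            f"from {k_req} to {rank}"
        )
    k_eff = min(k_req, rank)
    scores = U[:, :k_eff] * S[:k_eff]
    var = S[:k_eff] ** 2 / (n - 1)
    gh = (scores**2 / var).sum(axis=1) / k_eff
    return gh, k_eff


def gh_outliers(X, k: int | None = None, threshold: float = 3.0):
    """Flag spectral outliers with Global H above ``threshold``.

    Returns ``(keep_index, report_frame)`` where the report lists the
    flagged samples with their GH values.
    """
    gh, _ = gh_scores(X, k)
    flagged = np.flatnonzero(gh > threshold)
    keep = np.flatnonzero(gh <= threshold)
    report = pd.DataFrame({"index": flagged, "gh": gh[flagged]})
    return keep, report


def t_outlier_iterations(
    X,
    y,
    n_factors: int,
    max_iter: int = 3,
    t_threshold: float = 3.0,
    modified: bool = True,
):
    """Iterative chemistry-outlier culling on the T statistic.

    Fit, compute ``T_i = |y_i - yhat_i| / SEC``, drop samples with
    ``T > t_threshold``, refit; at most ``max_iter`` passes, stopping early
    when nothing is dropped.  Returns ``(kept_indices, report_frame,
    iterations_run)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for T-statistic culling")
    kept = np.arange(X.shape[0])
    removed_rows = []
    iterations = 0
    fitter = fit_mpls if modified else fit_pls1
    for it in range(max_iter):
        k = min(n_factors, kept.size - 2)
        model = fitter(X[kept], y[kept], k)
        resid = np.abs(y[kept] - model.predict(X[kept]))
        if model.sec == 0.0:
            iterations = it + 1
            break
        t = resid / model.sec
        drop = t > t_threshold
        iterations = it + 1
        if not drop.any():
            break
        for idx, tv in zip(kept[drop], t[drop]):
            removed_rows.append({"iteration": it + 1, "index": int(idx),
                                 "t": float(tv)})
        kept = kept[~drop]
        if kept.size < 3:
            raise ValueError("T-statistic culling removed nearly all samples")
    report = pd.DataFrame(removed_rows, columns=["iteration", "index", "t"])
    return kept, report, iterations


# ---------------------------------------------------------------------------
# Cross-validation, splitting, statistics


@dataclass
class CVResult:
    predictions: np.ndarray  # (n,) at the chosen LF
    chosen_lf: int
    se_crv: float
    r2_crv: float
    rmsecv: np.ndarray  # per candidate LF


def kfold_cv(
    X,
    y,
    max_lf: int,
    k_folds: int = 5,
    seed: int = 0,
    modified: bool = True,
) -> CVResult:
    """Choose the latent factor count minimising RMSECV over random folds.

    Every sample is predicted exactly once from a model fitted without it;
    ties in RMSECV break toward fewer factors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if max_lf < 1:
        raise ValueError("max_lf must be >= 1")
    if n < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} samples for {k_folds}-fold CV")
    if max_lf >= n - n // k_folds:
        raise ValueError("max_lf too large for the training folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    preds = np.full((n, max_lf), np.nan)
    fitter = fit_mpls if modified else fit_pls1
    for fold in folds:
        train = np.setdiff1d(order, fold, assume_unique=False)
        model = fitter(X[train], y[train], max_lf)
        comp = model.predict_components(X[fold])
        k_eff = comp.shape[1]
        preds[fold, :k_eff] = comp
        if k_eff < max_lf:  # rank-deficient fold: later LFs equal the last
            preds[fold, k_eff:] = comp[:, [-1]]
    rmsecv = np.sqrt(((preds - y[:, None]) ** 2).mean(axis=0))
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest) LF
    p = preds[:, chosen - 1]
    se_crv = float(np.sqrt(((p - y) ** 2).sum() / (n - 1)))
    r2_crv = float(np.corrcoef(p, y)[0, 1] ** 2) if np.var(p) > 0 else 0.0
    return CVResult(p, chosen, se_crv, r2_crv, rmsecv)


def matched_split(
    y,
    fraction: float = 0.75,
    n_candidates: int = 100,
    seed: int = 0,
):
    """Random calibration/validation split with matched mean and SD.

    Among ``n_candidates`` seeded random splits, returns the one minimising
    ``|mean_cal - mean_val|/sd_all + |sd_cal - sd_val|/sd_all``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    n_cal = int(round(fraction * n))
    n_cal = min(max(n_cal, 2), n - 2)
    rng = np.random.default_rng(seed)
    sd_all = float(y.std(ddof=1))
    best, best_score = None, np.inf
    for _ in range(n_candidates):
        perm = rng.permutation(n)
        cal, val = perm[:n_cal], perm[n_cal:]
        if sd_all == 0.0:
            best = (np.sort(cal), np.sort(val))
            warnings.warn("degenerate y (sd 0): plain random split used")
            break
        score = (
            abs(y[cal].mean() - y[val].mean()) / sd_all
            + abs(y[cal].std(ddof=1) - y[val].std(ddof=1)) / sd_all
        )
        if score < best_score:
            best_score = score
            best = (np.sort(cal), np.sort(val))
    return best


@dataclass
class FitStats:
    """Calibration fitting statistics in reporting column order."""

    trait: str
    n_crv: int
    lf: int
    se_crv: float
    r2_crv: float
    n_exv: int
    se_exv: float
    r2_exv: float
    bias: float
    slope: float
    rpd_exv: float
    r2_band: str
    rpd_band: str
    pretreatment: str = ""

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "n_CrV": self.n_crv,
            "LF": self.lf,
            "SE_CrV": self.se_crv,
            "R2_CrV": self.r2_crv,
            "n_ExV": self.n_exv,
            "SE_ExV": self.se_exv,
            "R2_ExV": self.r2_exv,
            "BIAS": self.bias,
            "SLOPE": self.slope,
            "RPD_ExV": self.rpd_exv,
            "R2_band": self.r2_band,
            "RPD_band": self.rpd_band,
            "pretreatment": self.pretreatment,
        }


def fit_stats(y_ref, y_pred, sd_pool: float | None = None) -> dict:
    """External-validation statistics.

    bias = mean(yhat - y); SE is the bias-corrected standard error of
    prediction (n - 1 dof); R² the squared Pearson correlation; slope the
    OLS slope of reference on predicted; RPD = sd_pool / SE with the
    validation-set reference SD as the default pool.
    """
    y = np.asarray(y_ref, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for fit statistics")
    e = p - y
    bias = float(e.mean())
    se = float(np.sqrt(((e - bias) ** 2).sum() / (n - 1)))
    r2 = float(np.corrcoef(y, p)[0, 1] ** 2) if np.var(p) > 0 and np.var(y) > 0 else 0.0
    slope = float(np.polyfit(p, y, 1)[0]) if np.var(p) > 0 else np.nan
    pool = float(sd_pool) if sd_pool is not None else float(y.std(ddof=1))
    rpd = pool / se if se > 0 else float("inf")
    return {"n": n, "bias": bias, "se": se, "r2": r2, "slope": slope, "rpd": rpd,
            "se_zero": se == 0.0}


def classify_r2(r2: float) -> str:
    """Interpretation band for an external-validation R²."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("R2 must be in [0, 1]")
    if r2 < 0.66:
        return "inadequate"
    if r2 < 0.82:
        return "approximate"
    if r2 <= 0.90:
        return "good"
    return "excellent"


def classify_rpd(rpd: float) -> str:
    """Interpretation band for the ratio of performance to deviation."""
    if rpd <= 0:
        raise ValueError("RPD must be > 0")
    if rpd < 1.0:
        return "very poor"
    if rpd < 1.4:
        return "poor"
    if rpd < 1.8:
        return "fair"
    if rpd < 2.0:
        return "good"
    if rpd <= 2.5:
        return "very good"
    return "excellent"


# ---------------------------------------------------------------------------
# Full calibration protocol


@dataclass
class CalibrationConfig:
    max_lf: int = 10
    k_folds: int = 5
    gh_threshold: float = 3.0
    gh_factors: int = 10
    t_threshold: float = 3.0
    t_max_iter: int = 3
    split_fraction: float = 0.75
    n_split_candidates: int = 100
    modified: bool = True  # mPLS; False falls back to plain PLS1
    rpd_pool: str = "validation"  # or "all": pool for the RPD denominator
    seed: int = 0


@dataclass
class CalibrationResult:
    model: CalibrationModel
    stats: FitStats
    outliers: OutlierReport
    grid_results: pd.DataFrame  # per-cell CV performance


def calibrate_trait(
    spectra_matrix,
    wavelengths,
    y,
    grid: list[PretreatmentSpec] | None = None,
    config: CalibrationConfig | None = None,
    trait: str = "trait",
) -> CalibrationResult:
    """Run the full calibration protocol for one trait.

    Order: Global-H spectral culling -> matched 75/25 split -> for every
    pretreatment cell: T-statistic culling and LF selection by k-fold CV on
    the calibration set -> select the cell with the highest cross-validated
    R² -> external validation on the untouched validation set.  Validation
    samples never influence centring, scaling, outlier culling, LF choice or
    pretreatment choice.
    """
    X = np.asarray(spectra_matrix, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(y, dtype=float)
    config = config or CalibrationConfig()
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty pretreatment grid")
    if X.shape[0] < 12:
        raise ValueError("need at least 12 samples to calibrate")
    if X.shape[0] < 40:
        warnings.warn("fewer than 40 samples: calibration will be unstable")

    keep, spectral_report = gh_outliers(X, config.gh_factors, config.gh_threshold)
    X, y = X[keep], y[keep]

    cal_idx, val_idx = matched_split(
        y, config.split_fraction, config.n_split_candidates, config.seed
    )
    X_cal, y_cal = X[cal_idx], y[cal_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    cells = []
    best = None
    for cell_no, spec in enumerate(grid):
        Xt, wlt, ref = apply_pretreatment(X_cal, wl, spec)
        try:
            kept, chem_report, iters = t_outlier_iterations(
                Xt, y_cal, config.max_lf, config.t_max_iter, config.t_threshold,
                config.modified,
            )
            max_lf = min(config.max_lf,
                         kept.size - kept.size // config.k_folds - 1,
                         Xt.shape[1])
            cv = kfold_cv(Xt[kept], y_cal[kept], max_lf, config.k_folds,
                          config.seed, config.modified)
        except ValueError as err:
            cells.append({"pretreatment": spec.label, "lf": 0, "r2_crv": np.nan,
                          "se_crv": np.nan, "n_crv": 0, "error": str(err)})
            continue
        cells.append({"pretreatment": spec.label, "lf": cv.chosen_lf,
                      "r2_crv": cv.r2_crv, "se_crv": cv.se_crv,
                      "n_crv": int(kept.size), "error": ""})
        if best is None or cv.r2_crv > best["cv"].r2_crv:
            best = {"spec": spec, "ref": ref, "kept": kept, "cv": cv,
                    "chem_report": chem_report, "iters": iters, "wlt": wlt}
    if best is None:
        raise ValueError("no pretreatment cell produced a usable calibration")

    spec = best["spec"]
    Xt_cal, wlt, ref = apply_pretreatment(X_cal, wl, spec)
    kept = best["kept"]
    fitter = fit_mpls if config.modified else fit_pls1
    model = fitter(
        Xt_cal[kept], y_cal[kept], best["cv"].chosen_lf,
        pretreatment=spec, wavelengths=wlt, msc_reference=ref,
    )

    Xt_val, _, _ = apply_pretreatment(X_val, wl, spec, reference=ref)
    y_hat = model.predict(Xt_val)
    pool = float(y_val.std(ddof=1)) if config.rpd_pool == "validation" \
        else float(y.std(ddof=1))
    ext = fit_stats(y_val, y_hat, sd_pool=pool)

    stats = FitStats(
        trait=trait,
        n_crv=int(kept.size),
        lf=model.n_factors,
        se_crv=best["cv"].se_crv,
        r2_crv=best["cv"].r2_crv,
        n_exv=int(y_val.size),
        se_exv=ext["se"],
        r2_exv=ext["r2"],
        bias=ext["bias"],
        slope=ext["slope"],
        rpd_exv=ext["rpd"],
        r2_band=classify_r2(min(max(ext["r2"], 0.0), 1.0)),
        rpd_band=classify_rpd(ext["rpd"]) if ext["rpd"] > 0 else "very poor",
        pretreatment=spec.label,
    )
    report = OutlierReport(
        spectral=spectral_report,
        chemical=best["chem_report"],
        t_iterations=best["iters"],
    )
    return CalibrationResult(model=model, stats=stats, outliers=report,
                             grid_results=pd.DataFrame(cells))
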