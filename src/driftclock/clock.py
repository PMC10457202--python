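"""Penalized linear clocks mapping CpG β values to days in culture.

Two variants are used in the pipeline: an elastic-net clock (mixing α = 0.5,
λ by 10-fold cross-validation) trained on the drift-screen candidates, and a
ridge predictor (α = 0) restricted to the survival-refined CpG subset — the
"loss-of-potential" score.  Both minimise

    (1/2n) Σᵢ (yᵢ − b₀ − xᵢᵀb)²  +  λ [ α‖b‖₁ + ((1−α)/2)‖b‖₂² ]

over a log-spaced λ path, with predictors standardized internally and
coefficients reported on the original β scale.  Cross-validation folds are
stratified by day value so that no fold loses the time gradient, and the
fold assignment is seeded and recorded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

from .io_core import BetaMatrix, DriftClockError


@dataclass
class ClockModel:
    """Intercept + sparse per-CpG coefficients (days per unit β)."""

    intercept: float
    coefficients: dict[str, float]
    hyperparameters: dict = field(default_factory=dict)
    training_r2: float | None = None
    cpg_means: dict[str, float] = field(default_factory=dict)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "hyperparameters": self.hyperparameters,
                    "training_r2": self.training_r2,
                    "cpg_means": self.cpg_means,
                },
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            hyperparameters=d.get("hyperparameters", {}),
            training_r2=d.get("training_r2"),
            cpg_means=d.get("cpg_means", {}),
        )


def _design(beta: BetaMatrix, days) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(days, dtype=float)
    if y.size != len(beta.sample_ids):
        raise DriftClockError("days must align with beta sample columns")
    x = beta.values.T.copy()
    if not np.isfinite(x).all():
        raise DriftClockError("missing β values not allowed in clock training")
    return x, y


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    xs = (x - mu) / sd_safe
    xs[:, sd == 0] = 0.0
    return xs, mu, sd_safe


def _fit_std(
    xs: np.ndarray, yc: np.ndarray, alpha: float, lam: float, tol: float = 1e-8
) -> np.ndarray:
    """Solve the penalized problem on standardized predictors/centered y."""
    n = xs.shape[0]
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(xs, yc, rcond=None)
        return coef
    if alpha == 0.0:
        # closed-form ridge: (XᵀX/n + λI) b = Xᵀy/n
        p = xs.shape[1]
        return np.linalg.solve(xs.T @ xs / n + lam * np.eye(p), xs.T @ yc / n)
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                       max_iter=100_000, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(xs, yc)
    return model.coef_


def _path_fit_std(
    xs: np.ndarray, yc: np.ndarray, alpha: float, lambdas: np.ndarray,
    tol: float = 1e-4,
) -> np.ndarray:
    """Coefficients along a decreasing λ path (warm-started), shape (L, p)."""
    n, p = xs.shape
    out = np.empty((lambdas.size, p))
    if alpha == 0.0:
        # one eigendecomposition serves the whole ridge path
        gram = xs.T @ xs / n
        w, v = np.linalg.eigh(gram)
        xty = xs.T @ yc / n
        proj = v.T @ xty
        for j, lam in enumerate(lambdas):
            out[j] = v @ (proj / (w + lam))
        return out
    model = ElasticNet(alpha=float(lambdas[0]), l1_ratio=alpha,
                       fit_intercept=False, warm_start=True,
                       max_iter=50_000, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, lam in enumerate(lambdas):
            model.set_params(alpha=float(lam))
            model.fit(xs, yc)
            out[j] = model.coef_
    return out


def _lambda_path(
    xs: np.ndarray, yc: np.ndarray, alpha: float,
    n_lambdas: int, lambda_min_ratio: float | None,
) -> np.ndarray:
    n, p = xs.shape
    lam_max = np.abs(xs.T @ yc).max() / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    if lambda_min_ratio is None:
        lambda_min_ratio = 0.01 if n < p else 1e-4
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels such that each day value is spread across folds."""
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.random(y.size), y))
    folds = np.empty(y.size, dtype=int)
    folds[order] = np.arange(y.size) % n_folds
    return folds


def train_penalized_clock(
    beta_cand: BetaMatrix,
    days,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float | None = None,
    selection: str = "min",
) -> ClockModel:
    """Train an elastic-net (or ridge, α = 0) clock with seeded k-fold CV.

    λ is chosen to minimise mean CV squared error (``selection="min"``); the
    one-standard-error rule is available as ``selection="1se"``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise DriftClockError("alpha (mixing) must be in [0,1]")
    if selection not in {"min", "1se"}:
        raise DriftClockError(f"unknown selection rule {selection!r}")
    x, y = _design(beta_cand, days)
    n = x.shape[0]
    if np.unique(y).size < 2:
        raise DriftClockError("need >= 2 distinct day values")
    if not 2 <= n_folds <= n:
        raise DriftClockError("need n_samples >= n_folds >= 2")

    xs_full, mu, sd = _standardize(x)
    yc_full = y - y.mean()
    lambdas = _lambda_path(xs_full, yc_full, alpha, n_lambdas, lambda_min_ratio)
    folds = _stratified_folds(y, n_folds, seed)

    cv_err = np.zeros((n_folds, lambdas.size))
    for k in range(n_folds):
        tr, te = folds != k, folds == k
        xs_tr, mu_k, sd_k = _standardize(x[tr])
        y_mean_k = y[tr].mean()
        xs_te = (x[te] - mu_k) / sd_k
        coefs = _path_fit_std(xs_tr, y[tr] - y_mean_k, alpha, lambdas)
        preds = y_mean_k + xs_te @ coefs.T
        cv_err[k] = np.mean((y[te][:, None] - preds) ** 2, axis=0)

    mean_err = cv_err.mean(axis=0)
    j_min = int(np.argmin(mean_err))
    if selection == "1se":
        se = cv_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
        within = np.flatnonzero(mean_err <= mean_err[j_min] + se[j_min])
        j_sel = int(within[0])  # path is decreasing in λ; first = largest λ
    else:
        j_sel = j_min
    lam_sel = float(lambdas[j_sel])

    coef_std = _fit_std(xs_full, yc_full, alpha, lam_sel)
    coef_orig = coef_std / sd
    intercept = float(y.mean() - coef_orig @ mu)

    pred = intercept + x @ coef_orig
    metrics = evaluate_clock(pred, y)

    nz = np.flatnonzero(coef_orig != 0.0)
    coefficients = {beta_cand.cpg_ids[i]: float(coef_orig[i]) for i in nz}
    cpg_means = {beta_cand.cpg_ids[i]: float(mu[i]) for i in nz}
    model = ClockModel(
        intercept=intercept,
        coefficients=coefficients,
        hyperparameters={
            "alpha": alpha, "lambda": lam_sel, "n_folds": n_folds,
            "seed": seed, "selection": selection,
        },
        training_r2=metrics["r2"],
        cpg_means=cpg_means,
    )
    model.cv_ = {"lambdas": lambdas, "mean_cv_error": mean_err, "folds": folds}
    return model


def fit_at_lambda(
    beta_cand: BetaMatrix, days, alpha: float, lam: float
) -> ClockModel:
    """Single penalized fit at a fixed (α, λ) without cross-validation."""
    if not 0.0 <= alpha <= 1.0:
        raise DriftClockError("alpha (mixing) must be in [0,1]")
    if lam < 0:
        raise DriftClockError("lambda must be >= 0")
    x, y = _design(beta_cand, days)
    xs, mu, sd = _standardize(x)
    coef_std = _fit_std(xs, y - y.mean(), alpha, lam)
    coef_orig = coef_std / sd
    intercept = float(y.mean() - coef_orig @ mu)
    nz = np.flatnonzero(coef_orig != 0.0)
    return ClockModel(
        intercept=intercept,
        coefficients={beta_cand.cpg_ids[i]: float(coef_orig[i]) for i in nz},
        hyperparameters={"alpha": alpha, "lambda": lam},
        cpg_means={beta_cand.cpg_ids[i]: float(mu[i]) for i in nz},
    )


def kkt_residual(beta_cand: BetaMatrix, days, model: ClockModel) -> float:
    """Max violation of the elastic-net stationarity conditions at the fit.

    Computed on the internally standardized problem the solver saw: for
    active coefficients |∇ⱼ − λα·sign(bⱼ)| and for inactive ones
    max(0, |∇ⱼ| − λα), where ∇ⱼ = xⱼᵀr/n − λ(1−α)bⱼ.
    """
    alpha = model.hyperparameters["alpha"]
    lam = model.hyperparameters["lambda"]
    x, y = _design(beta_cand, days)
    xs, mu, sd = _standardize(x)
    n = x.shape[0]
    coef_orig = np.array(
        [model.coefficients.get(c, 0.0) for c in beta_cand.cpg_ids]
    )
    b = coef_orig * sd
    resid = (y - y.mean()) - xs @ b
    grad = xs.T @ resid / n - lam * (1.0 - alpha) * b
    active = b != 0.0
    viol = np.where(
        active,
        np.abs(grad - lam * alpha * np.sign(b)),
        np.maximum(0.0, np.abs(grad) - lam * alpha),
    )
    return float(viol.max()) if viol.size else 0.0


def predict_days(
    model: ClockModel, beta: BetaMatrix, impute_missing: bool = False
) -> pd.Series:
    """Apply a clock: ŷ = b₀ + xᵀb per sample; no clipping of negatives.

    All model CpGs must be present in ``beta`` unless ``impute_missing``
    substitutes the stored training mean for absent CpGs or missing values.
    """
    have = set(beta.cpg_ids)
    absent = [c for c in model.cpg_ids if c not in have]
    if absent and not impute_missing:
        raise DriftClockError(f"beta lacks model CpGs: {absent[:10]}")
    pred = np.full(len(beta.sample_ids), model.intercept, dtype=float)
    idx = pd.Index(beta.cpg_ids)
    for cpg, coef in model.coefficients.items():
        if cpg in have:
            row = beta.values[idx.get_loc(cpg)].copy()
            if np.isnan(row).any():
                if not impute_missing:
                    raise DriftClockError(f"missing β at model CpG {cpg!r}")
                row = np.where(np.isnan(row), model.cpg_means.get(cpg, np.nan), row)
        else:
            row = np.full(len(beta.sample_ids), model.cpg_means.get(cpg, np.nan))
        pred += coef * row
    if np.isnan(pred).any():
        raise DriftClockError("prediction undefined: no stored mean for an absent CpG")
    return pd.Series(pred, index=beta.sample_ids, name="predicted_days")


def evaluate_clock(predicted, truth) -> dict:
    """Prediction accuracy: squared-Pearson r², RMSE, and 1−SSres/SStot.

    ``r2`` follows the scatter-plot convention (squared Pearson correlation,
    insensitive to bias); ``r2_cod`` is the coefficient of determination.
    Constant predictions get r² = 0 by convention, with a warning.
    """
    pred = np.asarray(predicted, dtype=float)
    y = np.asarray(truth, dtype=float)
    if pred.size != y.size or pred.size < 2:
        raise DriftClockError("need >= 2 aligned (predicted, truth) pairs")
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_cod = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    if np.std(pred) == 0 or np.std(y) == 0:
        warnings.warn("constant predictions or truth: r² set to 0 by convention")
        return {"r2": 0.0, "rmse": rmse, "r2_cod": r2_cod}
    r = float(stats.pearsonr(pred, y).statistic)
    if r < 0:
        warnings.warn("negative slope: predictions anti-correlated with truth")
    return {"r2": r * r, "rmse": rmse, "r2_cod": r2_cod}
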