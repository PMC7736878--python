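"""Log-linear bio-optical calibration of spectral indices against
extracted chlorophyll a.

The model is log(Chl a [mg m^-2]) = alpha + beta * INDEX, fitted by
ordinary least squares on section-level data; the natural-log response
tames the strong right skew and heteroscedasticity of areal Chl a.
Models are scored by R^2, adjusted R^2, RMSE (log units), AIC and
seeded tenfold cross-validation.

Metric conventions: R^2_adj = 1 - (1 - R^2)(n - 1)/(n - 2);
RMSE = sqrt(RSS / n) (the n - 2 variant is also reported);
AIC = n ln(RSS / n) + 2k with k = 2 parameters. Absolute AIC values are
convention-dependent; only within-run comparisons are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class RegressionModel:
    """Fitted log-linear model for one spectral index."""

    index_name: str
    alpha: float  # intercept, log mg m^-2
    beta: float  # slope per index unit

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("regression coefficients must be finite")


@dataclass
class FitMetrics:
    r2: float
    r2_adj: float
    rmse: float  # sqrt(RSS/n), log units
    rmse_unbiased: float  # sqrt(RSS/(n-2))
    aic: float
    n: int
    mse_cv: float | None = None
    rmse_cv: float | None = None
    k_folds: int | None = None
    cv_seed: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _design(data: pd.DataFrame, index_name: str) -> tuple[np.ndarray, np.ndarray]:
    if index_name not in data.columns:
        raise KeyError(f"dataset has no column {index_name!r}")
    sub = data[[index_name, "chla_mg_m2"]].dropna()
    x = sub[index_name].to_numpy(dtype=float)
    chla = sub["chla_mg_m2"].to_numpy(dtype=float)
    if np.any(chla <= 0):
        raise ValueError("Chl a must be positive for the log transformation")
    return x, np.log(chla)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(alpha, beta, RSS) by OLS; rejects zero index variance."""
    if x.size < 3:
        raise ValueError("need at least 3 rows with defined index values")
    if np.ptp(x) == 0:
        raise ValueError("index has zero variance; slope is unidentifiable")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[0]), float(fit.params[1]), float(fit.ssr)


def fit_loglinear(data: pd.DataFrame,
                  index_name: str) -> tuple[RegressionModel, FitMetrics]:
    """Fit log(Chl a) = alpha + beta * index by OLS with the metric suite.

    *data* needs a ``chla_mg_m2`` column and one column per index; rows
    with undefined (NaN) index values are dropped.
    """
    x, y = _design(data, index_name)
    alpha, beta, rss = _ols(x, y)
    n = x.size
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    rmse = math.sqrt(rss / n)
    rmse_unbiased = math.sqrt(rss / (n - 2))
    aic = n * math.log(rss / n) + 2 * 2 if rss > 0 else -math.inf
    return (RegressionModel(index_name, alpha, beta),
            FitMetrics(r2, r2_adj, rmse, rmse_unbiased, aic, n))


def kfold_cv(data: pd.DataFrame, index_name: str, folds: int = 10,
             seed: int = 0) -> tuple[float, float]:
    """Seeded k-fold cross-validation; returns (MSE_cv, RMSE_cv).

    Rows are randomly partitioned into *folds* near-equal folds; for
    each fold the model is refitted on the complement and squared errors
    are taken on the holdout in log space. MSE_cv pools all held-out
    squared errors (identical to the mean of fold MSEs at equal fold
    sizes, deterministic when they are not).
    """
    x, y = _design(data, index_name)
    n = x.size
    if n < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    perm = np.random.default_rng(seed).permutation(n)
    sq_errors = []
    for fold in np.array_split(perm, folds):
        train = np.setdiff1d(perm, fold)
        alpha, beta, _ = _ols(x[train], y[train])
        pred = alpha + beta * x[fold]
        sq_errors.append((y[fold] - pred) ** 2)
    mse = float(np.concatenate(sq_errors).mean())
    return mse, math.sqrt(mse)


def predict_chla(model: RegressionModel, index_value, *,
                 smearing: float = 1.0) -> np.ndarray | float:
    """Back-transformed prediction exp(alpha + beta * index), mg m^-2.

    NaN index markers propagate to NaN predictions. No back-transform
    bias correction by default; pass Duan's smearing factor explicitly
    to enable one.
    """
    value = np.exp(model.alpha + model.beta * np.asarray(index_value, dtype=float))
    value = value * smearing
    if np.ndim(index_value) == 0:
        return float(value)
    return value


def model_leaderboard(data: pd.DataFrame, index_names: list[str],
                      folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Fit and cross-validate every index; rank the models.

    Returns one row per index with alpha, beta, R^2, RMSE, R^2_adj, AIC,
    MSE_cv and RMSE_cv, plus a ``best`` flag on the winner (highest
    R^2_adj, ties by lower AIC then lower RMSE_cv).
    """
    if len(index_names) < 2:
        raise ValueError("a leaderboard needs at least 2 indices")
    rows = []
    for name in index_names:
        model, metrics = fit_loglinear(data, name)
        mse_cv, rmse_cv = kfold_cv(data, name, folds=folds, seed=seed)
        rows.append({
            "index": name, "alpha": model.alpha, "beta": model.beta,
            "r2": metrics.r2, "rmse": metrics.rmse, "r2_adj": metrics.r2_adj,
            "aic": metrics.aic, "mse_cv": mse_cv, "rmse_cv": rmse_cv,
        })
    board = pd.DataFrame(rows).set_index("index")
    ranked = board.sort_values(["r2_adj", "aic", "rmse_cv"],
                               ascending=[False, True, True])
    board["best"] = board.index == ranked.index[0]
    return board
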