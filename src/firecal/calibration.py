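"""Bias quantification and regression calibration of fire-rate estimators.

Interval statistics are biased estimators of the population mean fire
interval / fire rotation (PMFI/FR).  This module quantifies that bias as
relative mean error,

    RME  = mean_i[(M_i - FR_i) / FR_i] * 100%

and the inaccuracy as relative mean absolute error,

    RMAE = mean_i[|M_i - FR_i| / FR_i] * 100%,

with one-sample t-tests of zero mean; it then fits through-origin
calibration regressions PMFI/FR = beta * estimator, removing up to two
points with externally studentized residuals above a threshold, estimates
prediction error by k-fold cross-validation, and selects best-subset
models that add sample-size covariates under a Mallows Cp criterion with
per-term significance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "BiasResult",
    "CalibrationModel",
    "bias_inaccuracy",
    "fit_origin_regression",
    "cross_validate",
    "best_subsets_with_sample_size",
]


@dataclass(frozen=True)
class BiasResult:
    """Bias (signed RME) and inaccuracy (RMAE) of one estimator, percent."""

    n: int
    mean_rme: float
    se_rme: float | None
    t_bias: float | None
    p_bias: float | None
    mean_rmae: float
    se_rmae: float | None
    t_inacc: float | None
    p_inacc: float | None


@dataclass
class CalibrationModel:
    """A fitted through-origin calibration regression.

    The model has the form ``PMFI/FR = slope * predictor`` plus optional
    sample-size covariate terms.  ``r2_adj`` uses the uncentered total sum
    of squares, the standard definition for no-intercept models.
    """

    predictor_name: str
    slope: float
    n: int
    r2_adj: float
    removed_outliers: list = field(default_factory=list)
    cv_rmse: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)
    slope_se: float | None = None
    slope_p: float | None = None

    def predict(self, value: float, covariate_values: dict[str, float] | None = None):
        """Predicted PMFI/FR (years) for an estimator value."""
        if value is None or not np.isfinite(value) or value <= 0:
            raise ValueError("predictor value must be positive and finite")
        out = self.slope * value
        for name, coef in self.covariates.items():
            if covariate_values is None or name not in covariate_values:
                raise ValueError(f"model requires covariate {name!r}")
            out += coef * covariate_values[name]
        return out


def _complete_pairs(m, fr):
    m = np.asarray(m, dtype=float)
    fr = np.asarray(fr, dtype=float)
    if m.shape != fr.shape:
        raise ValueError("estimator and reference arrays differ in length")
    keep = np.isfinite(m) & np.isfinite(fr)
    return m[keep], fr[keep], np.flatnonzero(keep)


def bias_inaccuracy(m, fr) -> BiasResult:
    """RME and RMAE of estimator values ``m`` against reference ``fr``.

    Pairs with missing values are dropped; both statistics are expressed
    in percent, with two-sided one-sample t-tests of zero mean when at
    least two pairs remain.
    """
    m, fr, _ = _complete_pairs(m, fr)
    if m.size == 0:
        raise ValueError("no complete estimator/reference pairs")
    if np.any(fr <= 0):
        raise ValueError("reference PMFI/FR values must be positive")
    rel = (m - fr) / fr * 100.0
    arel = np.abs(rel)
    n = int(m.size)

    def _test(x):
        if n < 2:
            return None, None, None
        se = float(x.std(ddof=1) / np.sqrt(n))
        t, p = stats.ttest_1samp(x, 0.0)
        return se, float(t), float(p)

    se_r, t_r, p_r = _test(rel)
    se_a, t_a, p_a = _test(arel)
    return BiasResult(
        n=n,
        mean_rme=float(rel.mean()), se_rme=se_r, t_bias=t_r, p_bias=p_r,
        mean_rmae=float(arel.mean()), se_rmae=se_a, t_inacc=t_a, p_inacc=p_a,
    )


def _origin_ols(x: np.ndarray, y: np.ndarray):
    return sm.OLS(y, x.reshape(-1, 1)).fit()


def fit_origin_regression(
    x,
    y,
    outlier_threshold: float = 3.0,
    max_outliers: int = 2,
    case_ids=None,
    predictor_name: str = "predictor",
) -> CalibrationModel:
    """Through-origin least squares with studentized-residual outlier removal.

    Points whose externally studentized residual exceeds
    ``outlier_threshold`` are removed one at a time (largest first, up to
    ``max_outliers``), refitting after each removal.  Leverage uses the
    no-intercept hat matrix.
    """
    x, y, kept = _complete_pairs(x, y)
    if case_ids is None:
        ids = [int(i) for i in kept]
    else:
        ids = [list(case_ids)[i] for i in kept]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs for a calibration fit")
    if np.allclose(x, 0.0):
        raise ValueError("all predictor values are zero; slope is undefined")

    removed: list = []
    while True:
        res = _origin_ols(x, y)
        if len(removed) >= max_outliers or x.size <= 3 or res.ssr < 1e-12:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = OLSInfluence(res).resid_studentized_external
        resid = np.where(np.isfinite(resid), resid, 0.0)
        worst = int(np.argmax(np.abs(resid)))
        if abs(resid[worst]) <= outlier_threshold:
            break
        removed.append(ids.pop(worst))
        x = np.delete(x, worst)
        y = np.delete(y, worst)

    return CalibrationModel(
        predictor_name=predictor_name,
        slope=float(res.params[0]),
        n=int(x.size),
        r2_adj=float(res.rsquared_adj),
        removed_outliers=removed,
        slope_se=float(res.bse[0]),
        slope_p=float(res.pvalues[0]),
    )


def cross_validate(x, y, folds: int = 10, seed: int = 0) -> float:
    """k-fold cross-validated RMSE (years) of the through-origin model.

    Cases are partitioned by a seeded uniform shuffle; each fold is
    predicted from a slope fitted on the remaining cases.  The reported
    value carries fold-assignment noise, so repeated analyses should fix
    the seed or report a band across seeds.
    """
    x, y, _ = _complete_pairs(x, y)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 cases to cross-validate")
    if folds > n:
        warnings.warn(
            f"{folds} folds requested for {n} cases; using {n} folds",
            stacklevel=2,
        )
        folds = n
    order = np.random.default_rng(seed).permutation(n)
    sq_err = 0.0
    for fold in np.array_split(order, folds):
        train = np.setdiff1d(order, fold)
        slope = np.dot(x[train], y[train]) / np.dot(x[train], x[train])
        sq_err += float(np.sum((y[fold] - slope * x[fold]) ** 2))
    return float(np.sqrt(sq_err / n))


def best_subsets_with_sample_size(
    x,
    covariates: pd.DataFrame,
    y,
    alpha: float = 0.05,
    predictor_name: str = "predictor",
) -> CalibrationModel:
    """Best-subset through-origin model adding sample-size covariates.

    Every candidate subset contains the estimator; Mallows Cp is computed
    against the full model (estimator plus all covariates).  Among subsets
    whose every term is significant at ``alpha``, the lowest-Cp model is
    chosen; if no subset with covariates qualifies, the estimator-only
    model is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = covariates.reset_index(drop=True)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
    x, y, cov = x[keep], y[keep], cov.loc[keep].reset_index(drop=True)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete cases")

    names = list(cov.columns)
    full_X = np.column_stack([x, cov.to_numpy(dtype=float)])
    full_res = sm.OLS(y, full_X).fit()
    mse_full = full_res.ssr / max(n - full_X.shape[1], 1)

    best = None  # (cp, subset, res)
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            X = np.column_stack([x] + [cov[c].to_numpy(dtype=float) for c in subset])
            res = sm.OLS(y, X).fit()
            p = X.shape[1]
            cp = res.ssr / mse_full - (n - 2 * p)
            if np.any(res.pvalues > alpha):
                continue
            if best is None or cp < best[0]:
                best = (cp, subset, res)

    if best is None or not best[1]:
        base = fit_origin_regression(
            x, y, max_outliers=0, predictor_name=predictor_name
        )
        return base

    _, subset, res = best
    return CalibrationModel(
        predictor_name=predictor_name,
        slope=float(res.params[0]),
        n=n,
        r2_adj=float(res.rsquared_adj),
        covariates={c: float(b) for c, b in zip(subset, res.params[1:])},
        slope_se=float(res.bse[0]),
        slope_p=float(res.pvalues[0]),
    )
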