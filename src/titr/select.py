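"""Regression modelling and statistical model selection.

The null model regresses the phenotype on the covariates (intercept,
age, sex, ten principal components and the coding-region score); a PRS
is judged by its gain in adjusted R2 over that null. Nested additions
are tested with the ANOVA F test; non-nested challengers with the
Davidson-MacKinnon J test (the challenger's fitted values added to the
current design). Binary traits use the same ordinary-least-squares
machinery on the 0/1 outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .prs import PrsProfile

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass
class RegressionModel:
    """An OLS fit of phenotype on named design columns (plus intercept)."""

    response: np.ndarray
    design: pd.DataFrame  # includes the intercept column
    coefficients: np.ndarray
    fitted: np.ndarray
    rss: float
    tss: float
    r2: float
    adj_r2: float
    n: int
    p: int  # non-intercept predictors, zero columns included

    @property
    def column_names(self) -> list[str]:
        return [c for c in self.design.columns if c != "intercept"]


def _find_collinear(x: np.ndarray, names: list[str]) -> list[str]:
    """Names of non-zero columns linearly dependent on earlier columns."""
    bad = []
    kept = np.empty((x.shape[0], 0))
    for i, name in enumerate(names):
        col = x[:, i:i + 1]
        norm = np.linalg.norm(col)
        if norm == 0:
            continue  # all-zero columns carry no information but are tolerated
        if kept.shape[1]:
            proj, *_ = np.linalg.lstsq(kept, col, rcond=None)
            resid = col - kept @ proj
        else:
            resid = col
        if np.linalg.norm(resid) < 1e-8 * norm:
            bad.append(name)
        else:
            kept = np.hstack([kept, col])
    return bad


def fit_model(phenotype: np.ndarray, covariates: pd.DataFrame | np.ndarray,
              extra_columns: dict[str, np.ndarray] | pd.DataFrame | None = None
              ) -> RegressionModel:
    """Ordinary least squares of the phenotype on covariates plus extras.

    Raises :class:`CollinearityError` naming the redundant columns when
    the design is rank deficient (all-zero columns excepted: they get a
    zero coefficient but still count toward the predictor tally).
    """
    y = np.asarray(phenotype, dtype=float)
    if isinstance(covariates, np.ndarray):
        covariates = pd.DataFrame(
            covariates, columns=[f"x{i}" for i in range(covariates.shape[1])])
    design = covariates.reset_index(drop=True).copy()
    if extra_columns is not None:
        extra = pd.DataFrame(extra_columns).reset_index(drop=True)
        design = pd.concat([design, extra], axis=1)
    n, p = design.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1; n={n}, p={p}")
    if design.isna().any().any() or not np.isfinite(y).all():
        raise ValueError("missing values in design or response")

    x = design.to_numpy(dtype=float)
    bad = _find_collinear(x, list(design.columns))
    if bad:
        raise CollinearityError(f"collinear design columns: {bad}")

    design.insert(0, "intercept", 1.0)
    xd = design.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, xd).fit()
    fitted = np.asarray(res.fittedvalues)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return RegressionModel(response=y, design=design,
                           coefficients=np.asarray(res.params), fitted=fitted,
                           rss=rss, tss=tss, r2=r2, adj_r2=adj, n=n, p=p)


def delta_r2(full: RegressionModel, null: RegressionModel) -> float:
    """Gain in adjusted R2 of the full model over the null (may be negative)."""
    if full.n != null.n:
        raise ValueError(f"sample size mismatch: {full.n} vs {null.n}")
    if not np.array_equal(full.response, null.response):
        raise ValueError("models fit different response vectors")
    return full.adj_r2 - null.adj_r2


def anova_nested(null: RegressionModel, full: RegressionModel) -> float:
    """ANOVA F test for nested linear models; returns the p-value.

    A degenerate addition (zero RSS reduction, e.g. an all-zero column)
    yields F = 0 and p = 1.
    """
    if not set(null.column_names) <= set(full.column_names):
        raise ValueError("models are not nested; use j_test for non-nested models")
    if not np.array_equal(full.response, null.response):
        raise ValueError("models fit different response vectors")
    ddf = full.p - null.p
    if ddf <= 0:
        raise ValueError("full model adds no predictors")
    df1 = full.n - full.p - 1
    num = max(null.rss - full.rss, 0.0) / ddf
    den = full.rss / df1
    if den == 0:
        return 0.0 if num > 0 else 1.0
    f = num / den
    return float(sps.f.sf(f, ddf, df1))


def j_test(current: RegressionModel, challenger: RegressionModel) -> float:
    """Davidson-MacKinnon J test for non-nested linear models.

    The challenger's fitted values are added to the current design; the
    two-sided p-value of that coefficient's t test is returned. A small
    p indicates the challenger adds information beyond the current
    model. Fitted values collinear with the current design yield p = 1
    with a warning (no added information).
    """
    if not np.array_equal(current.response, challenger.response):
        raise ValueError("models fit different response vectors")
    fitted = challenger.fitted
    xcur = current.design.to_numpy(dtype=float)
    proj, *_ = np.linalg.lstsq(xcur, fitted, rcond=None)
    resid = fitted - xcur @ proj
    norm = np.linalg.norm(fitted)
    if norm == 0 or np.linalg.norm(resid) < 1e-8 * norm:
        logger.warning("j_test: challenger fitted values collinear with current design")
        return 1.0
    x = np.column_stack([xcur, fitted])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(current.response, x).fit()
    return float(res.pvalues[-1])


def _fast_adj_r2(y: np.ndarray, x: np.ndarray, p: int) -> float:
    """adjusted R2 of y ~ [1, x] via lstsq; used by the bootstrap loop."""
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def bootstrap_delta_r2(phenotype: np.ndarray, covariates: pd.DataFrame,
                       prs: PrsProfile, n_boot: int = 1000,
                       seed: int = 0) -> tuple[float, float]:
    """Percentile 95% bootstrap confidence interval for the PRS delta-R2.

    Samples are resampled with replacement n_boot times; null and full
    models are refit on each resample. Degenerate resamples (constant
    phenotype) are redrawn with a logged count.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError("bootstrap requires at least 30 samples")
    xc = covariates.to_numpy(dtype=float)
    score = np.asarray(prs.score, dtype=float)
    xf = np.column_stack([xc, score])
    p_null, p_full = xc.shape[1], xf.shape[1]
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.std() > 0:
                break
            redraws += 1
        deltas[b] = (_fast_adj_r2(yb, xf[idx], p_full)
                     - _fast_adj_r2(yb, xc[idx], p_null))
    if redraws:
        logger.info("bootstrap_delta_r2: redrew %d degenerate resamples", redraws)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return float(lo), float(hi)
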