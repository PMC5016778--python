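"""Inferential layer: correlations, OLS/MLR, normal-family GLM, diagnostics.

Conventions
-----------
* All tests are two-sided at α = 0.05 unless stated otherwise.
* Permutation p-values use a fixed seed and default to 9,999 shuffles; the
  reported p is the add-one estimate (b + 1)/(m + 1).
* The overall significance of a multiple regression is the ANOVA-type
  F = (SSR/k) / (SSE/(n − k − 1)).
* The bivariate GLM assumes a normal response with identity or log link.
  Its G statistic is the scaled deviance difference against the
  intercept-only model, G = (D₀ − D₁)/φ̂ with dispersion φ̂ = D₁/(n − p),
  referred to χ²₁.  Under the identity link this reproduces the OLS fit
  exactly (G = t² of the slope).

Ordinary least squares, Breusch-Pagan and Shapiro-Wilk are delegated to
statsmodels/scipy; the result containers expose only the fields the
analysis needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson as _dw_statistic

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "CorrelationResult",
    "BonferroniResult",
    "MlrResult",
    "GlmResult",
    "DiagnosticsResult",
    "pearson",
    "bonferroni",
    "fit_mlr",
    "fit_ols",
    "fit_glm_normal",
    "durbin_watson",
    "breusch_pagan",
    "shapiro_wilk",
    "regression_diagnostics",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    t_stat: float
    p_value: float
    p_permutation: float | None = None
    n_perm: int | None = None
    bonferroni_alpha: float | None = None
    significant_after_bonferroni: bool | None = None

    def with_bonferroni(self, threshold: float) -> "CorrelationResult":
        return CorrelationResult(
            r=self.r,
            df=self.df,
            t_stat=self.t_stat,
            p_value=self.p_value,
            p_permutation=self.p_permutation,
            n_perm=self.n_perm,
            bonferroni_alpha=threshold,
            significant_after_bonferroni=self.p_value < threshold,
        )


@dataclass(frozen=True)
class BonferroniResult:
    threshold: float
    m: int
    alpha: float
    significant: tuple[bool, ...]


@dataclass(frozen=True)
class MlrResult:
    """Multiple (or simple) linear regression summary."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    intercept: float
    multiple_r: float
    r2: float
    r2_adjusted: float
    f_stat: float
    df1: int
    df2: int
    p_overall: float
    nobs: int
    ssr: float  # regression (explained) sum of squares
    sse: float  # error (residual) sum of squares
    residuals: tuple[float, ...] = field(repr=False, default=())
    fitted: tuple[float, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class GlmResult:
    """Bivariate normal-family GLM summary."""

    link: str
    slope: float
    intercept: float
    phi: float
    g_stat: float
    p_slope: float
    deviance: float
    null_deviance: float
    nobs: int
    converged: bool = True


@dataclass(frozen=True)
class DiagnosticsResult:
    durbin_watson: float
    dw_p: float
    breusch_pagan_stat: float
    bp_p: float
    shapiro_p: float


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def pearson(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 0,
    seed: int | None = None,
) -> CorrelationResult:
    """Product-moment correlation with t-based and optional permutation p.

    The t statistic is r·sqrt((n−2)/(1−r²)) with n − 2 degrees of freedom.
    When ``n_perm`` > 0, a two-sided permutation p is computed by shuffling
    ``y`` with a seeded generator and counting |r*| ≥ |r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError(
            "correlation undefined: an input vector has zero variance"
        )
    r, p = sps.pearsonr(x, y)
    r = float(r)
    df = n - 2
    if abs(r) < 1.0:
        t = r * math.sqrt(df / (1.0 - r * r))
    else:
        t = math.copysign(math.inf, r)
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
        r_obs = abs(float(xc @ yc) / denom)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(yc)
            if abs(float(xc @ perm) / denom) >= r_obs - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
    return CorrelationResult(
        r=r, df=df, t_stat=float(t), p_value=float(p),
        p_permutation=p_perm, n_perm=n_perm or None,
    )


def bonferroni(
    p_values: Sequence[float], m: int | None = None, alpha: float = 0.05
) -> BonferroniResult:
    """Bonferroni multiple-comparison threshold α/m with per-test flags.

    ``m`` defaults to the number of p-values but can be set to the declared
    family size when only a subset of the family is passed in.
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValidationError(f"family size m must be >= 1, got {m}")
    threshold = alpha / m
    return BonferroniResult(
        threshold=threshold,
        m=m,
        alpha=alpha,
        significant=tuple(p < threshold for p in p_values),
    )


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def _as_frame(data) -> pd.DataFrame:
    if hasattr(data, "frame"):
        return data.frame
    return data


def fit_mlr(data, response: str, predictors: Sequence[str]) -> MlrResult:
    """Least-squares regression of ``response`` on ``predictors``.

    Accepts a :class:`~coastnis.dataset_io.StudyDataset` or a DataFrame.
    The overall F follows the ANOVA decomposition
    F = (SSR/k)/(SSE/(n − k − 1)).  A rank-deficient design raises with the
    names of the offending columns; an exact fit (SSE = 0) reports F = +inf.
    """
    frame = _as_frame(data)
    predictors = list(predictors)
    if response in predictors:
        raise ValidationError(f"response {response!r} cannot also be a predictor")
    missing = [c for c in [response, *predictors] if c not in frame.columns]
    if missing:
        raise ValidationError(f"column(s) not in data: {missing}")
    y = frame[response].to_numpy(dtype=float)
    X = frame[predictors].to_numpy(dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError(
            f"need n > k + 1 observations (n={n}, k={k} predictors)"
        )
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        culprits = _collinear_columns(frame, predictors)
        raise ValidationError(
            f"singular design matrix; collinear or constant column(s): {culprits}"
        )
    model = sm.OLS(y, design).fit()
    sse = float(model.ssr)          # statsmodels: ssr = residual SS
    ssr = float(model.ess)          # ess = explained SS
    df1, df2 = k, n - k - 1
    if sse <= 1e-14 * max(ssr, 1.0):
        f_stat, p_overall = math.inf, 0.0
    else:
        f_stat = (ssr / df1) / (sse / df2)
        p_overall = float(sps.f.sf(f_stat, df1, df2))
    r2 = float(model.rsquared)
    return MlrResult(
        response=response,
        predictors=tuple(predictors),
        coefficients={p: float(b) for p, b in zip(predictors, model.params[1:])},
        std_errors={p: float(s) for p, s in zip(predictors, model.bse[1:])},
        t_values={p: float(t) for p, t in zip(predictors, model.tvalues[1:])},
        p_values={p: float(v) for p, v in zip(predictors, model.pvalues[1:])},
        intercept=float(model.params[0]),
        multiple_r=math.sqrt(max(r2, 0.0)),
        r2=r2,
        r2_adjusted=float(model.rsquared_adj),
        f_stat=float(f_stat),
        df1=df1,
        df2=df2,
        p_overall=p_overall,
        nobs=n,
        ssr=ssr,
        sse=sse,
        residuals=tuple(float(e) for e in model.resid),
        fitted=tuple(float(f) for f in model.fittedvalues),
    )


def fit_ols(x: Sequence[float], y: Sequence[float]) -> MlrResult:
    """Simple OLS of y on x (convenience wrapper around :func:`fit_mlr`)."""
    frame = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float)})
    return fit_mlr(frame, "y", ["x"])


def _collinear_columns(frame: pd.DataFrame, predictors: list[str]) -> list[str]:
    """Name predictors that are constant or linearly dependent on the rest."""
    culprits = [p for p in predictors if frame[p].nunique() <= 1]
    remaining = [p for p in predictors if p not in culprits]
    X = frame[remaining].to_numpy(dtype=float)
    n = len(frame)
    for i, p in enumerate(remaining):
        others = np.column_stack(
            [np.ones(n)] + [X[:, j] for j in range(len(remaining)) if j != i]
        )
        beta, res, *_ = np.linalg.lstsq(others, X[:, i], rcond=None)
        fitted = others @ beta
        if np.allclose(fitted, X[:, i], atol=1e-10 * max(1.0, np.abs(X[:, i]).max())):
            culprits.append(p)
    return culprits


# ---------------------------------------------------------------------------
# bivariate normal-family GLM
# ---------------------------------------------------------------------------

def fit_glm_normal(
    x: Sequence[float],
    y: Sequence[float],
    link: str = "identity",
    max_iter: int = 200,
) -> GlmResult:
    """Normal-response GLM of y on a single covariate x.

    With the identity link the fit is ordinary least squares.  With the log
    link the mean is exp(a + bx), fitted by IRLS with a guarded start so the
    fitted means stay positive even when y itself touches zero.

    G is the scaled deviance difference against the intercept-only model,
    (D₀ − D₁)/φ̂ with φ̂ = D₁/(n − 2), tested on χ²₁.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("covariate is constant; slope undefined")
    design = np.column_stack([np.ones(n), x])
    null_dev = float(((y - y.mean()) ** 2).sum())

    if link == "identity":
        model = sm.OLS(y, design).fit()
        a, b = model.params
        dev = float(model.ssr)
        converged = True
    elif link == "log":
        family = sm.families.Gaussian(link=sm.families.links.Log())
        glm = sm.GLM(y, design, family=family)
        # start from the log of the positive-clipped linear fit so the first
        # IRLS step has positive means
        lin = sm.OLS(y, design).fit().fittedvalues
        floor = max(1e-6, 1e-3 * float(np.abs(y).mean() or 1.0))
        start = sm.OLS(np.log(np.clip(lin, floor, None)), design).fit().params
        try:
            fit = glm.fit(start_params=start, maxiter=max_iter)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise ConvergenceError(f"log-link IRLS failed: {exc}") from exc
        if not fit.converged:
            raise ConvergenceError(
                f"log-link IRLS did not converge in {max_iter} iterations",
                trace=list(getattr(fit, "fit_history", {}).get("deviance", [])),
            )
        a, b = fit.params
        dev = float(fit.deviance)
        converged = True
    else:
        raise ValidationError(f"unknown link {link!r}; use 'identity' or 'log'")

    phi = dev / (n - 2)
    if phi <= 0:
        g = math.inf
        p_slope = 0.0
    else:
        g = max(0.0, (null_dev - dev) / phi)
        p_slope = float(sps.chi2.sf(g, 1))
    return GlmResult(
        link=link,
        slope=float(b),
        intercept=float(a),
        phi=float(phi),
        g_stat=float(g),
        p_slope=p_slope,
        deviance=dev,
        null_deviance=null_dev,
        nobs=n,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def durbin_watson(
    residuals: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Durbin-Watson lag-1 autocorrelation statistic with permutation p.

    DW = Σ(e_t − e_{t−1})² / Σe_t², in [0, 4], ≈ 2 for exchangeable
    residuals.  The p-value is two-sided against exchangeability: the
    residual order is permuted ``n_perm`` times (seeded) and |DW* − 2| ≥
    |DW − 2| is counted.  Pass ``n_perm=0`` to skip the p-value.
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or e.size < 3:
        raise ValidationError("need an ordered vector of at least 3 residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ValidationError("zero residual variance; DW undefined")
    dw = float(_dw_statistic(e))
    if n_perm <= 0:
        return dw, math.nan
    rng = np.random.default_rng(seed)
    obs = abs(dw - 2.0)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(e)
        if abs(float(_dw_statistic(perm)) - 2.0) >= obs - 1e-12:
            hits += 1
    return dw, (hits + 1) / (n_perm + 1)


def breusch_pagan(
    x: Sequence[float] | np.ndarray, residuals: Sequence[float]
) -> tuple[float, float]:
    """Breusch-Pagan LM test of homoskedasticity.

    The statistic is n·R² from regressing squared residuals on the
    covariate(s); the reference distribution is χ² with k degrees of
    freedom.  ``x`` may be a vector or an (n, k) matrix without constant.
    """
    e = np.asarray(residuals, dtype=float)
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != e.size:
        raise ValidationError("x and residuals must have the same length")
    if float(e @ e) == 0:
        return 0.0, 1.0
    exog = np.column_stack([np.ones(X.shape[0]), X])
    lm, lm_p, _, _ = het_breuschpagan(e, exog)
    return float(lm), float(lm_p)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (statistic, p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("Shapiro-Wilk needs at least 3 values")
    stat, p = sps.shapiro(v)
    return float(stat), float(p)


def regression_diagnostics(
    x: Sequence[float] | np.ndarray,
    residuals: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = 0,
) -> DiagnosticsResult:
    """Bundle of Durbin-Watson, Breusch-Pagan and Shapiro-Wilk on residuals."""
    dw, dw_p = durbin_watson(residuals, n_perm=n_perm, seed=seed)
    bp, bp_p = breusch_pagan(x, residuals)
    _, sw_p = shapiro_wilk(residuals)
    return DiagnosticsResult(
        durbin_watson=dw, dw_p=dw_p,
        breusch_pagan_stat=bp, bp_p=bp_p,
        shapiro_p=sw_p,
    )
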