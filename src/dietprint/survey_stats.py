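"""Design-based estimation for stratified multistage samples.

Point estimates are Horvitz-Thompson ratio means; variances use Taylor
linearization with the with-replacement between-PSU approximation: the
linearized score of each observation is totalled within PSU, and the
variance is the stratum-weighted between-PSU scatter of those totals,

    Var = sum_h  n_h/(n_h - 1) * sum_j (S_hj - S̄_h)(S_hj - S̄_h)',

with design degrees of freedom (#PSUs - #strata) for t-based confidence
intervals and tests — the convention used by the major survey packages.
Every stratum must contain at least two sampled PSUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, EstimationError


@dataclass(frozen=True)
class DesignEstimate:
    """Survey-weighted point estimate with linearized SE and 95% t-CI."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    df: int
    n: int


@dataclass(frozen=True)
class TrendResult:
    """Design-based linear trend across quintiles (slope per increment)."""

    slope: float
    se: float
    p_value: float
    df: int
    n: int
    adjusted: bool = False
    covariates: tuple[str, ...] = ()


def _check_design(strata: np.ndarray, psus: np.ndarray) -> tuple[pd.Series, int, int]:
    """Validate >=2 PSUs per stratum; return PSU labels, #PSUs, #strata."""
    labels = pd.Series(list(zip(strata, psus)))
    per_stratum = pd.DataFrame({"s": strata, "p": psus}).groupby("s")["p"].nunique()
    lonely = per_stratum[per_stratum < 2]
    if not lonely.empty:
        raise DesignError(
            f"stratum(a) {lonely.index.tolist()} have a single PSU; "
            "variance estimation needs >= 2 PSUs per stratum"
        )
    n_psu = int(per_stratum.sum())
    return labels, n_psu, int(per_stratum.size)


def _psu_total_cov(scores: np.ndarray, strata: np.ndarray, psus: np.ndarray) -> np.ndarray:
    """Between-PSU covariance of linearized score totals, summed over strata."""
    p = scores.shape[1]
    df = pd.DataFrame(scores)
    df["_s"] = strata
    df["_p"] = psus
    totals = df.groupby(["_s", "_p"], sort=False).sum()
    cov = np.zeros((p, p))
    for _, g in totals.groupby(level="_s", sort=False):
        z = g.to_numpy(dtype=float)
        n_h = z.shape[0]
        zc = z - z.mean(axis=0, keepdims=True)
        cov += (n_h / (n_h - 1)) * zc.T @ zc
    return cov


def weighted_mean(
    values: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    strata: np.ndarray | pd.Series,
    psus: np.ndarray | pd.Series,
    *,
    alpha: float = 0.05,
) -> DesignEstimate:
    """Survey-weighted mean with Taylor-linearized SE and t-based CI."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    s = np.asarray(strata)
    p = np.asarray(psus)
    if not (x.size == w.size == s.size == p.size):
        raise EstimationError("values, weights, strata, psus must align")
    if x.size == 0:
        raise EstimationError("empty input")
    if (w <= 0).any():
        raise EstimationError("weights must be strictly positive")
    _, n_psu, n_strata = _check_design(s, p)
    wsum = float(w.sum())
    point = float(np.sum(w * x) / wsum)
    z = (w * (x - point) / wsum)[:, None]
    var = float(_psu_total_cov(z, s, p)[0, 0])
    se = float(np.sqrt(max(var, 0.0)))
    dof = n_psu - n_strata
    tcrit = float(stats.t.ppf(1 - alpha / 2, dof)) if dof > 0 else np.nan
    return DesignEstimate(
        point=point,
        se=se,
        ci_low=point - tcrit * se,
        ci_high=point + tcrit * se,
        df=dof,
        n=int(x.size),
    )


def design_wls(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    strata: np.ndarray,
    psus: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Weighted least squares with linearized (PSU-aggregated sandwich)
    covariance.  Returns (beta, vcov, design df)."""
    w = np.asarray(weights, dtype=float)
    _, n_psu, n_strata = _check_design(np.asarray(strata), np.asarray(psus))
    A = X.T @ (X * w[:, None])
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise EstimationError("collinear design matrix") from None
    cond = np.linalg.cond(A)
    if cond > 1e12:
        raise EstimationError(f"collinear design matrix (condition number {cond:.2e})")
    beta = Ainv @ (X.T @ (w * y))
    resid = y - X @ beta
    scores = X * (w * resid)[:, None]
    G = _psu_total_cov(scores, np.asarray(strata), np.asarray(psus))
    vcov = Ainv @ G @ Ainv
    return beta, vcov, n_psu - n_strata


def trend_test(
    outcome: np.ndarray | pd.Series,
    quintile: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    strata: np.ndarray | pd.Series,
    psus: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> TrendResult:
    """Test for linear trend across quintiles 1..5.

    The quintile index enters as a continuous integer score in a
    survey-weighted linear regression; the two-sided P uses the linearized
    slope SE on design degrees of freedom.  ``covariates`` (e.g. age and a
    male indicator) are appended as adjustment columns.
    """
    y = np.asarray(outcome, dtype=float)
    q = np.asarray(quintile, dtype=float)
    cols = [np.ones_like(y), q]
    names: tuple[str, ...] = ()
    if covariates is not None:
        names = tuple(covariates.columns)
        for c in covariates.columns:
            cols.append(np.asarray(covariates[c], dtype=float))
    X = np.column_stack(cols)
    beta, vcov, dof = design_wls(
        y, X, np.asarray(weights, dtype=float), np.asarray(strata), np.asarray(psus)
    )
    slope = float(beta[1])
    se = float(np.sqrt(max(vcov[1, 1], 0.0)))
    if se == 0.0:
        pval = 1.0 if slope == 0.0 else 0.0
    else:
        tstat = slope / se
        pval = float(2 * stats.t.sf(abs(tstat), dof))
    return TrendResult(
        slope=slope,
        se=se,
        p_value=pval,
        df=dof,
        n=int(y.size),
        adjusted=covariates is not None,
        covariates=names,
    )


def wald_difference_test(
    values_a: np.ndarray | pd.Series,
    values_b: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    strata: np.ndarray | pd.Series,
    psus: np.ndarray | pd.Series,
) -> dict[str, float]:
    """Paired Wald test of the survey-weighted mean difference a - b.

    Both value vectors must come from the same individuals in the same
    order (the pairing absorbs the individual-level covariance).  A nonzero
    constant difference is degenerate (SE 0): reported with a warning and
    P = 0; an identically zero difference yields P = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise EstimationError("paired value vectors differ in length")
    est = weighted_mean(a - b, weights, strata, psus)
    if est.se == 0.0:
        if est.point == 0.0:
            return {"difference": 0.0, "se": 0.0, "p_value": 1.0, "df": est.df}
        warnings.warn("degenerate paired difference: constant shift with zero SE")
        return {"difference": est.point, "se": 0.0, "p_value": 0.0, "df": est.df}
    tstat = est.point / est.se
    return {
        "difference": est.point,
        "se": est.se,
        "p_value": float(2 * stats.t.sf(abs(tstat), est.df)),
        "df": est.df,
    }
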