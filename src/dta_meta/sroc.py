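"""Summary ROC analysis via the constant linear (Moses-Littenberg) model.

Each study contributes a point ``(S, D)`` where ``D = logit(TPR) -
logit(FPR)`` (the log diagnostic odds ratio) and ``S = logit(TPR) +
logit(FPR)`` (a proxy for the positivity threshold).  The model ``D = a +
b*S`` is fitted by least squares (unweighted by default, optionally weighted
by ``1/var(D)``) and induces a summary ROC curve

    logit(TPR) = (a + (1 + b) * logit(FPR)) / (1 - b)

from which the area under the curve and the Q* index (the point where
sensitivity equals specificity) are derived, with delta-method standard
errors.  Two fitted tests are compared with a two-sample Z statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSlopeError,
    InsufficientStudiesError,
    SingularDesignError,
    ValidationError,
    ZeroCellError,
)
from .studies import CorrectedCounts

__all__ = [
    "DSPoint",
    "SROCFit",
    "SROCComparison",
    "compute_ds",
    "fit_moses",
    "sroc_curve",
    "sroc_auc",
    "q_star",
    "compare_tests",
]

_EPS = 1e-12


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class DSPoint:
    """One study's coordinates in (S, D) space, with the variance of D."""

    study_id: str
    d: float
    s: float
    var_d: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d) and math.isfinite(self.s)):
            raise ValidationError(f"study {self.study_id!r}: D/S must be finite")
        if self.var_d <= 0:
            raise ValidationError(f"study {self.study_id!r}: var_d must be > 0")


@dataclass(frozen=True)
class SROCFit:
    """Coefficients of the linear SROC fit plus derived summary statistics.

    ``se_a``, ``se_b`` and ``cov_ab`` are NaN when fewer than 3 points were
    fitted (no residual degrees of freedom).  ``auc``/``q_star`` and their
    standard errors are NaN until filled in by :func:`sroc_auc` /
    :func:`q_star` (the convenience wrappers in the report module do this).
    """

    a: float
    b: float
    se_a: float
    se_b: float
    cov_ab: float
    weighted: bool
    k: int
    auc: float = math.nan
    se_auc: float = math.nan
    q_star: float = math.nan
    se_q_star: float = math.nan


@dataclass(frozen=True)
class SROCComparison:
    z: float
    p_value: float
    statistic_compared: str = "q_star"


def compute_ds(counts: CorrectedCounts, study_id: str = "") -> DSPoint:
    """Map (corrected) cell counts to the (S, D) plane."""
    if counts.has_zero_cell:
        raise ZeroCellError(
            f"study {study_id!r}: zero cell; D/S are undefined without a continuity correction"
        )
    sens = counts.tp / (counts.tp + counts.fn)
    fpr = counts.fp / (counts.fp + counts.tn)
    d = _logit(sens) - _logit(fpr)
    s = _logit(sens) + _logit(fpr)
    var_d = 1.0 / counts.tp + 1.0 / counts.fp + 1.0 / counts.fn + 1.0 / counts.tn
    return DSPoint(study_id=study_id, d=d, s=s, var_d=var_d)


def fit_moses(points: Sequence[DSPoint], weighted: bool = False) -> SROCFit:
    """Least-squares fit of ``D = a + b*S``.

    ``weighted=True`` uses weights ``1/var_d``.  Coefficient covariance uses
    the standard linear-model formula with the residual variance estimate;
    with only two points the fit is exact and the SEs are NaN.
    """
    k = len(points)
    if k < 2:
        raise InsufficientStudiesError("the linear SROC fit needs at least 2 studies")
    s = np.array([p.s for p in points])
    d = np.array([p.d for p in points])
    w = 1.0 / np.array([p.var_d for p in points]) if weighted else np.ones(k)

    X = np.column_stack([np.ones(k), s])
    XtWX = X.T @ (w[:, None] * X)
    if abs(np.linalg.det(XtWX)) < 1e-12 * max(1.0, float(np.trace(XtWX)) ** 2):
        raise SingularDesignError("all S values are (numerically) identical; slope is unidentifiable")
    XtWd = X.T @ (w * d)
    coef = np.linalg.solve(XtWX, XtWd)
    a, b = float(coef[0]), float(coef[1])

    if k >= 3:
        resid = d - X @ coef
        sigma2 = float(np.sum(w * resid**2)) / (k - 2)
        cov = sigma2 * np.linalg.inv(XtWX)
        se_a, se_b = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        cov_ab = float(cov[0, 1])
    else:
        se_a = se_b = cov_ab = math.nan

    return SROCFit(a=a, b=b, se_a=se_a, se_b=se_b, cov_ab=cov_ab, weighted=weighted, k=k)


def sroc_curve(fit: SROCFit, fpr) -> np.ndarray | float:
    """TPR of the summary ROC curve at the given FPR value(s)."""
    if abs(fit.b) >= 1:
        raise DegenerateSlopeError(
            f"|slope| = {abs(fit.b):.3f} >= 1: the implied curve is not monotone-valid"
        )
    scalar = np.isscalar(fpr)
    f = np.clip(np.asarray(fpr, dtype=float), _EPS, 1 - _EPS)
    if np.any((np.asarray(fpr, dtype=float) <= 0) | (np.asarray(fpr, dtype=float) >= 1)):
        raise ValidationError("fpr must lie strictly inside (0, 1)")
    logit_f = np.log(f / (1 - f))
    logit_t = (fit.a + (1 + fit.b) * logit_f) / (1 - fit.b)
    tpr = 1.0 / (1.0 + np.exp(-logit_t))
    return float(tpr) if scalar else tpr


def _auc_value(a: float, b: float, grid_step: float, lo: float, hi: float) -> float:
    if abs(b) >= 1:
        raise DegenerateSlopeError(f"|slope| = {abs(b):.3f} >= 1")
    n = max(3, int(round((hi - lo) / grid_step)) + 1)
    f = np.linspace(lo, hi, n)
    fc = np.clip(f, _EPS, 1 - _EPS)
    logit_f = np.log(fc / (1 - fc))
    logit_t = (a + (1 + b) * logit_f) / (1 - b)
    tpr = 1.0 / (1.0 + np.exp(-logit_t))
    return float(np.trapezoid(tpr, f))


def sroc_auc(
    fit: SROCFit,
    grid_step: float = 1e-4,
    fpr_range: str | tuple[float, float] = "full",
) -> tuple[float, float]:
    """Area under the summary ROC curve, with a delta-method standard error.

    ``fpr_range="full"`` integrates over (0, 1) (the extrapolated AUC, the
    default); a ``(lo, hi)`` tuple restricts the integral to an observed FPR
    range.  The SE combines a central-finite-difference gradient in (a, b)
    with the fit's coefficient covariance; it is NaN when the fit carries no
    SEs (k < 3).
    """
    if fpr_range == "full":
        lo, hi = 0.0, 1.0
    else:
        lo, hi = fpr_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError(f"invalid fpr range ({lo}, {hi})")
    auc = _auc_value(fit.a, fit.b, grid_step, lo, hi)

    if math.isnan(fit.se_a):
        return auc, math.nan
    ha = 1e-5 * max(1.0, abs(fit.a))
    hb = 1e-5 * max(1.0, abs(fit.b))
    dda = (_auc_value(fit.a + ha, fit.b, grid_step, lo, hi) - _auc_value(fit.a - ha, fit.b, grid_step, lo, hi)) / (2 * ha)
    ddb = (_auc_value(fit.a, fit.b + hb, grid_step, lo, hi) - _auc_value(fit.a, fit.b - hb, grid_step, lo, hi)) / (2 * hb)
    var = (
        dda**2 * fit.se_a**2
        + ddb**2 * fit.se_b**2
        + 2 * dda * ddb * fit.cov_ab
    )
    return auc, math.sqrt(max(0.0, var))


def q_star(fit: SROCFit) -> tuple[float, float]:
    """Q* index: the TPR at the sensitivity = specificity point (S = 0).

    ``q_star = 1 / (1 + exp(-a/2))``; its SE follows by the delta method,
    ``se_a * q*(1-q*) / 2`` (NaN when the fit carries no SEs).
    """
    q = _inv_logit(fit.a / 2.0)
    se = fit.se_a * q * (1.0 - q) / 2.0 if math.isfinite(fit.se_a) else math.nan
    return q, se


def with_summaries(
    fit: SROCFit,
    grid_step: float = 1e-4,
    fpr_range: str | tuple[float, float] = "full",
) -> SROCFit:
    """Return a copy of ``fit`` with AUC and Q* (and their SEs) filled in."""
    auc, se_auc = sroc_auc(fit, grid_step=grid_step, fpr_range=fpr_range)
    q, se_q = q_star(fit)
    return replace(fit, auc=auc, se_auc=se_auc, q_star=q, se_q_star=se_q)


def compare_tests(stat1: float, se1: float, stat2: float, se2: float, statistic: str = "q_star") -> SROCComparison:
    """Two-sample Z comparison of a summary statistic between two tests."""
    if not (se1 > 0 and se2 > 0):
        raise ValidationError("standard errors must be > 0")
    z = (stat1 - stat2) / math.sqrt(se1**2 + se2**2)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    # keep p strictly positive even when the normal tail underflows
    p = min(1.0, max(p, math.ulp(0.0)))
    return SROCComparison(z=z, p_value=p, statistic_compared=statistic)
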