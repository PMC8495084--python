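"""Threshold-effect and publication-bias diagnostics.

* Spearman rank correlation between per-study logit(TPR) and logit(FPR): a
  significant positive correlation indicates that studies vary mainly in
  their implicit positivity threshold rather than in accuracy.
* Funnel-plot asymmetry regression for diagnostic accuracy data: ln(DOR) is
  regressed on 1/sqrt(ESS) with weights ESS, where ESS = 4*n1*n2/(n1+n2) is
  the effective sample size; a slope significantly different from zero flags
  small-study (publication) bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientStudiesError, ValidationError
from .studies import StudyRecord, apply_continuity_correction
from .sroc import compute_ds

__all__ = [
    "ThresholdResult",
    "DeeksResult",
    "spearman_threshold",
    "deeks_test",
    "effective_sample_size",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdResult:
    rho: float
    p_value: float
    scale: str
    k: int


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    intercept: float
    p_value: float
    ess: tuple[float, ...]
    k: int
    excluded: tuple[str, ...] = ()


def effective_sample_size(n_diseased: float, n_healthy: float) -> float:
    """ESS = 4*n1*n2/(n1+n2), the harmonic-mean-based funnel-plot axis."""
    if n_diseased <= 0 or n_healthy <= 0:
        raise ValidationError("both groups must be non-empty for an effective sample size")
    return 4.0 * n_diseased * n_healthy / (n_diseased + n_healthy)


def _rates(
    studies: Sequence[StudyRecord],
    correction_mode: str,
    correction_value: float,
) -> tuple[np.ndarray, np.ndarray]:
    tpr, fpr = [], []
    for s in studies:
        c = apply_continuity_correction(s, mode=correction_mode, value=correction_value)
        tpr.append(c.tp / (c.tp + c.fn))
        fpr.append(c.fp / (c.fp + c.tn))
    return np.array(tpr), np.array(fpr)


def spearman_threshold(
    studies: Sequence[StudyRecord],
    scale: str = "logit",
    *,
    correction_mode: str = "affected_studies",
    correction_value: float = 0.5,
) -> ThresholdResult:
    """Spearman correlation between per-study TPR and FPR (threshold effect).

    The default correlates logit(TPR) with logit(FPR); ``scale="raw"`` uses
    the raw rates (identical rho unless the transform creates/destroys ties).
    The two-sided p-value uses the t approximation with k-2 df.
    """
    k = len(studies)
    if k < 3:
        raise InsufficientStudiesError("the threshold diagnostic needs at least 3 studies")
    if scale not in ("logit", "raw"):
        raise ValidationError(f"scale must be 'logit' or 'raw', got {scale!r}")
    tpr, fpr = _rates(studies, correction_mode, correction_value)
    if scale == "logit":
        x = np.log(tpr / (1 - tpr))
        y = np.log(fpr / (1 - fpr))
    else:
        x, y = tpr, fpr
    rho, p = stats.spearmanr(x, y)
    return ThresholdResult(rho=float(rho), p_value=float(p), scale=scale, k=k)


def deeks_test(
    studies: Sequence[StudyRecord],
    *,
    correction_mode: str = "affected_studies",
    correction_value: float = 0.5,
) -> DeeksResult:
    """Funnel-plot asymmetry regression for diagnostic odds ratios.

    Weighted least squares of ln(DOR) on 1/sqrt(ESS) with weights ESS; the
    reported p-value is the two-sided t test (k-2 df) for the slope.  Studies
    with no diseased or no healthy subjects are excluded with a warning.
    """
    kept, excluded = [], []
    for s in studies:
        if s.n_diseased == 0 or s.n_healthy == 0:
            excluded.append(s.study_id)
            logger.warning(
                "excluding study %r from the funnel-plot regression: empty group", s.study_id
            )
        else:
            kept.append(s)
    k = len(kept)
    if k < 3:
        raise InsufficientStudiesError("the funnel-plot regression needs at least 3 usable studies")

    ess = np.array([effective_sample_size(s.n_diseased, s.n_healthy) for s in kept])
    ln_dor = np.array(
        [
            compute_ds(
                apply_continuity_correction(s, mode=correction_mode, value=correction_value),
                study_id=s.study_id,
            ).d
            for s in kept
        ]
    )
    x = 1.0 / np.sqrt(ess)
    w = ess

    X = np.column_stack([np.ones(k), x])
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * ln_dor))
    intercept, slope = float(coef[0]), float(coef[1])
    resid = ln_dor - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (k - 2)
    cov = sigma2 * np.linalg.inv(XtWX)
    se_slope = math.sqrt(cov[1, 1])
    if se_slope == 0:
        p = 1.0
    else:
        t = slope / se_slope
        p = 2.0 * float(stats.t.sf(abs(t), k - 2))
    return DeeksResult(
        slope=slope,
        intercept=intercept,
        p_value=min(1.0, p),
        ess=tuple(float(e) for e in ess),
        k=k,
        excluded=tuple(excluded),
    )
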