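"""Fixed-effect and DerSimonian-Laird random-effects pooling.

Sensitivity and specificity are pooled on the raw proportion scale with
inverse-variance weights (per-study variance ``p(1-p)/n``); the likelihood
ratios and the diagnostic odds ratio are pooled on the natural-log scale and
back-transformed.  Heterogeneity (Cochran Q, I-squared, the DerSimonian-Laird
tau-squared) is always computed on the scale used for pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientStudiesError, ValidationError
from .studies import StudyRecord, apply_continuity_correction, per_study_measures

__all__ = [
    "PooledResult",
    "HeterogeneityResult",
    "pool_inverse_variance",
    "heterogeneity",
    "dsl_tau_squared",
    "pool_measure",
    "leave_one_out",
]

MEASURES = ("sens", "spec", "plr", "nlr", "dor")
_LOG_SCALE = frozenset({"plr", "nlr", "dor"})


@dataclass(frozen=True)
class HeterogeneityResult:
    cochran_q: float
    df: int
    p_het: float
    i_squared: float
    tau_squared: float


@dataclass(frozen=True)
class PooledResult:
    """Pooled estimate with CI and heterogeneity for one measure and model."""

    measure: str
    model: str
    estimate: float
    ci_low: float
    ci_high: float
    k: int
    cochran_q: float
    df: int
    p_het: float
    i_squared: float
    tau_squared: float
    se_scale: float  # standard error on the pooling scale
    clamped: bool = False


def _check_inputs(values: Sequence[float], variances: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(values, dtype=float)
    v = np.asarray(variances, dtype=float)
    if x.size == 0:
        raise InsufficientStudiesError("no studies to pool")
    if x.shape != v.shape:
        raise ValidationError("values and variances must have the same length")
    if np.any(v <= 0):
        raise ValidationError("all per-study variances must be > 0")
    return x, v


def dsl_tau_squared(values: Sequence[float], variances: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance."""
    x, v = _check_inputs(values, variances)
    k = x.size
    if k < 2:
        return 0.0
    w = 1.0 / v
    xbar = float(np.sum(w * x) / np.sum(w))
    q = float(np.sum(w * (x - xbar) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def pool_inverse_variance(
    values: Sequence[float],
    variances: Sequence[float],
    model: str = "random",
    tau_squared: float | None = None,
) -> tuple[float, float]:
    """Inverse-variance pooled estimate and its standard error.

    Fixed model weights are ``1/v_i``; random model weights ``1/(v_i + tau2)``
    with the DerSimonian-Laird ``tau2`` unless one is supplied.
    """
    x, v = _check_inputs(values, variances)
    if model not in ("fixed", "random"):
        raise ValidationError(f"model must be 'fixed' or 'random', got {model!r}")
    if model == "random":
        t2 = dsl_tau_squared(x, v) if tau_squared is None else float(tau_squared)
        if t2 < 0:
            raise ValidationError("tau_squared must be >= 0")
        w = 1.0 / (v + t2)
    else:
        w = 1.0 / v
    est = float(np.sum(w * x) / np.sum(w))
    se = float(np.sum(w)) ** -0.5
    return est, se


def heterogeneity(values: Sequence[float], variances: Sequence[float]) -> HeterogeneityResult:
    """Cochran Q, its chi-square p-value, I-squared and the DL tau-squared."""
    x, v = _check_inputs(values, variances)
    k = x.size
    if k < 2:
        raise InsufficientStudiesError("heterogeneity needs at least 2 studies")
    w = 1.0 / v
    xbar = float(np.sum(w * x) / np.sum(w))
    q = float(np.sum(w * (x - xbar) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(
        cochran_q=q,
        df=df,
        p_het=p,
        i_squared=i2,
        tau_squared=dsl_tau_squared(x, v),
    )


def _study_scale_value(
    record: StudyRecord,
    measure: str,
    correction_mode: str,
    correction_value: float,
) -> tuple[float, float]:
    """(value, variance) on the pooling scale for one study."""
    counts = apply_continuity_correction(record, mode=correction_mode, value=correction_value)
    if measure in _LOG_SCALE:
        m = per_study_measures(counts)
        value = math.log({"plr": m.plr, "nlr": m.nlr, "dor": m.dor}[measure])
        if measure == "dor":
            var = m.var_log_dor
        else:
            c_sens = counts.tp / (counts.tp + counts.fn)
            c_fpr = counts.fp / (counts.fp + counts.tn)
            n1 = counts.tp + counts.fn
            n2 = counts.fp + counts.tn
            if measure == "plr":
                var = (1 - c_sens) / (c_sens * n1) + (1 - c_fpr) / (c_fpr * n2)
            else:
                var = c_sens / ((1 - c_sens) * n1) + c_fpr / ((1 - c_fpr) * n2)
        return value, var
    # Proportions: the point estimate comes from the raw cells; the variance
    # uses the corrected cells whenever a zero cell would make it vanish.
    rtp, rfp, rfn, rtn = record.tp, record.fp, record.fn, record.tn
    if measure == "sens":
        value = rtp / (rtp + rfn) if (rtp + rfn) > 0 else math.nan
        p_var, n_var = counts.tp / (counts.tp + counts.fn), counts.tp + counts.fn
    elif measure == "spec":
        value = rtn / (rtn + rfp) if (rtn + rfp) > 0 else math.nan
        p_var, n_var = counts.tn / (counts.tn + counts.fp), counts.tn + counts.fp
    else:
        raise ValidationError(f"unknown measure {measure!r}")
    if math.isnan(value):
        raise ValidationError(
            f"study {record.study_id!r}: no subjects in the denominator for {measure}"
        )
    var = p_var * (1 - p_var) / n_var
    if var <= 0:
        # raw p is 0 or 1 and no correction was applied (mode 'never' without
        # a zero in the off-diagonal cells is possible): fall back on a
        # half-count correction for the variance alone.
        p_adj = (p_var * n_var + 0.5) / (n_var + 1.0)
        var = p_adj * (1 - p_adj) / n_var
    return value, var


def pool_measure(
    studies: Sequence[StudyRecord],
    measure: str,
    model: str = "random",
    *,
    correction_mode: str = "affected_studies",
    correction_value: float = 0.5,
    ci_level: float = 0.95,
) -> PooledResult:
    """Pool one accuracy measure over a single-test collection of studies.

    All records must share the same ``test_label``; two-test datasets are
    split by arm before pooling.
    """
    if measure not in MEASURES:
        raise ValidationError(f"measure must be one of {MEASURES}, got {measure!r}")
    if not studies:
        raise InsufficientStudiesError("no studies to pool")
    labels = {s.test_label for s in studies}
    if len(labels) > 1:
        raise ValidationError(
            f"mixed test labels {sorted(labels)}: split the arms before pooling"
        )
    pairs = [
        _study_scale_value(s, measure, correction_mode, correction_value) for s in studies
    ]
    values = [p[0] for p in pairs]
    variances = [p[1] for p in pairs]
    k = len(studies)

    if k >= 2:
        het = heterogeneity(values, variances)
    else:
        het = HeterogeneityResult(cochran_q=0.0, df=0, p_het=math.nan, i_squared=0.0, tau_squared=0.0)

    est, se = pool_inverse_variance(values, variances, model=model, tau_squared=het.tau_squared if model == "random" else None)
    z = float(stats.norm.ppf(0.5 + ci_level / 2))
    lo, hi = est - z * se, est + z * se

    clamped = False
    if measure in _LOG_SCALE:
        est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
    else:
        if lo < 0.0 or hi > 1.0:
            clamped = True
        lo, hi = max(0.0, lo), min(1.0, hi)

    return PooledResult(
        measure=measure,
        model=model,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        k=k,
        cochran_q=het.cochran_q,
        df=het.df,
        p_het=het.p_het,
        i_squared=het.i_squared,
        tau_squared=het.tau_squared,
        se_scale=se,
        clamped=clamped,
    )


def leave_one_out(
    studies: Sequence[StudyRecord],
    analysis: Callable[[Sequence[StudyRecord]], object],
) -> list[tuple[str, object]]:
    """Re-run ``analysis`` k times, each time excluding one study.

    Returns ``[(excluded_study_id, analysis_result), ...]`` in input order.
    """
    if len(studies) < 2:
        raise InsufficientStudiesError("leave-one-out needs at least 2 studies")
    out = []
    for i, s in enumerate(studies):
        subset = [t for j, t in enumerate(studies) if j != i]
        out.append((s.study_id, analysis(subset)))
    return out
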