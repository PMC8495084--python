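"""Study-level 2x2 tables: parsing, validation, continuity correction and
per-study accuracy measures.

A *study record* holds the four cells of one study's contingency table for one
index test (``tp``, ``fp``, ``fn``, ``tn``), counted against the reference
standard.  Zero cells are handled by an explicit continuity-correction step so
that downstream log/logit transforms never silently produce infinities; raw
counts are always retained so that proportions (sensitivity, specificity) can
be reported uncorrected while log-scale measures use corrected cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError, ZeroCellError

__all__ = [
    "StudyRecord",
    "CorrectedCounts",
    "AccuracyMeasures",
    "read_studies",
    "write_studies",
    "studies_to_frame",
    "apply_continuity_correction",
    "per_study_measures",
]

REQUIRED_COLUMNS = ("study_id", "test_label", "tp", "fp", "fn", "tn")
OPTIONAL_COLUMNS = ("year", "design")
_DESIGNS = ("prospective", "retrospective")


@dataclass(frozen=True)
class StudyRecord:
    """One study's labelled 2x2 cell counts for one index test."""

    study_id: str
    test_label: str
    tp: int
    fp: int
    fn: int
    tn: int
    year: int | None = None
    design: str | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(
                    f"study {self.study_id!r}: cell {name!r} must be an integer, got {v!r}"
                )
            if v < 0:
                raise ValidationError(
                    f"study {self.study_id!r}: cell {name!r} must be >= 0, got {v}"
                )
        if self.total == 0:
            raise ValidationError(f"study {self.study_id!r}: all four cells are zero")
        if self.design is not None and self.design not in _DESIGNS:
            raise ValidationError(
                f"study {self.study_id!r}: design must be one of {_DESIGNS}, got {self.design!r}"
            )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return min(self.tp, self.fp, self.fn, self.tn) == 0


@dataclass(frozen=True)
class CorrectedCounts:
    """Possibly continuity-corrected cell counts, with the raw integers kept.

    ``corrected`` is True iff ``correction_value`` was added to every cell.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    corrected: bool = False
    correction_value: float = 0.5
    raw_tp: int | None = None
    raw_fp: int | None = None
    raw_fn: int | None = None
    raw_tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"corrected cell {name!r} must be >= 0")

    @property
    def has_zero_cell(self) -> bool:
        return min(self.tp, self.fp, self.fn, self.tn) == 0

    def raw(self) -> tuple[float, float, float, float]:
        """Raw cells if known, else the stored (uncorrected) cells."""
        if self.raw_tp is None:
            return (self.tp, self.fp, self.fn, self.tn)
        return (self.raw_tp, self.raw_fp, self.raw_fn, self.raw_tn)


@dataclass(frozen=True)
class AccuracyMeasures:
    """Per-study accuracy measures with variances and confidence intervals.

    ``sens``/``spec`` are computed from the raw cells; ``plr``/``nlr``/``dor``
    and the logit/log variances from the (possibly corrected) cells, so they
    are always finite after correction.  CIs are Clopper-Pearson exact for
    sens/spec and log-scale Wald for the ratio measures.
    """

    sens: float
    spec: float
    fpr: float
    plr: float
    nlr: float
    dor: float
    var_logit_sens: float
    var_logit_fpr: float
    var_log_dor: float
    ci_level: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    plr_ci: tuple[float, float]
    nlr_ci: tuple[float, float]
    dor_ci: tuple[float, float]


def _coerce_count(value, row_label: str, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_label}: field {column!r} is not a number: {value!r}")
    if math.isnan(f):
        raise ValidationError(f"row {row_label}: field {column!r} is missing")
    if f != int(f):
        raise ValidationError(f"row {row_label}: field {column!r} must be an integer, got {value!r}")
    if f < 0:
        raise ValidationError(f"row {row_label}: field {column!r} must be >= 0, got {value!r}")
    return int(f)


def read_studies(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[StudyRecord]:
    """Read study records from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row.  Required columns: ``study_id``,
        ``test_label``, ``tp``, ``fp``, ``fn``, ``tn``.  Optional: ``year``,
        ``design``.
    schema
        Optional map from canonical column name to the name used in the file,
        e.g. ``{"tp": "true_pos"}``.

    Returns
    -------
    list of StudyRecord, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = dict(schema) if schema else {}
    colmap = {canon: rename.get(canon, canon) for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    missing = [colmap[c] for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        label = f"{idx + 2}"  # 1-based, counting the header line
        study_id = str(row[colmap["study_id"]]).strip()
        test_label = str(row[colmap["test_label"]]).strip()
        if not study_id:
            raise ValidationError(f"row {label}: empty study_id")
        key = (study_id, test_label)
        if key in seen:
            raise ValidationError(
                f"row {label}: duplicate (study_id, test_label) pair {key!r}"
            )
        seen.add(key)
        cells = {c: _coerce_count(row[colmap[c]], label, c) for c in ("tp", "fp", "fn", "tn")}
        year = None
        if colmap["year"] in df.columns:
            raw_year = str(row[colmap["year"]]).strip()
            if raw_year:
                year = _coerce_count(raw_year, label, "year")
        design = None
        if colmap["design"] in df.columns:
            raw_design = str(row[colmap["design"]]).strip().lower()
            design = raw_design or None
        records.append(
            StudyRecord(study_id=study_id, test_label=test_label, year=year, design=design, **cells)
        )
    return records


def studies_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    """Tabulate records in the same schema :func:`read_studies` accepts."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "year": r.year,
                "test_label": r.test_label,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
                "design": r.design,
            }
        )
    return pd.DataFrame(rows, columns=["study_id", "year", "test_label", "tp", "fp", "fn", "tn", "design"])


def write_studies(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Serialize records to CSV (round-trips through :func:`read_studies`)."""
    studies_to_frame(records).to_csv(path, index=False)


def apply_continuity_correction(
    record: StudyRecord,
    mode: str = "affected_studies",
    value: float = 0.5,
) -> CorrectedCounts:
    """Apply a continuity correction to one study's cells.

    ``mode``:

    * ``"affected_studies"`` — add ``value`` to all four cells iff any cell is
      zero (the Meta-DiSc convention, the default);
    * ``"all_studies"`` — always add ``value``;
    * ``"never"`` — pass the raw counts through unchanged.  Callers that then
      request logits on a zero-cell table get a :class:`ZeroCellError`.
    """
    if value <= 0:
        raise ValidationError(f"correction value must be > 0, got {value}")
    if mode not in ("affected_studies", "all_studies", "never"):
        raise ValidationError(f"unknown continuity-correction mode {mode!r}")
    correct = mode == "all_studies" or (mode == "affected_studies" and record.has_zero_cell)
    add = value if correct else 0.0
    return CorrectedCounts(
        tp=record.tp + add,
        fp=record.fp + add,
        fn=record.fn + add,
        tn=record.tn + add,
        corrected=correct,
        correction_value=value,
        raw_tp=record.tp,
        raw_fp=record.fp,
        raw_fn=record.fn,
        raw_tn=record.tn,
    )


def _clopper_pearson(x: float, n: float, ci_level: float) -> tuple[float, float]:
    # Exact binomial CI; accepts non-integer x from corrected tables by
    # using the beta-quantile form directly.
    alpha = 1.0 - ci_level
    lo = 0.0 if x <= 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x >= n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return (lo, hi)


def per_study_measures(counts: CorrectedCounts, ci_level: float = 0.95) -> AccuracyMeasures:
    """Compute one study's accuracy measures from (corrected) cell counts.

    Ratio measures and variances need strictly positive cells; a zero cell
    (i.e. correction mode ``never`` on an affected study) raises
    :class:`ZeroCellError`.
    """
    if not 0 < ci_level < 1:
        raise ValidationError(f"ci_level must be in (0, 1), got {ci_level}")
    if counts.has_zero_cell:
        raise ZeroCellError(
            "zero cell in 2x2 table: ratio measures and logit variances are undefined; "
            "apply a continuity correction first"
        )
    rtp, rfp, rfn, rtn = counts.raw()
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn

    sens = rtp / (rtp + rfn)
    spec = rtn / (rtn + rfp)
    fpr = 1.0 - spec

    # Ratio measures from corrected cells so they are finite.
    c_sens = tp / (tp + fn)
    c_fpr = fp / (fp + tn)
    plr = c_sens / c_fpr
    nlr = (1.0 - c_sens) / (1.0 - c_fpr)
    dor = (tp * tn) / (fp * fn)

    var_logit_sens = 1.0 / tp + 1.0 / fn
    var_logit_fpr = 1.0 / fp + 1.0 / tn
    var_log_dor = 1.0 / tp + 1.0 / fp + 1.0 / fn + 1.0 / tn
    var_log_plr = (1.0 - c_sens) / (c_sens * (tp + fn)) + (1.0 - c_fpr) / (c_fpr * (fp + tn))
    var_log_nlr = c_sens / ((1.0 - c_sens) * (tp + fn)) + c_fpr / ((1.0 - c_fpr) * (fp + tn))

    z = float(stats.norm.ppf(0.5 + ci_level / 2))

    def log_wald(est: float, var: float) -> tuple[float, float]:
        half = z * math.sqrt(var)
        return (est * math.exp(-half), est * math.exp(half))

    return AccuracyMeasures(
        sens=sens,
        spec=spec,
        fpr=fpr,
        plr=plr,
        nlr=nlr,
        dor=dor,
        var_logit_sens=var_logit_sens,
        var_logit_fpr=var_logit_fpr,
        var_log_dor=var_log_dor,
        ci_level=ci_level,
        sens_ci=_clopper_pearson(rtp, rtp + rfn, ci_level),
        spec_ci=_clopper_pearson(rtn, rtn + rfp, ci_level),
        plr_ci=log_wald(plr, var_log_plr),
        nlr_ci=log_wald(nlr, var_log_nlr),
        dor_ci=log_wald(dor, var_log_dor),
    )
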