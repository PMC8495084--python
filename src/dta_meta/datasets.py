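"""Packaged example data.

The package ships the per-study enrolment table of the eight published
studies that compared intracardiac (ICE) against transesophageal (TEE)
echocardiography for left-atrial-appendage thrombus in the same patients.

The corresponding per-study 2x2 cell counts were published only in a
supplementary appendix that is not redistributable here, so
:func:`load_laa_counts` raises with an explanation; analyses of real data
must supply their own CSV in the :func:`dta_meta.studies.read_studies`
schema.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DtaMetaError
from .studies import StudyRecord, read_studies

__all__ = ["load_laa_enrollment", "enrollment_totals", "load_laa_counts"]

_DATA = resources.files("dta_meta") / "data"

#: File that would hold the eight studies' 2x2 cells, were it available.
LAA_COUNTS_FILENAME = "laa_ice_tee_2x2.csv"


def load_laa_enrollment() -> pd.DataFrame:
    """Per-study enrolment of the eight ICE-vs-TEE studies.

    Columns: ``study_id``, ``year``, ``design``, ``n_ice``, ``n_tee``.
    """
    with resources.as_file(_DATA / "laa_ice_tee_enrollment.csv") as path:
        return pd.read_csv(path)


def enrollment_totals() -> dict[str, int]:
    """Arm and overall enrolment totals of the packaged eight-study table."""
    df = load_laa_enrollment()
    n_ice = int(df["n_ice"].sum())
    n_tee = int(df["n_tee"].sum())
    return {"ICE": n_ice, "TEE": n_tee, "total": n_ice + n_tee, "k": len(df)}


def load_laa_counts() -> list[StudyRecord]:
    """The eight studies' 2x2 tables — unavailable; raises with an explanation.

    If a transcription becomes available, drop it into the package data
    directory as ``laa_ice_tee_2x2.csv`` (schema: ``study_id, year,
    test_label, tp, fp, fn, tn``) and this loader will pick it up.
    """
    target = _DATA / LAA_COUNTS_FILENAME
    try:
        with resources.as_file(target) as path:
            if path.exists():
                return read_studies(path)
    except FileNotFoundError:
        pass
    raise DtaMetaError(
        "the per-study 2x2 cell counts of the eight ICE/TEE studies were published "
        "only in a supplementary appendix that this package cannot redistribute; "
        f"supply your own transcription as {LAA_COUNTS_FILENAME!r} in the package "
        "data directory, or load any CSV with dta_meta.studies.read_studies"
    )
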