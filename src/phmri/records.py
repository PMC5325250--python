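"""Per-patient record and cohort-table plumbing.

The cohort CSV has one row per patient with a fixed column order
(:data:`COHORT_COLUMNS`): imaging percentile features, lesion volumes,
clinical covariates, and the hemorrhage label.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["PatientRecord", "COHORT_COLUMNS", "cohort_to_frame", "frame_to_records"]

#: Fixed column order of the cohort CSV.
COHORT_COLUMNS = [
    "patient_id",
    "cbv_p10",
    "adc_p10",
    "k2_p90",
    "core_volume_ml",
    "tmax6_volume_ml",
    "penumbral_pattern",
    "global_reperfusion",
    "age",
    "sex",
    "hypertension",
    "diabetes",
    "sbp",
    "nihss",
    "iv_tpa",
    "thrombectomy",
    "ph_label",
]


@dataclass
class PatientRecord:
    """One patient's features, volumes, clinical covariates, and label.

    ``cbv_p10`` is dimensionless (ratio to contralateral), ``adc_p10`` in
    1e-6 mm^2/s, ``k2_p90`` a decimal fraction, volumes in mL, ``sbp`` in
    mm Hg, ``age`` in years. ``global_reperfusion`` and ``ph_label`` may
    be None when not available.
    """

    patient_id: str
    cbv_p10: float | None = None
    adc_p10: float | None = None
    k2_p90: float | None = None
    core_volume_ml: float | None = None
    tmax6_volume_ml: float | None = None
    penumbral_pattern: int | None = None
    global_reperfusion: int | None = None
    age: float | None = None
    sex: int | None = None
    hypertension: int | None = None
    diabetes: int | None = None
    sbp: float | None = None
    nihss: int | None = None
    iv_tpa: int | None = None
    thrombectomy: int | None = None
    ph_label: int | None = None

    def __post_init__(self) -> None:
        if self.adc_p10 is not None and self.adc_p10 < 0:
            raise ValueError(f"adc_p10 must be >= 0; got {self.adc_p10}")
        if self.core_volume_ml is not None and self.core_volume_ml < 0:
            raise ValueError(f"core_volume_ml must be >= 0; got {self.core_volume_ml}")
        for name in ("cbv_p10", "adc_p10", "k2_p90"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name} must be finite; got {v}")


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Cohort table with the documented column order."""
    rows = [asdict(r) for r in records]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in COHORT_COLUMNS:
            if col not in frame.columns:
                continue
            v = row[col]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                kwargs[col] = None
            elif col in ("patient_id",):
                kwargs[col] = str(v)
            elif col in (
                "penumbral_pattern", "global_reperfusion", "sex", "hypertension",
                "diabetes", "nihss", "iv_tpa", "thrombectomy", "ph_label",
            ):
                kwargs[col] = int(v)
            else:
                kwargs[col] = float(v)
        records.append(PatientRecord(**kwargs))
    return records
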