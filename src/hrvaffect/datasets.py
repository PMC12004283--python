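"""In-study demographic and enrollment fixtures.

The patient table (sex, age, etiology, clinical diagnosis, chronicity and
CRS-R score of the eleven analyzed patients with disorders of consciousness)
and the enrollment/exclusion accounting are the only study quantities that
are reproducible from printed inputs; they anchor the worked examples and
the demographics t-test.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["patients", "patient_ages", "healthy_summary", "cohort_accounting"]

_PATIENT_ROWS = [
    # id,  sex, age, etiology, diagnosis, days since injury, CRS-R
    ("P1", "M", 35, "Anoxia", "UWS", 817, 7),
    ("P2", "F", 32, "Anoxia", "UWS", 152, 8),
    ("P3", "F", 31, "Anoxia", "UWS", 281, 6),
    ("P4", "F", 19, "Anoxia", "UWS", 126, 5),
    ("P5", "M", 18, "Anoxia", "UWS", 676, 7),
    ("P6", "M", 57, "Anoxia", "UWS", 903, 8),
    ("P7", "F", 73, "TBI", "MCS", 117, 11),
    ("P8", "M", 25, "TBI", "MCS", 557, 10),
    ("P9", "M", 25, "TBI", "MCS", 2202, 12),
    ("P10", "F", 40, "TBI", "MCS", 8881, 13),
    ("P11", "M", 30, "TBI", "MCS", 210, 14),
]

_COLUMNS = ["patient", "sex", "age", "etiology", "diagnosis",
            "time_since_injury_days", "crs_r"]

#: Enrollment and loss per cohort: healthy subjects lost to recording
#: failures, patients discarded for detached electrodes / excessive noise.
_ACCOUNTING = {
    "HC": {"enrolled": 19, "excluded": 2},
    "DOC": {"enrolled": 22, "excluded": 11},
}


def patients() -> pd.DataFrame:
    """Demographic/clinical table of the analyzed patients (one row each)."""
    return pd.DataFrame(_PATIENT_ROWS, columns=_COLUMNS)


def patient_ages() -> np.ndarray:
    """Ages (years) of the analyzed patients."""
    return patients()["age"].to_numpy(dtype=float)


def healthy_summary() -> dict:
    """Reported descriptives of the analyzed healthy cohort."""
    return {"n": 17, "women": 9, "men": 8,
            "age_mean": 34.65, "age_sd": 11.65}


def cohort_accounting() -> dict:
    """Enrollment, exclusion and included counts per cohort."""
    out = {}
    for grp, d in _ACCOUNTING.items():
        out[grp] = {**d, "included": d["enrolled"] - d["excluded"]}
    return out
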