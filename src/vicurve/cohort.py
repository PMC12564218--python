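"""The analysis cohort container: VA profiles plus questionnaire scores."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional

import pandas as pd

from .profiles import VAProfile

VA_COLUMNS = ["patient_id", "distance_cm", "va_letters"]
QOL_COLUMNS = ["patient_id", "total_score", "near_activities", "distance_activities", "complete"]


@dataclass
class Cohort:
    """Paired per-patient VA measurements and quality-of-life scores.

    ``va`` is long-format (one row per patient and distance); ``qol`` has
    one row per patient with 0-100 scores and a completeness flag;
    ``covariates`` optionally carries demographics (age, gender, preop_se)
    for the quartile comparison. ``provenance`` records where the data came
    from (simulation parameters or source files).
    """

    va: pd.DataFrame
    qol: pd.DataFrame
    covariates: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in VA_COLUMNS if c not in self.va.columns]
        if missing:
            raise ValueError(f"VA table missing columns: {missing}")
        missing = [c for c in QOL_COLUMNS if c not in self.qol.columns]
        if missing:
            raise ValueError(f"QoL table missing columns: {missing}")
        bad = self.va["va_letters"]
        if ((bad < 0) | (bad > 100)).any():
            raise ValueError("VA values must lie within [0, 100] Letters")

    @property
    def patient_ids(self) -> List[str]:
        return list(self.qol["patient_id"])

    @property
    def n(self) -> int:
        return len(self.qol)

    def profiles(self) -> Iterator[VAProfile]:
        """Yield one :class:`VAProfile` per patient, in qol-table order."""
        grouped = {
            pid: g for pid, g in self.va.groupby("patient_id", sort=False)
        }
        for pid in self.patient_ids:
            g = grouped.get(pid)
            if g is None:
                continue
            yield VAProfile.from_pairs(
                str(pid), zip(g["distance_cm"], g["va_letters"])
            )

    def subset(self, patient_ids) -> "Cohort":
        keep = set(patient_ids)
        cov = None
        if self.covariates is not None:
            cov = self.covariates[self.covariates["patient_id"].isin(keep)].reset_index(drop=True)
        return Cohort(
            va=self.va[self.va["patient_id"].isin(keep)].reset_index(drop=True),
            qol=self.qol[self.qol["patient_id"].isin(keep)].reset_index(drop=True),
            covariates=cov,
            provenance=dict(self.provenance),
        )
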