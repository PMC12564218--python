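"""NEI-VFQ-25 scoring and complete-case filtering.

The National Eye Institute Visual Functioning Questionnaire (NEI-VFQ-25)
is a 25-item patient-reported outcome instrument. Each ordinal response is
linearly recoded to a 0-100 scale (100 = best visual function), subscale
scores are means of their non-missing recoded items, and the composite
(total) score is the unweighted mean of the eleven vision-targeted
subscales — the single general-health item is excluded. The recode table
and subscale membership are bundled as ``data/nei_vfq25_items.csv``.

Analysis is complete-case: a record counts as complete only when every
item carries a scoreable response, which in particular requires all
near-activities and distance-activities items to be answered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import EmptyCohortError
from .profiles import DISTANCES_9

logger = logging.getLogger(__name__)

GENERAL_HEALTH = "general_health"


def _load_table() -> pd.DataFrame:
    with resources.files("vicurve.data").joinpath("nei_vfq25_items.csv").open("rb") as fh:
        return pd.read_csv(fh, dtype={"item_id": str, "subscale": str, "response": int})


_TABLE = _load_table()
#: recoded 0-100 value per (item, response); NaN = response treated as missing
RECODE: Dict[tuple, float] = {
    (r.item_id, int(r.response)): float(r.score) if pd.notna(r.score) else np.nan
    for r in _TABLE.itertuples()
}
ITEM_SUBSCALE: Dict[str, str] = dict(zip(_TABLE["item_id"], _TABLE["subscale"]))
ALL_ITEMS = tuple(dict.fromkeys(_TABLE["item_id"]))
VISION_SUBSCALES = tuple(
    s for s in dict.fromkeys(_TABLE["subscale"]) if s != GENERAL_HEALTH
)


@dataclass(frozen=True)
class QoLRecord:
    """One patient's NEI-VFQ-25 scores (0-100; higher = better function)."""

    patient_id: str
    total_score: float
    near_activities: float
    distance_activities: float
    complete: bool
    subscales: Optional[Dict[str, float]] = None


def score_nei_vfq(
    item_responses: Mapping[str, Optional[int]],
    patient_id: str = "",
) -> QoLRecord:
    """Score one questionnaire from item responses.

    ``item_responses`` maps item ids (``q1`` ... ``q25``, with the driving
    items ``q15c``/``q16``/``q16a``) to ordinal response levels; ``None``
    marks an unanswered item. Unknown ids or out-of-range responses raise
    ``ValueError`` naming the offender.
    """
    recoded: Dict[str, float] = {}
    for item, resp in item_responses.items():
        if item not in ITEM_SUBSCALE:
            raise ValueError(f"unknown NEI-VFQ-25 item id {item!r}")
        if resp is None:
            recoded[item] = np.nan
            continue
        key = (item, int(resp))
        if key not in RECODE:
            raise ValueError(f"response {resp!r} out of range for item {item!r}")
        recoded[item] = RECODE[key]

    # items never mentioned count as missing
    values = {item: recoded.get(item, np.nan) for item in ALL_ITEMS}

    subscale_scores: Dict[str, float] = {}
    for sub in dict.fromkeys(ITEM_SUBSCALE.values()):
        vals = [values[i] for i, s in ITEM_SUBSCALE.items() if s == sub]
        arr = np.asarray(vals, float)
        subscale_scores[sub] = float(np.nanmean(arr)) if np.isfinite(arr).any() else np.nan

    vision = [subscale_scores[s] for s in VISION_SUBSCALES if np.isfinite(subscale_scores[s])]
    total = float(np.mean(vision)) if vision else np.nan
    complete = all(np.isfinite(values[i]) for i in ALL_ITEMS)
    return QoLRecord(
        patient_id=patient_id,
        total_score=total,
        near_activities=subscale_scores["near_activities"],
        distance_activities=subscale_scores["distance_activities"],
        complete=complete,
        subscales=subscale_scores,
    )


def score_items_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Score a long item-level table ``patient_id,item_id,response``."""
    records = []
    for pid, g in items.groupby("patient_id", sort=False):
        resp = dict(zip(g["item_id"], g["response"]))
        rec = score_nei_vfq(resp, patient_id=str(pid))
        records.append(
            (rec.patient_id, rec.total_score, rec.near_activities,
             rec.distance_activities, rec.complete)
        )
    return pd.DataFrame(
        records,
        columns=["patient_id", "total_score", "near_activities",
                 "distance_activities", "complete"],
    )


def filter_complete(
    cohort: Cohort,
    required_distances: Sequence[float] = DISTANCES_9,
) -> Cohort:
    """Keep patients with a complete questionnaire and a full VA grid.

    Mirrors the inclusion rule of a complete-case analysis: any missing
    questionnaire response or missing test distance excludes the patient.
    Removal counts and reasons are logged. Idempotent.
    """
    qol = cohort.qol
    complete_ids = set(qol.loc[qol["complete"].astype(bool), "patient_id"])
    incomplete = cohort.n - len(complete_ids)

    required = set(float(d) for d in required_distances)
    counts = cohort.va.groupby("patient_id")["distance_cm"].apply(
        lambda s: required.issubset(set(s.astype(float)))
    )
    full_va_ids = set(counts[counts].index)
    missing_va = [pid for pid in complete_ids if pid not in full_va_ids]

    keep = [pid for pid in qol["patient_id"] if pid in complete_ids and pid in full_va_ids]
    if incomplete:
        logger.info("filter_complete: removed %d patient(s): incomplete questionnaire", incomplete)
    if missing_va:
        logger.info(
            "filter_complete: removed %d patient(s): missing distance in VA profile (%s)",
            len(missing_va), ", ".join(map(str, missing_va[:10])),
        )
    if not keep:
        raise EmptyCohortError("no patients remain after complete-case filtering")
    return cohort.subset(keep)
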