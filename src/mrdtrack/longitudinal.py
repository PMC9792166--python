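"""Serial-sample monitoring: molecular relapse, lead time, CEA, swimmer export.

Each patient contributes an ordered timeline of plasma draws around a
curative-intent surgery.  Molecular relapse is the earliest
post-operative ctDNA-positive sample; lead time is how far it precedes
the clinical (imaging/biopsy) relapse diagnosis, in months of 30.4375
days.  Serum CEA below 5 ng/mL is considered normal.

Samples drawn on the surgery date itself count as pre-operative
(pre-op draws happen up to the day of surgery); indeterminate ctDNA
calls are skipped, never treated as negative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

from .plasma_mrd import CallStatus, CtdnaCall

__all__ = [
    "CeaStatus",
    "TimelineSample",
    "TreatmentWindow",
    "PatientTimeline",
    "MonitoringVerdict",
    "CEA_NORMAL_MAX",
    "DAYS_PER_MONTH",
    "classify_cea",
    "months_between",
    "detect_molecular_relapse",
    "lead_time",
    "monitor",
    "swimmer_export",
]

#: CEA below this (ng/mL) is normal; at/above is elevated
CEA_NORMAL_MAX = 5.0
#: calendar-neutral month length used for fractional-month intervals
DAYS_PER_MONTH = 30.4375


class CeaStatus(str, enum.Enum):
    NORMAL = "normal"
    ELEVATED = "elevated"


def classify_cea(value_ng_per_ml: float) -> CeaStatus:
    """CEA status: < 5 ng/mL normal, >= 5 ng/mL elevated."""
    if value_ng_per_ml < 0:
        raise ValueError("CEA cannot be negative")
    return (
        CeaStatus.NORMAL
        if value_ng_per_ml < CEA_NORMAL_MAX
        else CeaStatus.ELEVATED
    )


def months_between(start: date, end: date) -> float:
    """Signed interval ``end - start`` in months of 30.4375 days."""
    return (end - start).days / DAYS_PER_MONTH


@dataclass(frozen=True)
class TimelineSample:
    """One plasma draw: date, ctDNA call, optional paired CEA value."""

    date: date
    call: CtdnaCall
    cea_ng_per_ml: float | None = None


@dataclass(frozen=True)
class TreatmentWindow:
    start: date
    end: date
    label: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("treatment window ends before it starts")


@dataclass(frozen=True)
class PatientTimeline:
    """Ordered clinical/molecular events for one patient."""

    patient_id: str
    surgery_date: date
    samples: tuple[TimelineSample, ...]
    clinical_relapse_date: date | None = None
    adjuvant_windows: tuple[TreatmentWindow, ...] = ()

    def __post_init__(self) -> None:
        dates = [s.date for s in self.samples]
        if any(a >= b for a, b in zip(dates, dates[1:])):
            raise ValueError("samples must be strictly ordered by date")
        if (
            self.clinical_relapse_date is not None
            and self.clinical_relapse_date <= self.surgery_date
        ):
            raise ValueError("clinical relapse must postdate surgery")

    @property
    def preop_samples(self) -> tuple[TimelineSample, ...]:
        """Samples on or before the surgery date."""
        return tuple(s for s in self.samples if s.date <= self.surgery_date)

    @property
    def postop_samples(self) -> tuple[TimelineSample, ...]:
        return tuple(s for s in self.samples if s.date > self.surgery_date)


@dataclass(frozen=True)
class MonitoringVerdict:
    """Summary of one patient's molecular monitoring."""

    patient_id: str
    molecular_relapse_date: date | None
    lead_time_months: float | None
    cea_elevated_at_molecular_relapse: bool | None
    negative_lead_time: bool = False

    def __post_init__(self) -> None:
        both = (
            self.molecular_relapse_date is not None
            and self.lead_time_months is not None
        )
        neither = self.lead_time_months is None
        if not (both or neither):
            raise ValueError(
                "lead time requires a molecular relapse date"
            )


def detect_molecular_relapse(timeline: PatientTimeline) -> date | None:
    """Date of the earliest post-operative ctDNA-positive sample.

    Pre-operative positivity never qualifies (it reflects the primary
    tumor, not residual disease).  Indeterminate calls are skipped.
    Returns ``None`` when every post-operative call is negative or
    indeterminate; raises when there are no post-operative samples at
    all.
    """
    postop = timeline.postop_samples
    if not postop:
        raise ValueError(
            f"patient {timeline.patient_id} has no post-operative samples"
        )
    for sample in postop:
        if sample.call.status is CallStatus.POSITIVE:
            return sample.date
    return None


def lead_time(timeline: PatientTimeline) -> float | None:
    """Months by which molecular relapse precedes clinical relapse.

    ``(clinical - molecular)`` in 30.4375-day months; ``None`` when
    either date is missing.  Negative values (molecular call after
    clinical diagnosis) are permitted and surfaced by
    :func:`monitor`.
    """
    if timeline.clinical_relapse_date is None:
        return None
    molecular = detect_molecular_relapse(timeline)
    if molecular is None:
        return None
    return months_between(molecular, timeline.clinical_relapse_date)


def monitor(timeline: PatientTimeline) -> MonitoringVerdict:
    """Full monitoring verdict for one patient."""
    molecular = detect_molecular_relapse(timeline)
    lt = lead_time(timeline)
    cea_at_molecular: bool | None = None
    if molecular is not None:
        for s in timeline.samples:
            if s.date == molecular and s.cea_ng_per_ml is not None:
                cea_at_molecular = (
                    classify_cea(s.cea_ng_per_ml) is CeaStatus.ELEVATED
                )
    return MonitoringVerdict(
        patient_id=timeline.patient_id,
        molecular_relapse_date=molecular,
        lead_time_months=lt,
        cea_elevated_at_molecular_relapse=cea_at_molecular,
        negative_lead_time=lt is not None and lt < 0,
    )


def swimmer_export(timelines: Sequence[PatientTimeline]) -> pd.DataFrame:
    """Flatten timelines into a plot-ready event table.

    One row per (patient, event): every sample with its call and CEA,
    one clinical-relapse marker when present, and one row per
    treatment window.  Dates are expressed in months from surgery;
    rows are sorted by patient then date.
    """
    if not timelines:
        raise ValueError("no timelines to export")
    rows = []
    for tl in timelines:
        for s in tl.samples:
            rows.append(
                {
                    "patient_id": tl.patient_id,
                    "event": "sample",
                    "months_from_surgery": months_between(
                        tl.surgery_date, s.date
                    ),
                    "status": s.call.status.value,
                    "mean_vaf": (
                        math.nan if s.call.mean_vaf is None else s.call.mean_vaf
                    ),
                    "cea_ng_per_ml": (
                        math.nan if s.cea_ng_per_ml is None else s.cea_ng_per_ml
                    ),
                    "label": "preop" if s.date <= tl.surgery_date else "postop",
                }
            )
        if tl.clinical_relapse_date is not None:
            rows.append(
                {
                    "patient_id": tl.patient_id,
                    "event": "clinical_relapse",
                    "months_from_surgery": months_between(
                        tl.surgery_date, tl.clinical_relapse_date
                    ),
                    "status": "",
                    "mean_vaf": math.nan,
                    "cea_ng_per_ml": math.nan,
                    "label": "",
                }
            )
        for w in tl.adjuvant_windows:
            rows.append(
                {
                    "patient_id": tl.patient_id,
                    "event": "treatment",
                    "months_from_surgery": months_between(
                        tl.surgery_date, w.start
                    ),
                    "status": "",
                    "mean_vaf": math.nan,
                    "cea_ng_per_ml": math.nan,
                    "label": w.label,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["patient_id", "months_from_surgery"], kind="stable"
    ).reset_index(drop=True)


def verdicts_to_frame(verdicts: Iterable[MonitoringVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "molecular_relapse_date": (
                    "" if v.molecular_relapse_date is None
                    else v.molecular_relapse_date.isoformat()
                ),
                "lead_time_months": (
                    math.nan if v.lead_time_months is None else v.lead_time_months
                ),
                "cea_elevated_at_molecular_relapse": (
                    "" if v.cea_elevated_at_molecular_relapse is None
                    else str(v.cea_elevated_at_molecular_relapse).lower()
                ),
                "negative_lead_time": str(v.negative_lead_time).lower(),
            }
            for v in verdicts
        ]
    )
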