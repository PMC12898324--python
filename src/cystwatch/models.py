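"""Domain types for side-branch IPMN surveillance cohorts.

A cohort is a list of patients; each patient carries demographics,
comorbidities, an ordered longitudinal series of imaging observations of the
leading cyst and pancreatic duct, and the management events that actually
happened (imaging, surgical referral/resection, surveillance cessation).
All enums serialize as lower-snake-case strings; dates are ISO-8601.
"""

from __future__ import annotations

import datetime as dt
import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

DAYS_PER_MONTH = 30.4375  # mean Gregorian month; all intervals are in months


def months_between(start: dt.date, end: dt.date) -> float:
    """Elapsed time from ``start`` to ``end`` in (fractional) months."""
    return (end - start).days / DAYS_PER_MONTH


def add_months(start: dt.date, months: float) -> dt.date:
    return start + dt.timedelta(days=round(months * DAYS_PER_MONTH))


class Modality(str, enum.Enum):
    MRI_MRCP = "mri_mrcp"
    EUS = "eus"
    CT = "ct"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Comorbidity(str, enum.Enum):
    DIABETES_OR_IFG = "diabetes_or_ifg"
    SMOKER = "smoker"
    ALCOHOL = "alcohol"
    PANCREATITIS_HISTORY = "pancreatitis_history"
    LIVER_BILIARY_DISEASE = "liver_biliary_disease"
    FAMILY_HISTORY_PANCREATITIS = "family_history_pancreatitis"
    NON_GI_MALIGNANCY = "non_gi_malignancy"
    GI_MALIGNANCY = "gi_malignancy"
    CHOLELITHIASIS_CCY = "cholelithiasis_ccy"
    PSC = "psc"
    PANCREAS_DIVISUM = "pancreas_divisum"
    CHRONIC_PANCREATITIS = "chronic_pancreatitis"


class EventType(str, enum.Enum):
    IMAGING_MRI_MRCP = "imaging_mri_mrcp"
    IMAGING_EUS = "imaging_eus"
    IMAGING_CT = "imaging_ct"
    SURGERY_REFERRAL = "surgery_referral"
    SURGERY_PERFORMED = "surgery_performed"
    SURVEILLANCE_STOPPED = "surveillance_stopped"


IMAGING_EVENTS = frozenset(
    {EventType.IMAGING_MRI_MRCP, EventType.IMAGING_EUS, EventType.IMAGING_CT}
)
SURGERY_EVENTS = frozenset({EventType.SURGERY_REFERRAL, EventType.SURGERY_PERFORMED})

EVENT_MODALITY = {
    EventType.IMAGING_MRI_MRCP: Modality.MRI_MRCP,
    EventType.IMAGING_EUS: Modality.EUS,
    EventType.IMAGING_CT: Modality.CT,
}


class CystObservation(BaseModel):
    """One dated imaging assessment of the cyst/duct features of a patient.

    Optional clinical fields (``mpd_diameter``, ``mural_nodule_size``,
    ``ca19_9``) left as ``None`` are interpreted downstream as "feature not
    demonstrated".
    """

    observation_date: dt.date
    leading_cyst_size: float = Field(gt=0, description="mm, largest cyst")
    n_cysts: int = Field(default=1, ge=1)
    mpd_diameter: Optional[float] = Field(default=None, ge=0, description="mm")
    mural_nodule_size: Optional[float] = Field(default=None, gt=0, description="mm")
    mural_nodule_enhancing: Optional[bool] = None
    wall_thickened: bool = False
    abrupt_duct_change: bool = False
    lymphadenopathy: bool = False
    obstructive_jaundice: bool = False
    ca19_9: Optional[float] = Field(default=None, ge=0, description="U/mL")
    acute_pancreatitis_episode: bool = False
    new_onset_diabetes: bool = False
    modality: Modality = Modality.MRI_MRCP


class ManagementEvent(BaseModel):
    event_date: dt.date
    event_type: EventType

    @property
    def is_imaging(self) -> bool:
        return self.event_type in IMAGING_EVENTS

    @property
    def is_surgery(self) -> bool:
        return self.event_type in SURGERY_EVENTS


class PatientRecord(BaseModel):
    """Demographics, observation series, actual management, and outcome.

    ``radiological_followup_months`` and ``clinical_followup_months`` are
    independent clocks; neither bounds the other.
    """

    patient_id: str
    age_at_index: float = Field(ge=18, description="years; adults only")
    sex: Sex
    surgically_fit: bool = True
    limited_life_expectancy: bool = False
    comorbidities: set[Comorbidity] = Field(default_factory=set)
    observations: list[CystObservation] = Field(min_length=1)
    management_events: list[ManagementEvent] = Field(default_factory=list)
    outcome_pdac: bool = False
    outcome_pdac_date: Optional[dt.date] = None
    clinical_followup_months: float = Field(ge=0)
    radiological_followup_months: float = Field(ge=0)

    @model_validator(mode="after")
    def _check_series(self) -> "PatientRecord":
        dates = [o.observation_date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"patient {self.patient_id}: observation dates must be strictly increasing"
            )
        if self.observations[0].modality is not Modality.MRI_MRCP:
            raise ValueError(
                f"patient {self.patient_id}: index observation must be MRI/MRCP"
            )
        ev = [e.event_date for e in self.management_events]
        if any(b < a for a, b in zip(ev, ev[1:])):
            raise ValueError(
                f"patient {self.patient_id}: management event dates must be non-decreasing"
            )
        return self

    @property
    def index_date(self) -> dt.date:
        return self.observations[0].observation_date

    def observation_at(self, at: dt.date) -> Optional[CystObservation]:
        """Most recent observation on or before ``at`` (None if none)."""
        latest = None
        for obs in self.observations:
            if obs.observation_date <= at:
                latest = obs
        return latest

    def events_after_index(self) -> list[ManagementEvent]:
        return [e for e in self.management_events if e.event_date > self.index_date]


class Cohort(BaseModel):
    patients: list[PatientRecord] = Field(default_factory=list)
    provenance: str = ""

    @field_validator("patients")
    @classmethod
    def _unique_ids(cls, patients: list[PatientRecord]) -> list[PatientRecord]:
        ids = [p.patient_id for p in patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids: {dupes}")
        return patients

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)
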