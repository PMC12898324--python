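"""Concordance audit: actual management versus the rule engine.

Each patient's first post-index management decision is compared with the
engine's recommendation at the index scan and classified as concordant,
over-surveillance (more intensive than recommended: earlier imaging,
escalated modality, or surgery when surveillance sufficed) or
under-surveillance (later or omitted imaging, surveillance stopped, or
surveillance when surgery was indicated). Patients whose follow-up is too
short to adjudicate are reported as indeterminate and excluded from the
partition denominator, never silently dropped.

The imaging-burden metric compares the whole observed follow-up against a
counterfactual guideline schedule that re-evaluates the engine at every
scheduled visit against the patient's observed trajectory state.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional

from pydantic import BaseModel, Field

from .engine import Action, Recommendation, recommend
from .models import (
    Cohort,
    EventType,
    EVENT_MODALITY,
    IMAGING_EVENTS,
    Modality,
    PatientRecord,
    add_months,
    months_between,
)
from .policy import DecisionPolicy

logger = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12.0

# modality escalation ordering: CT and MRI/MRCP are cross-sectional peers,
# EUS is the escalation modality
MODALITY_INTENSITY = {Modality.CT: 0, Modality.MRI_MRCP: 0, Modality.EUS: 1}


class ConcordanceClass(str, enum.Enum):
    CONCORDANT = "concordant"
    OVER = "over"
    UNDER = "under"
    INDETERMINATE = "indeterminate"


class TolerancePolicy(BaseModel):
    """Scheduling jitter tolerated before a follow-up interval counts as
    non-concordant: +/- max(pct of the recommended interval, months).
    ``surgery_grace_months`` bounds how long a recommended referral may take.
    With ``modality_strict`` EUS in place of MRI (or vice versa) at the
    right time is non-concordant; by default both count as surveillance."""

    interval_pct: float = Field(default=25.0, ge=0)
    interval_months: float = Field(default=3.0, ge=0)
    surgery_grace_months: float = Field(default=6.0, gt=0)
    modality_strict: bool = False

    def half_width(self, interval_months: float) -> float:
        return max(interval_months * self.interval_pct / 100.0, self.interval_months)


class AuditResult(BaseModel):
    patient_id: str
    concordance_class: ConcordanceClass
    recommended: Recommendation
    observed_first_action: Optional[str] = None
    observed_imaging_count: int = 0
    expected_imaging_count: int = 0
    excess_per_patient_year: Optional[float] = None
    followup_patient_years: float = 0.0


class CohortAuditSummary(BaseModel):
    n_total: int
    n_concordant: int
    n_over: int
    n_under: int
    n_indeterminate: int = 0
    pct_concordant: Optional[float] = None
    pct_over: Optional[float] = None
    pct_under: Optional[float] = None
    mean_excess_per_patient_year: Optional[float] = None
    over_group_excess_per_patient_year: Optional[float] = None
    total_patient_years: float = 0.0
    pdac_events: int = 0
    pdac_incidence_pct_per_patient_year: Optional[float] = None


def partition_percentages(counts: list[int], decimals: int = 1) -> list[float]:
    """Class percentages from raw counts, rounded to ``decimals``."""
    total = sum(counts)
    if total == 0:
        raise ValueError("empty partition: no classified patients")
    return [round(100.0 * c / total, decimals) for c in counts]


def incidence_per_patient_year(events: int, patient_years: float) -> float:
    """Incidence as percent per patient-year, to two decimals."""
    if patient_years <= 0:
        raise ValueError("patient_years must be positive")
    return round(100.0 * events / patient_years, 2)


def classify_patient(
    patient: PatientRecord,
    recommendation: Recommendation,
    tolerance: Optional[TolerancePolicy] = None,
) -> ConcordanceClass:
    """Classify the first post-index management decision against the
    recommendation computed at the index observation date."""
    tol = tolerance or TolerancePolicy()
    events = patient.events_after_index()
    first = events[0] if events else None
    followup = patient.radiological_followup_months

    if recommendation.action is Action.SURGERY_REFERRAL:
        if first is None:
            if followup < tol.surgery_grace_months:
                logger.info("patient %s: indeterminate (short follow-up)", patient.patient_id)
                return ConcordanceClass.INDETERMINATE
            return ConcordanceClass.UNDER
        if first.is_surgery:
            delay = months_between(patient.index_date, first.event_date)
            if delay <= tol.surgery_grace_months:
                return ConcordanceClass.CONCORDANT
            return ConcordanceClass.UNDER
        # any surveillance (or cessation) instead of the indicated surgery
        return ConcordanceClass.UNDER

    # a surveillance recommendation with interval T and tolerance +/- w
    interval = recommendation.interval_months
    assert interval is not None
    width = tol.half_width(interval)

    if first is None:
        if followup < interval + width:
            logger.info("patient %s: indeterminate (short follow-up)", patient.patient_id)
            return ConcordanceClass.INDETERMINATE
        return ConcordanceClass.UNDER
    if first.is_surgery:
        return ConcordanceClass.OVER
    if first.event_type is EventType.SURVEILLANCE_STOPPED:
        return ConcordanceClass.UNDER

    when = months_between(patient.index_date, first.event_date)
    if when < interval - width:
        return ConcordanceClass.OVER
    if when > interval + width:
        return ConcordanceClass.UNDER
    if tol.modality_strict and recommendation.modality is not None:
        observed = MODALITY_INTENSITY[EVENT_MODALITY[first.event_type]]
        wanted = MODALITY_INTENSITY[recommendation.modality]
        if observed > wanted:
            return ConcordanceClass.OVER
        if observed < wanted:
            return ConcordanceClass.UNDER
    return ConcordanceClass.CONCORDANT


def expected_imaging_count(
    patient: PatientRecord, policy: DecisionPolicy, mri_only: bool = False
) -> int:
    """Number of scans the guideline schedule would have produced during the
    patient's radiological follow-up window.

    Walks the window from the index scan: at each scheduled visit the engine
    is re-evaluated against the observed trajectory state at that time, one
    scan is accrued, and the clock advances by the then-current interval.
    A visit falling exactly at the window end is counted. A surgical
    recommendation stops scheduling. With ``mri_only`` only visits whose
    scheduled modality is MRI/MRCP are counted (the walk still advances
    through EUS visits), matching the MRI-only observed count.
    """
    window = patient.radiological_followup_months
    if window <= 0:
        return 0
    t = 0.0
    visit_number = 0
    count = 0
    while True:
        rec = recommend(
            patient, add_months(patient.index_date, t), policy, visit_number=visit_number
        )
        if rec.action is Action.SURGERY_REFERRAL:
            break
        assert rec.interval_months is not None
        t_next = t + rec.interval_months
        if t_next > window + 1e-9:
            break
        if not mri_only or rec.modality is Modality.MRI_MRCP:
            count += 1
        t = t_next
        visit_number += 1
    return count


def observed_imaging_count(patient: PatientRecord, mri_only: bool = True) -> int:
    """Post-index imaging events; by default MRI/MRCP only, matching the
    burden metric's unit (MRI/MRCPs per patient-year)."""
    kinds = {EventType.IMAGING_MRI_MRCP} if mri_only else IMAGING_EVENTS
    return sum(1 for e in patient.events_after_index() if e.event_type in kinds)


def audit_patient(
    patient: PatientRecord,
    policy: DecisionPolicy,
    tolerance: Optional[TolerancePolicy] = None,
    mri_only: bool = True,
) -> AuditResult:
    rec = recommend(patient, patient.index_date, policy, visit_number=0)
    cls = classify_patient(patient, rec, tolerance)
    observed = observed_imaging_count(patient, mri_only=mri_only)
    expected = expected_imaging_count(patient, policy, mri_only=mri_only)
    years = patient.radiological_followup_months / MONTHS_PER_YEAR
    excess = (observed - expected) / years if years > 0 else None
    events = patient.events_after_index()
    first = events[0].event_type.value if events else None
    return AuditResult(
        patient_id=patient.patient_id,
        concordance_class=cls,
        recommended=rec,
        observed_first_action=first,
        observed_imaging_count=observed,
        expected_imaging_count=expected,
        excess_per_patient_year=excess,
        followup_patient_years=years,
    )


def audit_cohort(
    cohort: Cohort,
    policy: DecisionPolicy,
    tolerance: Optional[TolerancePolicy] = None,
    mri_only: bool = True,
) -> tuple[list[AuditResult], CohortAuditSummary]:
    """Audit every patient and summarize the three-class partition, the
    imaging burden, and the PDAC incidence per patient-year."""
    results = [audit_patient(p, policy, tolerance, mri_only) for p in cohort.patients]
    return results, summarize_audit(results, cohort)


def summarize_audit(results: list[AuditResult], cohort: Cohort) -> CohortAuditSummary:
    by_class = {c: 0 for c in ConcordanceClass}
    for r in results:
        by_class[r.concordance_class] += 1
    n_classified = (
        by_class[ConcordanceClass.CONCORDANT]
        + by_class[ConcordanceClass.OVER]
        + by_class[ConcordanceClass.UNDER]
    )
    pcts: list[Optional[float]] = [None, None, None]
    if n_classified > 0:
        pcts = partition_percentages(
            [
                by_class[ConcordanceClass.CONCORDANT],
                by_class[ConcordanceClass.OVER],
                by_class[ConcordanceClass.UNDER],
            ]
        )

    def aggregate_excess(rows: list[AuditResult]) -> Optional[float]:
        years = sum(r.followup_patient_years for r in rows)
        if years <= 0:
            return None
        delta = sum(r.observed_imaging_count - r.expected_imaging_count for r in rows)
        return delta / years

    total_years = sum(r.followup_patient_years for r in results)
    pdac_events = sum(1 for p in cohort.patients if p.outcome_pdac)
    incidence = (
        incidence_per_patient_year(pdac_events, total_years) if total_years > 0 else None
    )
    over_rows = [r for r in results if r.concordance_class is ConcordanceClass.OVER]
    return CohortAuditSummary(
        n_total=n_classified,
        n_concordant=by_class[ConcordanceClass.CONCORDANT],
        n_over=by_class[ConcordanceClass.OVER],
        n_under=by_class[ConcordanceClass.UNDER],
        n_indeterminate=by_class[ConcordanceClass.INDETERMINATE],
        pct_concordant=pcts[0],
        pct_over=pcts[1],
        pct_under=pcts[2],
        mean_excess_per_patient_year=aggregate_excess(results),
        over_group_excess_per_patient_year=aggregate_excess(over_rows),
        total_patient_years=total_years,
        pdac_events=pdac_events,
        pdac_incidence_pct_per_patient_year=incidence,
    )
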