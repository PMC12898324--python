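"""Deterministic rule engine mapping a patient's feature state to a
management recommendation.

The engine stratifies a patient at a given date into high-risk stigmata
(HRS) and worrisome features (WF) using the thresholds of the active
:class:`~cystwatch.policy.DecisionPolicy`, then applies the precedence
HRS > WF > size band:

* any HRS and the patient is surgically fit -> surgical referral;
* any HRS but not fit -> intensified EUS surveillance (unfit rule);
* one or more WFs -> EUS-based surveillance, interval from the highest
  applicable WF-count tier (the Kyoto framework weighs the cumulative
  count of worrisome features);
* otherwise -> cross-sectional imaging at the size-band interval.

When a patient has multiple cysts, size-derived features use the leading
cyst while boolean findings count if reported on any cyst (the observation
already aggregates them).
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .models import CystObservation, Modality, PatientRecord, months_between
from .policy import DecisionPolicy

logger = logging.getLogger(__name__)


class Hrs(str, enum.Enum):
    MPD_GE_10MM = "mpd_ge_10mm"
    OBSTRUCTIVE_JAUNDICE = "obstructive_jaundice"
    ENHANCING_NODULE_GE_5MM = "enhancing_nodule_ge_5mm"


class Wf(str, enum.Enum):
    CYST_GE_30MM = "cyst_ge_30mm"
    NODULE_LT_5MM = "nodule_lt_5mm"
    WALL_THICKENED = "wall_thickened"
    MPD_5_TO_9MM = "mpd_5_to_9mm"
    ABRUPT_DUCT_CHANGE = "abrupt_duct_change"
    LYMPHADENOPATHY = "lymphadenopathy"
    CA19_9_ELEVATED = "ca19_9_elevated"
    GROWTH_GT_5MM_PER_2Y = "growth_gt_5mm_per_2y"
    ACUTE_PANCREATITIS = "acute_pancreatitis"
    NEW_ONSET_DIABETES = "new_onset_diabetes"


class Action(str, enum.Enum):
    SURGERY_REFERRAL = "surgery_referral"
    EUS_SURVEILLANCE = "eus_surveillance"
    IMAGING_SURVEILLANCE = "imaging_surveillance"


# escalation ordering used by monotonicity checks and the auditor
ACTION_INTENSITY = {
    Action.IMAGING_SURVEILLANCE: 0,
    Action.EUS_SURVEILLANCE: 1,
    Action.SURGERY_REFERRAL: 2,
}


class FeatureAssessment(BaseModel):
    high_risk_stigmata: frozenset[Hrs] = Field(default_factory=frozenset)
    worrisome_features: frozenset[Wf] = Field(default_factory=frozenset)
    wf_count: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "FeatureAssessment":
        if self.wf_count != len(self.worrisome_features):
            raise ValueError("wf_count must equal |worrisome_features|")
        if Hrs.MPD_GE_10MM in self.high_risk_stigmata and Wf.MPD_5_TO_9MM in self.worrisome_features:
            raise ValueError("duct >=10 mm and duct 5-9 mm are mutually exclusive")
        if (
            Hrs.ENHANCING_NODULE_GE_5MM in self.high_risk_stigmata
            and Wf.NODULE_LT_5MM in self.worrisome_features
        ):
            raise ValueError("stigmata-grade and worrisome-grade nodule are mutually exclusive")
        return self


class Recommendation(BaseModel):
    action: Action
    modality: Optional[Modality] = None
    interval_months: Optional[float] = None
    rationale: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _contract(self) -> "Recommendation":
        if self.action is Action.SURGERY_REFERRAL:
            if self.interval_months is not None:
                raise ValueError("surgical referral carries no surveillance interval")
        elif self.interval_months is None or self.interval_months <= 0:
            raise ValueError("surveillance requires a positive interval")
        return self


class GrowthUndefined(Exception):
    """Fewer than two usable size measurements: growth cannot be assessed."""


def compute_growth_rate(
    observations: list[CystObservation],
    at: Optional[dt.date] = None,
    window_months: float = 24.0,
    use_regression: bool = False,
) -> float:
    """Leading-cyst growth rate in mm per 24 months.

    Uses the trailing ``window_months`` window ending at ``at`` (default:
    the last observation): rate = (last size - first size in window) /
    elapsed months x 24. With ``use_regression`` a least-squares slope over
    the window is returned instead; the two agree on collinear series.

    Raises :class:`GrowthUndefined` when fewer than two observations fall
    in the window, and ``ValueError`` on unordered dates.
    """
    dates = [o.observation_date for o in observations]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("observation dates must be strictly increasing")
    if at is None:
        usable = list(observations)
    else:
        usable = [o for o in observations if o.observation_date <= at]
    if len(usable) < 2:
        raise GrowthUndefined("need at least two observations")
    end = usable[-1]
    start_window = [
        o
        for o in usable
        if months_between(o.observation_date, end.observation_date) <= window_months
    ]
    if len(start_window) < 2:
        raise GrowthUndefined("only one observation inside the trailing window")
    if use_regression:
        t = np.array(
            [months_between(start_window[0].observation_date, o.observation_date) for o in start_window]
        )
        y = np.array([o.leading_cyst_size for o in start_window])
        slope = np.polyfit(t, y, 1)[0]
        return float(slope * 24.0)
    first = start_window[0]
    elapsed = months_between(first.observation_date, end.observation_date)
    return (end.leading_cyst_size - first.leading_cyst_size) / elapsed * 24.0


def assess_observation(
    obs: CystObservation,
    policy: DecisionPolicy,
    growth_rate: Optional[float] = None,
) -> FeatureAssessment:
    """Stratify a single observation (plus an optional pre-computed growth
    rate) into high-risk stigmata and worrisome features."""
    th = policy.thresholds
    hrs: set[Hrs] = set()
    wf: set[Wf] = set()

    if obs.mpd_diameter is not None:
        if obs.mpd_diameter >= th.mpd_hrs_mm:
            hrs.add(Hrs.MPD_GE_10MM)
        elif th.mpd_wf_lower_mm <= obs.mpd_diameter < th.mpd_hrs_mm:
            wf.add(Wf.MPD_5_TO_9MM)
    if obs.obstructive_jaundice:
        hrs.add(Hrs.OBSTRUCTIVE_JAUNDICE)
    if obs.mural_nodule_size is not None:
        if obs.mural_nodule_enhancing and obs.mural_nodule_size >= th.enhancing_nodule_hrs_mm:
            hrs.add(Hrs.ENHANCING_NODULE_GE_5MM)
        else:
            # a nodule below the stigmata grade (small, or non-enhancing)
            wf.add(Wf.NODULE_LT_5MM)
    if obs.leading_cyst_size >= th.cyst_wf_mm:
        wf.add(Wf.CYST_GE_30MM)
    if obs.wall_thickened:
        wf.add(Wf.WALL_THICKENED)
    if obs.abrupt_duct_change:
        wf.add(Wf.ABRUPT_DUCT_CHANGE)
    if obs.lymphadenopathy:
        wf.add(Wf.LYMPHADENOPATHY)
    if obs.ca19_9 is not None and obs.ca19_9 > th.ca19_9_uln:
        wf.add(Wf.CA19_9_ELEVATED)
    if growth_rate is not None and growth_rate > th.growth_wf_mm_per_2y:
        wf.add(Wf.GROWTH_GT_5MM_PER_2Y)
    if policy.include_kyoto_wfs:
        if obs.acute_pancreatitis_episode:
            wf.add(Wf.ACUTE_PANCREATITIS)
        if obs.new_onset_diabetes:
            wf.add(Wf.NEW_ONSET_DIABETES)
    return FeatureAssessment(
        high_risk_stigmata=frozenset(hrs),
        worrisome_features=frozenset(wf),
        wf_count=len(wf),
    )


def assess_features(
    patient: PatientRecord, at: dt.date, policy: DecisionPolicy
) -> FeatureAssessment:
    """Evaluate thresholds on the patient's most recent observation at
    ``at``; missing optional fields count as "feature not demonstrated"."""
    obs = patient.observation_at(at)
    if obs is None:
        raise ValueError(
            f"patient {patient.patient_id}: no observation on or before {at.isoformat()}"
        )
    if obs.mpd_diameter is None or obs.ca19_9 is None:
        logger.debug(
            "patient %s: missing MPD/CA19-9 at %s treated as feature absent",
            patient.patient_id,
            at,
        )
    try:
        growth = compute_growth_rate(
            patient.observations, at=at, use_regression=policy.use_regression_growth
        )
    except GrowthUndefined:
        growth = None
    return assess_observation(obs, policy, growth_rate=growth)


def recommend_from_assessment(
    assessment: FeatureAssessment,
    cyst_size_mm: float,
    surgically_fit: bool,
    policy: DecisionPolicy,
    visit_number: int = 0,
) -> Recommendation:
    """Apply the policy's precedence to an already-computed feature state.

    ``visit_number`` is the number of surveillance visits already completed
    under the current size band, selecting between a band's initial and
    stable intervals; the recommendation at the index scan uses 0.
    """
    trace = [f"policy:{policy.name}@{policy.version}#{policy.checksum()}"]
    if assessment.high_risk_stigmata:
        trace.append("hrs:" + ",".join(sorted(h.value for h in assessment.high_risk_stigmata)))
        if surgically_fit:
            trace.append("rule:hrs->surgery_referral")
            return Recommendation(action=Action.SURGERY_REFERRAL, modality=None, rationale=trace)
        trace.append("rule:hrs_unfit->eus_surveillance")
        return Recommendation(
            action=Action.EUS_SURVEILLANCE,
            modality=policy.unfit_rule.modality,
            interval_months=policy.unfit_rule.interval_months,
            rationale=trace,
        )
    if assessment.wf_count >= 1:
        tier = policy.wf_tier_for(assessment.wf_count)
        trace.append("wf:" + ",".join(sorted(w.value for w in assessment.worrisome_features)))
        trace.append(f"rule:wf_count>={tier.min_count}->eus_surveillance@{tier.interval_months}mo")
        return Recommendation(
            action=Action.EUS_SURVEILLANCE,
            modality=tier.modality,
            interval_months=tier.interval_months,
            rationale=trace,
        )
    band = policy.band_for(cyst_size_mm)
    interval = band.interval_at(visit_number)
    trace.append(
        f"rule:size_band[{band.lower_mm},{band.upper_mm})mm,visit{visit_number}->"
        f"{band.modality.value}@{interval}mo"
    )
    return Recommendation(
        action=Action.IMAGING_SURVEILLANCE,
        modality=band.modality,
        interval_months=interval,
        rationale=trace,
    )


def recommend(
    patient: PatientRecord,
    at: dt.date,
    policy: DecisionPolicy,
    visit_number: int = 0,
) -> Recommendation:
    """Management recommendation for ``patient`` at date ``at``."""
    assessment = assess_features(patient, at, policy)
    obs = patient.observation_at(at)
    assert obs is not None
    return recommend_from_assessment(
        assessment, obs.leading_cyst_size, patient.surgically_fit, policy, visit_number
    )
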