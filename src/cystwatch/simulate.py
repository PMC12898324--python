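"""Synthetic retrospective SB-IPMN surveillance cohorts.

The generator emulates the structure of a single-centre surveillance
registry: adult patients with a branch-duct cyst found on an index MRI/MRCP,
followed longitudinally, whose real-world management may match the
guideline schedule, exceed it (over-surveillance) or fall short of it
(under-surveillance). Marginal distributions default to the registry this
package models: median age 69.5 (IQR 63.2-75.2) years, 69% male, median
leading cyst size 10 (6-14) mm, 10.5% multi-cystic, median radiological
follow-up 48.5 (28-75) months, and a 15.8/60.3/23.9 concordant/over/under
management split with younger patients shifted toward over-surveillance
and larger cysts toward concordance.

Right-skewed quantities (cyst size, follow-up) use a log-normal fitted by
quantile matching to the (median, IQR) targets. Each patient draws from an
independent substream spawned from the master seed, keyed by patient index,
so enlarging a cohort never perturbs earlier patients.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .audit import TolerancePolicy
from .engine import Action, Recommendation, recommend
from .models import (
    Cohort,
    Comorbidity,
    CystObservation,
    EventType,
    ManagementEvent,
    Modality,
    PatientRecord,
    Sex,
    add_months,
)
from .policy import DecisionPolicy, default_policy

_Z_IQR = 0.6744897501960817  # standard normal 75th percentile

# overall comorbidity prevalences of the modelled registry (fraction)
DEFAULT_COMORBIDITY_PREVALENCE: dict[str, float] = {
    "diabetes_or_ifg": 0.296,
    "smoker": 0.158,
    "alcohol": 0.011,
    "pancreatitis_history": 0.054,
    "liver_biliary_disease": 0.253,
    "family_history_pancreatitis": 0.044,
    "non_gi_malignancy": 0.288,
    "gi_malignancy": 0.041,
    "cholelithiasis_ccy": 0.255,
    "psc": 0.013,
    "pancreas_divisum": 0.071,
    "chronic_pancreatitis": 0.011,
}


def lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching the target median and IQR ratio."""
    if not 0 < q1 < median < q3:
        raise ValueError("need 0 < q1 < median < q3")
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2 * _Z_IQR)
    return mu, sigma


class BehaviorSpec(BaseModel):
    """How actual management relates to the guideline recommendation.

    A latent class is drawn per patient from ``base_probs`` — ordered
    (concordant, over, under) — shifted on the logit scale by covariate
    modifiers, then
    realized as management events placed inside / below / beyond the audit
    tolerance around the recommended interval.
    """

    base_probs: tuple[float, float, float] = (0.603, 0.239, 0.158)
    # log-odds shifts: younger patients tend to be over-surveilled, larger
    # cysts tend to be managed per guideline
    under_50_over_shift: float = math.log(1.61)
    cyst_gt20_concordant_shift: float = math.log(2.1)
    under_stop_prob: float = Field(default=0.15, ge=0, le=1)
    exact_schedule: bool = False

    @model_validator(mode="after")
    def _probs(self) -> "BehaviorSpec":
        if abs(sum(self.base_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.base_probs):
            raise ValueError("base class probabilities must be non-negative and sum to 1")
        return self


class CohortSpec(BaseModel):
    """Parameters of the synthetic registry."""

    n_patients: int = Field(default=368, ge=0)
    seed: int = 0
    age_median: float = 69.5
    age_iqr: tuple[float, float] = (63.2, 75.2)
    age_min: float = 18.0
    frac_under_50: float = Field(default=19 / 368, ge=0, le=1)
    male_fraction: float = Field(default=0.69, ge=0, le=1)
    cyst_median_mm: float = 10.0
    cyst_iqr_mm: tuple[float, float] = (6.0, 14.0)
    multi_cyst_prob: float = Field(default=0.105, ge=0, le=1)
    rad_followup_median_months: float = 48.5
    rad_followup_iqr_months: tuple[float, float] = (28.0, 75.0)
    clin_followup_median_months: float = 64.0
    clin_followup_iqr_months: tuple[float, float] = (46.0, 88.0)
    comorbidity_prevalence: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    # baseline probabilities of duct/nodule/clinical findings at the index scan
    p_mpd_measured: float = 0.8
    p_mpd_wf: float = 0.03
    p_mpd_hrs: float = 0.008
    p_nodule_small: float = 0.015
    p_nodule_hrs: float = 0.006
    p_jaundice: float = 0.004
    p_wall_thickened: float = 0.010
    p_lymphadenopathy: float = 0.004
    p_abrupt_duct_change: float = 0.005
    p_acute_pancreatitis: float = 0.005
    p_new_onset_diabetes: float = 0.008
    p_ca19_9_measured: float = 0.7
    ca19_9_log_median: float = math.log(12.0)
    ca19_9_log_sigma: float = 0.6
    # per-feature onset hazard during follow-up (per patient-year)
    feature_onset_hazard_per_py: float = Field(default=0.004, ge=0)
    p_unfit: float = Field(default=0.03, ge=0, le=1)
    growth_drift_mean_mm_per_year: float = 0.10
    growth_drift_sd_mm_per_year: float = 0.40
    measurement_noise_sd_mm: float = 0.5
    pdac_hazard_per_py: float = Field(default=0.0006, ge=0)
    behavior: BehaviorSpec = Field(default_factory=BehaviorSpec)

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        for name, (m, (q1, q3)) in {
            "age": (self.age_median, self.age_iqr),
            "cyst": (self.cyst_median_mm, self.cyst_iqr_mm),
            "rad_followup": (self.rad_followup_median_months, self.rad_followup_iqr_months),
            "clin_followup": (self.clin_followup_median_months, self.clin_followup_iqr_months),
        }.items():
            if not 0 < q1 <= m <= q3:
                raise ValueError(f"{name}: need 0 < q1 <= median <= q3")
        for k, v in self.comorbidity_prevalence.items():
            Comorbidity(k)  # raises on unknown keys
            if not 0 <= v <= 1:
                raise ValueError(f"comorbidity prevalence {k} outside [0,1]")
        return self


CLASS_NAMES = ("concordant", "over", "under")

_IMAGING_EVENT_FOR = {
    Modality.MRI_MRCP: EventType.IMAGING_MRI_MRCP,
    Modality.EUS: EventType.IMAGING_EUS,
    Modality.CT: EventType.IMAGING_CT,
}


def _sample_class(
    rng: np.random.Generator, spec: BehaviorSpec, under_50: bool, cyst_gt20: bool
) -> str:
    logits = np.log(np.clip(np.asarray(spec.base_probs, dtype=float), 1e-12, None))
    if under_50:
        logits[1] += spec.under_50_over_shift
    if cyst_gt20:
        logits[0] += spec.cyst_gt20_concordant_shift
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return CLASS_NAMES[rng.choice(3, p=p)]


def _draw_index_observation(
    rng: np.random.Generator, spec: CohortSpec, index_date: dt.date, size_mm: float
) -> CystObservation:
    mpd: Optional[float] = None
    if rng.random() < spec.p_mpd_measured:
        u = rng.random()
        if u < spec.p_mpd_hrs:
            mpd = float(rng.uniform(10.0, 14.0))
        elif u < spec.p_mpd_hrs + spec.p_mpd_wf:
            mpd = float(rng.uniform(5.0, 9.0))
        else:
            mpd = float(rng.uniform(1.0, 4.5))
    nodule_size: Optional[float] = None
    nodule_enh: Optional[bool] = None
    u = rng.random()
    if u < spec.p_nodule_hrs:
        nodule_size, nodule_enh = float(rng.uniform(5.0, 9.0)), True
    elif u < spec.p_nodule_hrs + spec.p_nodule_small:
        nodule_size, nodule_enh = float(rng.uniform(1.0, 4.5)), bool(rng.random() < 0.5)
    ca: Optional[float] = None
    if rng.random() < spec.p_ca19_9_measured:
        ca = float(rng.lognormal(spec.ca19_9_log_median, spec.ca19_9_log_sigma))
    return CystObservation(
        observation_date=index_date,
        leading_cyst_size=size_mm,
        n_cysts=int(2 + rng.integers(0, 2)) if rng.random() < spec.multi_cyst_prob else 1,
        mpd_diameter=mpd,
        mural_nodule_size=nodule_size,
        mural_nodule_enhancing=nodule_enh,
        wall_thickened=bool(rng.random() < spec.p_wall_thickened),
        abrupt_duct_change=bool(rng.random() < spec.p_abrupt_duct_change),
        lymphadenopathy=bool(rng.random() < spec.p_lymphadenopathy),
        obstructive_jaundice=bool(rng.random() < spec.p_jaundice),
        ca19_9=ca,
        acute_pancreatitis_episode=bool(rng.random() < spec.p_acute_pancreatitis),
        new_onset_diabetes=bool(rng.random() < spec.p_new_onset_diabetes),
        modality=Modality.MRI_MRCP,
    )


def _followup_observation(
    rng: np.random.Generator,
    spec: CohortSpec,
    index_obs: CystObservation,
    date: dt.date,
    months: float,
    drift_mm_per_year: float,
    modality: Modality,
) -> CystObservation:
    size = (
        index_obs.leading_cyst_size
        + drift_mm_per_year * months / 12.0
        + rng.normal(0.0, spec.measurement_noise_sd_mm)
    )
    size = max(size, 1.0)
    onset = 1.0 - math.exp(-spec.feature_onset_hazard_per_py * months / 12.0)
    return index_obs.model_copy(
        update={
            "observation_date": date,
            "leading_cyst_size": float(size),
            "modality": modality,
            "wall_thickened": index_obs.wall_thickened or rng.random() < onset,
            "lymphadenopathy": index_obs.lymphadenopathy or rng.random() < onset,
        }
    )


def _exact_schedule(
    rng: np.random.Generator,
    spec: CohortSpec,
    stub: PatientRecord,
    policy: DecisionPolicy,
    drift: float,
) -> tuple[list[ManagementEvent], list[CystObservation]]:
    """Imaging events exactly at the guideline scheduler's visit times.

    Mirrors the auditor's counterfactual walk step for step — including the
    re-evaluation of the engine against the accumulating observation series
    — so the observed imaging count equals the expected one by construction.
    """
    window = stub.radiological_followup_months
    index_obs = stub.observations[0]
    observations = [index_obs]
    events: list[ManagementEvent] = []
    t, visit = 0.0, 0
    while True:
        current = stub.model_copy(update={"observations": list(observations)})
        rec = recommend(
            current, add_months(stub.index_date, t), policy, visit_number=visit
        )
        if rec.action is Action.SURGERY_REFERRAL:
            break
        assert rec.interval_months is not None and rec.modality is not None
        t_next = t + rec.interval_months
        if t_next > window + 1e-9:
            break
        date = add_months(stub.index_date, t_next)
        events.append(
            ManagementEvent(event_date=date, event_type=_IMAGING_EVENT_FOR[rec.modality])
        )
        if date > observations[-1].observation_date:
            observations.append(
                _followup_observation(
                    rng, spec, index_obs, date, t_next, drift, rec.modality
                )
            )
        t, visit = t_next, visit + 1
    return events, observations


def _realize_management(
    rng: np.random.Generator,
    spec: CohortSpec,
    latent: str,
    rec: Recommendation,
    stable_interval: float,
    followup_months: float,
    tolerance: TolerancePolicy,
) -> tuple[str, list[float], list[EventType], float]:
    """Place the first post-index decision (and subsequent imaging cadence)
    so that the audit adjudicates the realized class.

    Returns (realized class, event times in months, event types, possibly
    extended follow-up in months).
    """
    behavior = spec.behavior
    if rec.action is Action.SURGERY_REFERRAL:
        if latent == "over":
            latent = "concordant"  # nothing exceeds a surgical referral
        grace = tolerance.surgery_grace_months
        if latent == "concordant":
            t = float(rng.uniform(0.5, 0.9 * grace))
            return "concordant", [t], [EventType.SURGERY_PERFORMED], followup_months
        # under: surveillance imaging (or nothing) instead of surgery
        if rng.random() < 0.5:
            t = float(rng.uniform(grace * 1.2, max(grace * 2.0, followup_months)))
            fu = max(followup_months, t + 1.0)
            return "under", [t], [EventType.IMAGING_MRI_MRCP], fu
        return "under", [], [], max(followup_months, grace + 1.0)

    interval = rec.interval_months
    assert interval is not None and rec.modality is not None
    width = tolerance.half_width(interval)
    first_kind = _IMAGING_EVENT_FOR[rec.modality]
    if latent == "concordant":
        t_first = interval + float(rng.uniform(-0.8, 0.8)) * width
        gap_mult = (0.9, 1.1)
    elif latent == "over":
        t_first = float(rng.uniform(0.25, 0.85)) * (interval - width)
        t_first = max(t_first, 0.5)
        gap_mult = (0.4, 0.8)
        first_kind = EventType.IMAGING_MRI_MRCP
    else:  # under
        if rng.random() < behavior.under_stop_prob:
            t = float(rng.uniform(1.0, 6.0))
            return "under", [t], [EventType.SURVEILLANCE_STOPPED], followup_months
        t_first = (interval + width) * float(rng.uniform(1.15, 1.8))
        gap_mult = (1.3, 1.9)
    fu = max(followup_months, t_first + 1.0)
    times = [t_first]
    kinds = [first_kind]
    # subsequent imaging keeps the class-characteristic cadence relative to
    # the policy's steady-state interval for this patient
    t = t_first
    while True:
        gap = stable_interval * float(rng.uniform(*gap_mult))
        gap = max(gap, 1.0)
        t = t + gap
        if t > fu:
            break
        times.append(t)
        kinds.append(EventType.IMAGING_MRI_MRCP)
    return latent, times, kinds, fu


def _generate_patient(
    rng: np.random.Generator,
    spec: CohortSpec,
    policy: DecisionPolicy,
    tolerance: TolerancePolicy,
    index: int,
) -> tuple[PatientRecord, str]:
    age_mu = spec.age_median
    age_sigma = (spec.age_iqr[1] - spec.age_iqr[0]) / (2 * _Z_IQR)
    if rng.random() < spec.frac_under_50:
        age = float(rng.uniform(max(spec.age_min, 35.0), 50.0))
    else:
        age = float(rng.normal(age_mu, age_sigma))
        while age < 50.0:
            age = float(rng.normal(age_mu, age_sigma))
    sex = Sex.MALE if rng.random() < spec.male_fraction else Sex.FEMALE

    mu, sigma = lognormal_params(spec.cyst_median_mm, *spec.cyst_iqr_mm)
    size = float(rng.lognormal(mu, sigma))
    mu, sigma = lognormal_params(
        spec.rad_followup_median_months, *spec.rad_followup_iqr_months
    )
    rad_fu = float(rng.lognormal(mu, sigma))
    mu, sigma = lognormal_params(
        spec.clin_followup_median_months, *spec.clin_followup_iqr_months
    )
    clin_fu = float(rng.lognormal(mu, sigma))

    index_date = dt.date(2008, 1, 1) + dt.timedelta(days=int(rng.integers(0, 3653)))
    index_obs = _draw_index_observation(rng, spec, index_date, size)
    comorbidities = {
        Comorbidity(k) for k, p in spec.comorbidity_prevalence.items() if rng.random() < p
    }
    limited = rng.random() < spec.p_unfit
    fit = not limited and age < 90.0

    stub = PatientRecord(
        patient_id=f"sim-{index:05d}",
        age_at_index=age,
        sex=sex,
        surgically_fit=fit,
        limited_life_expectancy=limited,
        comorbidities=comorbidities,
        observations=[index_obs],
        clinical_followup_months=clin_fu,
        radiological_followup_months=rad_fu,
    )
    rec = recommend(stub, index_date, policy, visit_number=0)

    drift = float(
        rng.normal(spec.growth_drift_mean_mm_per_year, spec.growth_drift_sd_mm_per_year)
    )

    if spec.behavior.exact_schedule:
        events, observations = _exact_schedule(rng, spec, stub, policy, drift)
        realized = "concordant"
        fu = rad_fu
    else:
        latent = _sample_class(rng, spec.behavior, age < 50.0, size > 20.0)
        if rec.action is Action.IMAGING_SURVEILLANCE:
            stable = policy.band_for(index_obs.leading_cyst_size).stable_interval_months
        else:
            stable = rec.interval_months or 6.0
        realized, times, kinds, fu = _realize_management(
            rng, spec, latent, rec, stable, rad_fu, tolerance
        )
        events = []
        observations = [index_obs]
        for t, kind in zip(times, kinds):
            date = add_months(index_date, t)
            events.append(ManagementEvent(event_date=date, event_type=kind))
            if kind in _IMAGING_EVENT_FOR.values() and date > observations[-1].observation_date:
                observations.append(
                    _followup_observation(
                        rng, spec, index_obs, date, t, drift, _modality_of(kind)
                    )
                )

    years = fu / 12.0
    pdac = bool(rng.random() < 1.0 - math.exp(-spec.pdac_hazard_per_py * years))
    pdac_date = (
        add_months(index_date, float(rng.uniform(0.5, max(fu, 1.0)))) if pdac else None
    )
    patient = stub.model_copy(
        update={
            "observations": observations,
            "management_events": events,
            "radiological_followup_months": fu,
            "outcome_pdac": pdac,
            "outcome_pdac_date": pdac_date,
        }
    )
    return PatientRecord.model_validate(patient.model_dump()), realized


def _modality_of(kind: EventType) -> Modality:
    for mod, ev in _IMAGING_EVENT_FOR.items():
        if ev == kind:
            return mod
    raise ValueError(kind)


def generate_with_known_truth(
    spec: CohortSpec,
    policy: Optional[DecisionPolicy] = None,
    tolerance: Optional[TolerancePolicy] = None,
    seed: Optional[int] = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort together with each patient's realized latent
    management class, for scoring the auditor against ground truth."""
    policy = policy or default_policy()
    tolerance = tolerance or TolerancePolicy()
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = master.spawn(spec.n_patients)
    patients: list[PatientRecord] = []
    truth_rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        patient, realized = _generate_patient(rng, spec, policy, tolerance, i)
        patients.append(patient)
        truth_rows.append({"patient_id": patient.patient_id, "true_class": realized})
    cohort = Cohort(patients=patients, provenance=f"synthetic (seed={seed if seed is not None else spec.seed})")
    return cohort, pd.DataFrame(truth_rows)


def generate(
    spec: CohortSpec,
    policy: Optional[DecisionPolicy] = None,
    tolerance: Optional[TolerancePolicy] = None,
    seed: Optional[int] = None,
) -> Cohort:
    """Generate a synthetic cohort (see module docstring)."""
    cohort, _ = generate_with_known_truth(spec, policy, tolerance, seed)
    return cohort
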