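import datetime as dt

import pytest

from cystwatch import (
    CohortSpec,
    CystObservation,
    ManagementEvent,
    PatientRecord,
    default_policy,
)

INDEX = dt.date(2020, 1, 6)


def make_patient(
    size_mm: float = 10.0,
    age: float = 70.0,
    sex: str = "male",
    fit: bool = True,
    followup_months: float = 60.0,
    events: list[tuple[float, str]] | None = None,
    extra_obs: list[tuple[float, float]] | None = None,
    patient_id: str = "p1",
    **obs_kwargs,
):
    """Convenience builder: one index MRI plus optional (months, size)
    follow-up observations and (months, event_type) management events."""
    from cystwatch.models import add_months

    observations = [
        CystObservation(
            observation_date=INDEX, leading_cyst_size=size_mm, **obs_kwargs
        )
    ]
    for months, size in extra_obs or []:
        observations.append(
            CystObservation(
                observation_date=add_months(INDEX, months),
                leading_cyst_size=size,
            )
        )
    mgmt = [
        ManagementEvent(event_date=add_months(INDEX, months), event_type=kind)
        for months, kind in (events or [])
    ]
    return PatientRecord(
        patient_id=patient_id,
        age_at_index=age,
        sex=sex,
        surgically_fit=fit,
        observations=observations,
        management_events=mgmt,
        clinical_followup_months=followup_months,
        radiological_followup_months=followup_months,
    )


@pytest.fixture(scope="session")
def policy():
    return default_policy()


@pytest.fixture(scope="session")
def small_cohort_with_truth(policy):
    """A 400-patient synthetic cohort with latent class labels, shared
    across tests to keep the suite fast."""
    from cystwatch import generate_with_known_truth

    spec = CohortSpec(n_patients=400)
    return generate_with_known_truth(spec, policy, seed=7)
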