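"""Ask the guideline engine what to do for a single patient.

A 72-year-old with a 24 mm branch-duct cyst and a slightly dilated main
pancreatic duct (6 mm) has one worrisome feature, so the engine recommends
EUS at a short interval rather than routine MRI surveillance.
"""

import datetime as dt

from cystwatch import CystObservation, PatientRecord, default_policy, recommend

patient = PatientRecord(
    patient_id="example-01",
    age_at_index=72,
    sex="female",
    surgically_fit=True,
    observations=[
        CystObservation(
            observation_date=dt.date(2022, 3, 14),
            leading_cyst_size=24.0,
            mpd_diameter=6.0,
        )
    ],
    clinical_followup_months=0.0,
    radiological_followup_months=0.0,
)

policy = default_policy()
rec = recommend(patient, patient.index_date, policy)

print(f"action:   {rec.action.value}")
print(f"modality: {rec.modality.value if rec.modality else '-'}")
print(f"interval: {rec.interval_months} months")
print("rationale:")
for line in rec.rationale:
    print(f"  {line}")
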