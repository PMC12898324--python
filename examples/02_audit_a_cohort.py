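"""Audit actual management against the guideline, patient by patient.

We simulate a small registry-like cohort, then classify each patient as
concordant, over-surveilled or under-surveilled by comparing the timing
and modality of what actually happened after the index scan with what the
policy recommended at the index scan.
"""

from cystwatch import CohortSpec, audit_cohort, default_policy, generate

policy = default_policy()
cohort = generate(CohortSpec(n_patients=200), policy, seed=11)

results, summary = audit_cohort(cohort, policy)

print(f"patients audited:   {summary.n_total} (+{summary.n_indeterminate} indeterminate)")
print(f"concordant:         {summary.n_concordant} ({summary.pct_concordant}%)")
print(f"over-surveillance:  {summary.n_over} ({summary.pct_over}%)")
print(f"under-surveillance: {summary.n_under} ({summary.pct_under}%)")
print(f"excess MRI/MRCP per patient-year: {summary.mean_excess_per_patient_year:.2f}")

# the per-patient results carry the recommendation behind each classification
first = results[0]
print(f"\nfirst patient ({first.patient_id}): {first.concordance_class.value}")
print(f"  recommended: {first.recommended.action.value} @ {first.recommended.interval_months} months")
print(f"  observed first action: {first.observed_first_action}")
print(f"  imaging observed/expected: {first.observed_imaging_count}/{first.expected_imaging_count}")
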