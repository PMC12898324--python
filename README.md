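# cystwatch

Rule-based decision support and concordance auditing for the surveillance of
side-branch intraductal papillary mucinous neoplasms (IPMN) of the pancreas.

Incidentally detected pancreatic cysts are common, and consensus guidelines
(most recently the 2024 Kyoto revision of the international IPMN guidelines)
stratify them by **high-risk stigmata** (main pancreatic duct ≥ 10 mm,
obstructive jaundice, enhancing mural nodule ≥ 5 mm → surgical referral for
fit patients), **worrisome features** (cyst ≥ 30 mm, small mural nodule,
thickened wall, duct 5–9 mm, abrupt duct-calibre change, lymphadenopathy,
CA 19-9 above normal, growth > 5 mm in 2 years, acute pancreatitis,
new-onset diabetes → short-interval EUS) and otherwise by **size bands**
with fixed MRI/MRCP surveillance schedules. In practice, real-world
management often departs from these schedules in both directions.

`cystwatch` makes that comparison computable. It provides:

- **`cystwatch.engine`** — a deterministic guideline engine: patient record
  in, recommendation out (action, modality, interval), with an auditable
  rationale trace. The rule table lives in a versioned, checksummed YAML
  policy file (`cystwatch/data/kyoto_policy.yaml`), so alternative or future
  guideline revisions are plain data, not code changes.
- **`cystwatch.audit`** — a concordance auditor that classifies each patient
  as *concordant*, *over-surveilled*, *under-surveilled* or *indeterminate*
  by comparing the first management event after the index scan with the
  recommendation at the index scan (tolerance: ±max(25% of the interval,
  3 months); surgery within a 6-month grace period). It also computes a
  counterfactual imaging schedule per patient and reports **excess MRI/MRCP
  per patient-year**.
- **`cystwatch.stats`** — the statistical battery of a concordance study:
  median (IQR) descriptives, chi-square/Fisher and Mann–Whitney/
  Kruskal–Wallis univariable screens, and multivariable logistic regression
  with age and sex forced in and screened covariates entering at p < 0.2.
- **`cystwatch.simulate`** — a synthetic registry generator with known latent
  behaviour labels, calibrated to a realistic surveillance cohort
  (n = 368, median age 69.5, median cyst 10 mm, ~60% concordant management).
  Because the truth labels are known, the generator doubles as a validation
  harness for the auditor.
- **`cystwatch.cli`** — a thin command line (`cystwatch recommend | audit |
  simulate | report | run`).

## Worked example

A 72-year-old, surgically fit, with a 24 mm branch-duct cyst and a 6 mm main
pancreatic duct (one worrisome feature):

```python
import datetime as dt
from cystwatch import CystObservation, PatientRecord, default_policy, recommend

patient = PatientRecord(
    patient_id="example-01",
    age_at_index=72, sex="female", surgically_fit=True,
    observations=[CystObservation(
        observation_date=dt.date(2022, 3, 14),
        leading_cyst_size=24.0, mpd_diameter=6.0,
    )],
    clinical_followup_months=0.0, radiological_followup_months=0.0,
)
rec = recommend(patient, patient.index_date, default_policy())
```

prints (via `examples/01_recommend_one_patient.py`):

```
action:   eus_surveillance
modality: eus
interval: 6.0 months
rationale:
  policy:kyoto-2024-default@1#36485a9dd3f7
  wf:mpd_5_to_9mm
  rule:wf_count>=1->eus_surveillance@6.0mo
```

Auditing a simulated 200-patient cohort
(`examples/02_audit_a_cohort.py`):

```
patients audited:   200 (+0 indeterminate)
concordant:         139 (69.5%)
over-surveillance:  31 (15.5%)
under-surveillance: 30 (15.0%)
excess MRI/MRCP per patient-year: 0.25

first patient (sim-00000): concordant
  recommended: imaging_surveillance @ 6.0 months
  observed first action: imaging_mri_mrcp
  imaging observed/expected: 4/4
```

The same pipeline from the shell:

```sh
cystwatch run --seed 5 --out-dir out/   # simulate -> audit -> report files
cystwatch audit --cohort out/cohort.csv --out report.json
```

All four scripts in `examples/` are short and narrative; each runs in a few
seconds with `python examples/<name>.py`.

## Tests

```sh
python -m pytest -q tests/
```

The suite checks the engine against an independently written straight-line
decision tree over the full feature grid, the exact statistics against
brute-force enumeration (every 2×2 table with n ≤ 40 for Fisher; every rank
assignment with n ≤ 12 for Mann–Whitney), monotonicity of the rule table
(adding a worrisome feature never relaxes management), auditor recovery of
known behaviour labels, and the exactly-zero-excess property of
policy-following cohorts under randomly drawn policies. The full run takes
about two minutes; most of that is the exhaustive Fisher sweep.

## Layout

```
src/cystwatch/      library (models, io, policy, engine, audit, stats, simulate, cli)
examples/           narrative example scripts
scripts/acceptance.py   deterministic headline-quantity computation
docs/methods.md     model description, parameters, numerical choices, limitations
tests/              pytest suite, with independent oracles in tests/oracles.py
```

See `docs/methods.md` for the precise rule semantics, tolerance definitions,
generator calibration and known limitations.
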