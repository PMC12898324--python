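# Methods

This document records the model implemented by `cystwatch`, its parameters
and units, the scope of the synthetic generator, the numerical choices that
affect results, and known limitations.

## Data model

A `PatientRecord` holds demographics (`age_at_index` ≥ 18, `sex`,
`surgically_fit`, comorbidity set), a strictly date-ordered list of
`CystObservation`s (the first is the index MRI/MRCP), a list of
`ManagementEvent`s (imaging of a given modality, surgery, or
surveillance-stop; dates non-decreasing), follow-up durations in months,
and the pancreatic-cancer outcome flag. Feature fields that may be
unmeasured (`mpd_diameter`, `mural_nodule_size`, `mural_nodule_enhancing`,
`ca19_9`) are optional; an absent value means *not assessed* and triggers
no rule. Units: millimetres for all diameters, months for all durations,
U/mL for CA 19-9.

Cohorts round-trip through a flat CSV (one row per observation/event,
grouped by `patient_id`) and a JSON format; schema violations are reported
with row numbers.

## Policy and engine

The rule table is data (`cystwatch/data/kyoto_policy.yaml`), validated on
load and identified by `name@version#checksum` (first 12 hex digits of the
SHA-256 of its canonical JSON). The default policy encodes:

- **High-risk stigmata**: MPD ≥ 10 mm, obstructive jaundice, enhancing
  mural nodule ≥ 5 mm. Any stigma → surgical referral if `surgically_fit`,
  otherwise EUS every 6 months.
- **Worrisome features**: cyst ≥ 30 mm, mural nodule not meeting the
  stigma definition, thickened/enhancing wall, MPD 5–9 mm, abrupt change
  in duct calibre, lymphadenopathy, CA 19-9 > 37 U/mL, growth > 5 mm per
  2 years (strict inequality), and — when `include_kyoto_wfs` is on, as it
  is by default — acute pancreatitis and new-onset diabetes. One or more
  worrisome features → EUS every 6 months.
- **Size bands** otherwise: < 20 mm → MRI/MRCP at 6 months, then every
  18 months; 20–29 mm → every 6 months in the first year, then every
  12 months. The `visit_number` argument selects the initial-vs-stable
  schedule position.

Precedence is stigmata > worrisome features > size band. Every
recommendation carries a rationale trace (`policy:…`, `hrs:…`/`wf:…`,
`rule:…`) sufficient to reconstruct why it fired.

**Mural-nodule convention.** A nodule that does not meet the stigma
definition — any non-enhancing nodule, or an enhancing nodule < 5 mm —
counts as the "small mural nodule" worrisome feature regardless of size.
Guideline texts leave the non-enhancing ≥ 5 mm case ambiguous; treating it
as worrisome (never silently benign) is the conservative reading, and the
independent test oracle encodes the same convention.

**Growth.** `compute_growth_rate` takes the earliest observation within a
trailing window (default 24 months) and the observation at the evaluation
date, and linearly scales the size difference to mm per 2 years. It raises
`GrowthUndefined` with fewer than two observations in the window.

## Concordance audit

Each audited patient is classified by comparing the recommendation at the
index date against the first management event after it:

- *Recommendation = surgery*: surgery within a 6-month grace period →
  **concordant**; anything else → **under** (or **indeterminate** when
  there are no events and follow-up is shorter than the grace period).
- *Recommendation = surveillance at interval I*: let the tolerance
  half-width be `w = max(25% of I, 3 months)`. First event inside
  `I ± w` → **concordant**; earlier → **over**; later, surveillance
  stopped, or no event despite follow-up beyond `I + w` → **under**;
  no event with follow-up shorter than `I + w` → **indeterminate**.
  Surgery against a surveillance recommendation → **over**. By default
  an EUS performed when MRI was recommended (or vice versa) still counts
  as concordant (`modality_strict=False`); strict mode additionally
  requires the modality intensity to match.

**Excess imaging.** For each patient a counterfactual schedule is walked
through the radiological follow-up window: at each scheduled visit the
engine is re-evaluated on the observations available by that date (so
feature onset during follow-up shortens subsequent intervals), surgery
stops the walk, and visits falling on the window end are counted. The
default metric counts MRI/MRCP visits only. Cohort excess is the
aggregate `(Σ observed − Σ expected) / Σ patient-years` over all audited
patients; a variant restricted to the over-surveilled subgroup is also
reported. On a cohort that follows the policy exactly, excess is exactly
zero by construction — this is a tested invariant, not an approximation.

## Statistics

Continuous variables are summarized as median (IQR); group comparisons use
the exact Mann–Whitney test when the combined sample is ≤ 20 without ties,
the normal approximation otherwise, and Kruskal–Wallis for the three-way
over/concordant/under contrast. Binary variables use the chi-square test
without continuity correction, switching to Fisher's exact test when any
expected cell count is below 5. The multivariable logistic model forces
age and sex and adds every screened covariate with univariable p < 0.2
(dropping continuous cyst size when the > 20 mm indicator is selected, to
avoid double-entering the same signal); odds ratios and Wald 95% CIs come
from maximum likelihood, and quasi-complete separation is detected before
fitting and reported with the offending variable's name.

Correctness is anchored by enumeration: Fisher's p equals the full
fixed-margin hypergeometric enumeration for **every** 2×2 table with
n ≤ 40 (135,750 tables), the exact Mann–Whitney p equals exhaustive rank
enumeration for every split with combined n ≤ 12, and the logistic odds
ratio equals the cross-product ratio (a·d)/(b·c) on saturated 2×2 data.

## Synthetic generator

`CohortSpec` defaults describe a registry-like surveillance cohort:
n = 368; age median 69.5 (IQR 63.2–75.2) with 19/368 under 50 (enforced by
rejection sampling of the tail); 69% male; leading cyst size median 10 mm
(IQR 6–14); 10.5% multiple cysts; radiological follow-up median 48.5
months (IQR 28–75); twelve comorbidities at fixed prevalences; baseline
high-risk/worrisome feature probabilities of a few per mille to a few per
cent; feature onset during follow-up at 0.004 per patient-year; cyst
growth as a per-patient linear drift N(0.10, 0.40) mm/year plus 0.5 mm
measurement noise; pancreatic-cancer hazard 0.0006 per patient-year.
Skewed marginals use lognormal distributions quantile-matched to the
target median and IQR (σ = ln(q3/q1) / (2 · 0.6745)).

The behaviour model draws a latent class per patient from base
probabilities (concordant 0.603, over 0.239, under 0.158) shifted on the
logit scale: age < 50 multiplies the odds of over-surveillance by 1.61 and
cyst > 20 mm multiplies the odds of concordance by 2.1. Events are then
placed inside, below or beyond the audit tolerance accordingly (with a
15% chance that an under-surveilled patient simply stops surveillance);
when the recommendation is surgery, the "over" class cannot be realized
and is relabelled concordant. A separate `exact_schedule` mode replays the
auditor's counterfactual walk step-for-step, producing cohorts whose
excess-imaging metric is exactly zero under any policy.

Reproducibility: the master seed feeds a `numpy` `SeedSequence`, which
spawns one independent substream per patient, so cohorts are bit-for-bit
reproducible and extending n leaves earlier patients unchanged.

**Scope.** The generator is calibrated to marginal summaries, not to joint
distributions; it does not model inter-observer size variability, missed
visits clustered by site, or competing mortality. It exists to exercise
and validate the engine/auditor, not to forecast clinical outcomes.

## Numerical choices

- One month = 30.4375 days everywhere dates are converted to months;
  date arithmetic is whole-day, so "exactly 24 months" constructed from
  dates lands within ±0.05 months of 24.0 — boundary-sensitive rules
  (growth > 5 mm/2 y) are therefore defined on the computed rate, and
  boundary tests exercise the comparison directly.
- Percentages are rounded half-even to 1 decimal (partition) or as
  requested; incidence per patient-year to 2 decimals.
- All thresholds are compared with ≥ / > exactly as written above; MPD
  10 mm is a stigma (inclusive), 5–9.9… mm worrisome.

## Limitations

- The engine evaluates one policy snapshot at a time; modelling a
  guideline change mid-follow-up requires two audits.
- The audit anchors on the first post-index event; chronically drifting
  adherence after a concordant first visit is only visible through the
  excess-imaging metric, not the class label.
- Indeterminate patients (insufficient follow-up) are excluded from the
  partition denominator and reported separately.
- Exact statistics fall back to asymptotic approximations outside their
  enumeration limits (Mann–Whitney n > 20 or ties).
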