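"""Descriptive table, univariable screen and multivariable logistic model.

Reproduces the analysis pipeline of a concordance study: describe the
cohort, screen covariates for association with guideline concordance, then
fit a logistic model with age and sex forced in and screened covariates
added at p < 0.2.
"""

from cystwatch import (
    CohortSpec,
    Grouping,
    audit_cohort,
    default_policy,
    describe,
    generate,
    select_and_fit,
    univariable_screen,
)

policy = default_policy()
cohort = generate(CohortSpec(n_patients=368), policy, seed=19)
results, _ = audit_cohort(cohort, policy)

print(describe(cohort).head(8).to_string())

print("\nunivariable screen (concordant vs not), first covariates:")
for r in univariable_screen(cohort, results, Grouping.CONCORDANT_VS_NOT)[:6]:
    print(f"  {r.variable:<28s} {r.test.value:<13s} p={r.p_value:.3f}")

model = select_and_fit(cohort, results, outcome="concordant")
print(f"\nlogistic model (outcome: concordant, n={model.n_used}):")
for t in model.terms:
    print(
        f"  {t.variable:<28s} OR {t.odds_ratio:.2f} "
        f"(95% CI {t.ci_lower:.2f}-{t.ci_upper:.2f}) p={t.p_value:.3f}"
    )
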