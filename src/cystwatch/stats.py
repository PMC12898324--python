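"""Cohort statistics relating patient covariates to concordance class.

Descriptive summaries report continuous variables as median (IQR) and
categorical ones as n (%). Univariable screening uses the chi-square test
(no continuity correction) for categorical covariates, falling back to
Fisher's exact test whenever any expected cell count is below 5, and the
Mann-Whitney (or Kruskal-Wallis, for the over/under contrast) test for
continuous covariates. Multivariable logistic regression forces age and
sex into the model and adds every covariate with univariable p < 0.2.
"""

from __future__ import annotations

import enum
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from pydantic import BaseModel

from .audit import AuditResult, ConcordanceClass
from .models import Cohort, Comorbidity

SCREEN_P_THRESHOLD = 0.2
FISHER_MIN_EXPECTED = 5
EXACT_MW_MAX_N = 20


class StatTest(str, enum.Enum):
    CHI_SQUARE = "chi_square"
    FISHER_EXACT = "fisher_exact"
    MANN_WHITNEY = "mann_whitney"
    KRUSKAL_WALLIS = "kruskal_wallis"


class Grouping(str, enum.Enum):
    CONCORDANT_VS_NOT = "concordant_vs_not"
    OVER_VS_UNDER = "over_vs_under"


class UnivariableResult(BaseModel):
    variable: str
    test: StatTest
    statistic: Optional[float] = None
    p_value: float
    group_summaries: dict[str, str]


class LogisticTerm(BaseModel):
    variable: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float


class LogisticModelResult(BaseModel):
    outcome: str
    terms: list[LogisticTerm]
    n_used: int
    selected: list[str]


class SeparationError(RuntimeError):
    """Maximum-likelihood logistic fit failed to converge; typically a
    covariate perfectly separates the outcome."""


CONTINUOUS_COVARIATES = ["age", "cyst_size_mm", "radiological_followup_months"]
BINARY_COVARIATES = ["male", "cyst_gt_20mm", "multiple_cysts"] + [c.value for c in Comorbidity]


def covariate_frame(cohort: Cohort, results: Optional[list[AuditResult]] = None) -> pd.DataFrame:
    """One row per patient: index-scan covariates plus, when audit results
    are supplied, the concordance class."""
    rows = []
    for p in cohort.patients:
        index_obs = p.observations[0]
        row = {
            "patient_id": p.patient_id,
            "age": p.age_at_index,
            "male": int(p.sex.value == "male"),
            "cyst_size_mm": index_obs.leading_cyst_size,
            "cyst_gt_20mm": int(index_obs.leading_cyst_size > 20.0),
            "multiple_cysts": int(index_obs.n_cysts > 1),
            "radiological_followup_months": p.radiological_followup_months,
        }
        for c in Comorbidity:
            row[c.value] = int(c in p.comorbidities)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    if results is not None:
        cls = {r.patient_id: r.concordance_class.value for r in results}
        df["concordance_class"] = df.index.map(cls)
    return df


def describe(cohort: Cohort) -> pd.DataFrame:
    """Baseline summary table: median (IQR) / n (%) per characteristic."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = covariate_frame(cohort)
    n = len(df)
    rows = []

    def med_iqr(series: pd.Series) -> str:
        q1, q2, q3 = series.quantile([0.25, 0.5, 0.75])
        return f"{q2:g} ({q1:g}–{q3:g})"

    rows.append(("n", str(n)))
    rows.append(("Age, years, median (IQR)", med_iqr(df["age"])))
    rows.append(("Male sex, n (%)", f"{int(df['male'].sum())} ({100 * df['male'].mean():.1f})"))
    rows.append(("Leading cyst size, mm, median (IQR)", med_iqr(df["cyst_size_mm"])))
    rows.append(
        (
            "Multiple cysts at baseline, n (%)",
            f"{int(df['multiple_cysts'].sum())} ({100 * df['multiple_cysts'].mean():.1f})",
        )
    )
    rows.append(
        ("Radiological follow-up, months, median (IQR)", med_iqr(df["radiological_followup_months"]))
    )
    for c in Comorbidity:
        rows.append(
            (f"{c.value}, n (%)", f"{int(df[c.value].sum())} ({100 * df[c.value].mean():.1f})")
        )
    return pd.DataFrame(rows, columns=["characteristic", "value"]).set_index("characteristic")


def _group_masks(df: pd.DataFrame, grouping: Grouping) -> tuple[pd.Series, pd.Series, str, str]:
    cls = df["concordance_class"]
    if grouping is Grouping.CONCORDANT_VS_NOT:
        a = cls == ConcordanceClass.CONCORDANT.value
        b = cls.isin([ConcordanceClass.OVER.value, ConcordanceClass.UNDER.value])
        return a, b, "concordant", "non_concordant"
    a = cls == ConcordanceClass.OVER.value
    b = cls == ConcordanceClass.UNDER.value
    return a, b, "over", "under"


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    return float(sps.fisher_exact(np.asarray(table))[1])


def categorical_test(x: pd.Series, y: pd.Series) -> tuple[StatTest, Optional[float], float]:
    """Chi-square on the 2x2 table of binary covariate vs group, switching
    to Fisher's exact test when any expected count is below 5."""
    table = np.array(
        [
            [int(((x == v) & (y == g)).sum()) for g in (0, 1)]
            for v in (0, 1)
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return StatTest.FISHER_EXACT, None, 1.0
    expected = sps.contingency.expected_freq(table)
    if (expected < FISHER_MIN_EXPECTED).any():
        return StatTest.FISHER_EXACT, None, fisher_exact_p(table)
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return StatTest.CHI_SQUARE, float(stat), float(p)


def continuous_test(
    a: np.ndarray, b: np.ndarray, kind: StatTest
) -> tuple[Optional[float], float]:
    if kind is StatTest.KRUSKAL_WALLIS:
        stat, p = sps.kruskal(a, b)
        return float(stat), float(p)
    n = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    method = "exact" if (n <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p)


def univariable_screen(
    cohort: Cohort,
    results: list[AuditResult],
    grouping: Grouping = Grouping.CONCORDANT_VS_NOT,
) -> list[UnivariableResult]:
    """One test per covariate comparing the two management groups."""
    df = covariate_frame(cohort, results)
    a_mask, b_mask, a_name, b_name = _group_masks(df, grouping)
    if a_mask.sum() == 0 or b_mask.sum() == 0:
        raise ValueError(f"grouping {grouping.value}: one group is empty")
    out: list[UnivariableResult] = []
    group = pd.Series(np.where(a_mask, 1, np.where(b_mask, 0, -1)), index=df.index)
    used = group >= 0
    cont_kind = (
        StatTest.KRUSKAL_WALLIS if grouping is Grouping.OVER_VS_UNDER else StatTest.MANN_WHITNEY
    )
    for var in CONTINUOUS_COVARIATES:
        a = df.loc[a_mask, var].to_numpy(float)
        b = df.loc[b_mask, var].to_numpy(float)
        stat, p = continuous_test(a, b, cont_kind)

        def miqr(v: np.ndarray) -> str:
            return f"{np.median(v):g} ({np.percentile(v, 25):g}–{np.percentile(v, 75):g})"

        out.append(
            UnivariableResult(
                variable=var,
                test=cont_kind,
                statistic=stat,
                p_value=p,
                group_summaries={a_name: miqr(a), b_name: miqr(b)},
            )
        )
    for var in BINARY_COVARIATES:
        kind, stat, p = categorical_test(df.loc[used, var], group[used])
        summaries = {
            a_name: f"{100 * df.loc[a_mask, var].mean():.1f}%",
            b_name: f"{100 * df.loc[b_mask, var].mean():.1f}%",
        }
        out.append(
            UnivariableResult(
                variable=var, test=kind, statistic=stat, p_value=p, group_summaries=summaries
            )
        )
    return out


def fit_logistic(
    df: pd.DataFrame, outcome: pd.Series, covariates: list[str], outcome_name: str
) -> LogisticModelResult:
    X = sm.add_constant(df[covariates].astype(float), has_constant="add")
    y = outcome.astype(float)
    for var in covariates:
        col = df[var]
        if col.nunique() == 2 and (pd.crosstab(col, y).to_numpy() == 0).any():
            # a zero cell in covariate x outcome: ML estimate diverges
            raise SeparationError(
                f"complete or quasi-complete separation by covariate {var!r}"
            )
    model = sm.Logit(y, X)
    try:
        fit = model.fit(disp=0, maxiter=200)
    except Exception as err:  # pragma: no cover - statsmodels raise paths vary
        raise SeparationError(f"logistic fit failed: {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge")
    conf = fit.conf_int()
    terms = [
        LogisticTerm(
            variable=var,
            odds_ratio=float(np.exp(fit.params[var])),
            ci_lower=float(np.exp(conf.loc[var, 0])),
            ci_upper=float(np.exp(conf.loc[var, 1])),
            p_value=float(fit.pvalues[var]),
        )
        for var in covariates
    ]
    return LogisticModelResult(
        outcome=outcome_name, terms=terms, n_used=int(len(y)), selected=covariates
    )


def select_and_fit(
    cohort: Cohort,
    results: list[AuditResult],
    outcome: str = "concordant",
    forced: tuple[str, ...] = ("age", "male"),
    age_under_50: bool = False,
) -> LogisticModelResult:
    """Screen covariates univariably at p < 0.2, then fit a multivariable
    logistic model with age and sex always included.

    ``outcome='concordant'`` models guideline concordance on the whole
    audited cohort; ``outcome='conservative_vs_liberal'`` models
    over- vs under-surveillance within the non-concordant subgroup.
    ``age_under_50`` swaps the continuous age term for an under-50
    indicator.
    """
    if outcome == "concordant":
        grouping = Grouping.CONCORDANT_VS_NOT
    elif outcome == "conservative_vs_liberal":
        grouping = Grouping.OVER_VS_UNDER
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    screen = univariable_screen(cohort, results, grouping)
    screened = [
        r.variable
        for r in screen
        if r.p_value < SCREEN_P_THRESHOLD and r.variable not in ("age", "radiological_followup_months")
    ]
    df = covariate_frame(cohort, results)
    a_mask, b_mask, _, _ = _group_masks(df, grouping)
    used = a_mask | b_mask
    df = df.loc[used].copy()
    y = a_mask.loc[used].astype(int)
    if age_under_50:
        df["age_under_50"] = (df["age"] < 50).astype(int)
        forced = tuple("age_under_50" if f == "age" else f for f in forced)
    covariates = list(dict.fromkeys(list(forced) + screened))
    # avoid entering a variable and its own dichotomization together
    if "cyst_size_mm" in covariates and "cyst_gt_20mm" in covariates:
        covariates.remove("cyst_size_mm")
    return fit_logistic(df, y, covariates, outcome)
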