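"""Rule-engine behaviour: growth rate, feature detection, precedence."""

import datetime as dt

import numpy as np
import pytest
from pydantic import ValidationError

from cystwatch import (
    Action,
    CystObservation,
    FeatureAssessment,
    GrowthUndefined,
    Hrs,
    Wf,
    assess_features,
    compute_growth_rate,
    load_policy,
    recommend,
)
from cystwatch.engine import ACTION_INTENSITY, recommend_from_assessment

from conftest import INDEX, make_patient


def obs_series(sizes_at_months):
    from cystwatch.models import add_months

    return [
        CystObservation(
            observation_date=add_months(INDEX, months), leading_cyst_size=size
        )
        for months, size in sizes_at_months
    ]


class TestGrowthRate:
    def test_six_mm_over_24_months(self):
        series = obs_series([(0, 10.0), (24, 16.0)])
        assert compute_growth_rate(series) == pytest.approx(6.0, rel=1e-3)

    def test_stable_size_any_spacing(self):
        series = obs_series([(0, 10.0), (13, 10.0)])
        assert compute_growth_rate(series) == pytest.approx(0.0)

    def test_first_vs_last_within_window_matches_regression_on_collinear(self):
        series = obs_series([(0, 10.0), (12, 12.5), (24, 15.0)])
        endpoint = compute_growth_rate(series)
        slope = compute_growth_rate(series, use_regression=True)
        assert endpoint == pytest.approx(5.0, rel=2e-2)
        assert endpoint == pytest.approx(slope, rel=2e-2)

    def test_single_observation_signals_undefined(self):
        with pytest.raises(GrowthUndefined):
            compute_growth_rate(obs_series([(0, 10.0)]))

    def test_observation_outside_trailing_window_ignored(self):
        # only the last point lies within 24 months of the end: undefined
        series = obs_series([(0, 10.0), (40, 20.0)])
        with pytest.raises(GrowthUndefined):
            compute_growth_rate(series)

    def test_unordered_dates_rejected(self):
        series = obs_series([(0, 10.0), (12, 11.0)])
        with pytest.raises(ValueError, match="increasing"):
            compute_growth_rate(list(reversed(series)))


class TestFeatureDetection:
    def test_duct_ten_mm_is_stigmata_boundary_inclusive(self, policy):
        patient = make_patient(mpd_diameter=10.0)
        fa = assess_features(patient, INDEX, policy)
        assert Hrs.MPD_GE_10MM in fa.high_risk_stigmata
        assert Wf.MPD_5_TO_9MM not in fa.worrisome_features

    def test_three_simultaneous_worrisome_features(self, policy):
        patient = make_patient(
            size_mm=30.0,
            mpd_diameter=7.0,
            mural_nodule_size=4.0,
            mural_nodule_enhancing=False,
        )
        fa = assess_features(patient, INDEX, policy)
        assert fa.high_risk_stigmata == frozenset()
        assert fa.worrisome_features == {
            Wf.CYST_GE_30MM,
            Wf.MPD_5_TO_9MM,
            Wf.NODULE_LT_5MM,
        }
        assert fa.wf_count == 3

    def test_normal_study_has_no_features(self, policy):
        fa = assess_features(make_patient(size_mm=10.0), INDEX, policy)
        assert fa.high_risk_stigmata == frozenset()
        assert fa.worrisome_features == frozenset()
        assert fa.wf_count == 0

    def test_growth_threshold_is_strict(self, policy):
        # "> 5 mm / 2 years": exactly 5 does not qualify, just above does
        from cystwatch.engine import assess_observation

        obs = make_patient(size_mm=10.0).observations[0]
        at_boundary = assess_observation(obs, policy, growth_rate=5.0)
        assert Wf.GROWTH_GT_5MM_PER_2Y not in at_boundary.worrisome_features
        above = assess_observation(obs, policy, growth_rate=5.01)
        assert Wf.GROWTH_GT_5MM_PER_2Y in above.worrisome_features

    def test_rapid_growth_detected_through_observation_series(self, policy):
        patient = make_patient(size_mm=10.0, extra_obs=[(24.0, 17.0)])
        fa = assess_features(
            patient, patient.observations[-1].observation_date, policy
        )
        assert Wf.GROWTH_GT_5MM_PER_2Y in fa.worrisome_features

    def test_missing_optional_fields_mean_feature_absent(self, policy):
        fa = assess_features(make_patient(mpd_diameter=None, ca19_9=None), INDEX, policy)
        assert fa.wf_count == 0

    def test_kyoto_additions_can_be_switched_off(self, policy):
        relaxed = policy.model_copy(update={"include_kyoto_wfs": False})
        patient = make_patient(acute_pancreatitis_episode=True, new_onset_diabetes=True)
        assert assess_features(patient, INDEX, policy).wf_count == 2
        assert assess_features(patient, INDEX, relaxed).wf_count == 0

    def test_wf_count_must_match_set(self):
        with pytest.raises(ValidationError):
            FeatureAssessment(worrisome_features=frozenset({Wf.WALL_THICKENED}), wf_count=2)

    def test_duct_grades_mutually_exclusive(self):
        with pytest.raises(ValidationError):
            FeatureAssessment(
                high_risk_stigmata=frozenset({Hrs.MPD_GE_10MM}),
                worrisome_features=frozenset({Wf.MPD_5_TO_9MM}),
                wf_count=1,
            )


class TestRecommend:
    def test_enhancing_nodule_in_fit_patient_means_surgery(self, policy):
        patient = make_patient(mural_nodule_size=6.0, mural_nodule_enhancing=True)
        rec = recommend(patient, INDEX, policy)
        assert rec.action is Action.SURGERY_REFERRAL
        assert rec.interval_months is None

    def test_stigmata_in_unfit_patient_means_eus_not_surgery(self, policy):
        patient = make_patient(obstructive_jaundice=True, fit=False)
        rec = recommend(patient, INDEX, policy)
        assert rec.action is Action.EUS_SURVEILLANCE
        assert rec.interval_months == 6.0

    def test_single_worrisome_feature_routes_to_eus(self, policy):
        rec = recommend(make_patient(wall_thickened=True), INDEX, policy)
        assert rec.action is Action.EUS_SURVEILLANCE
        assert rec.interval_months == 6.0

    def test_small_quiet_cyst_gets_default_band(self, policy):
        rec = recommend(make_patient(size_mm=10.0), INDEX, policy)
        assert rec.action is Action.IMAGING_SURVEILLANCE
        assert rec.modality.value == "mri_mrcp"
        assert rec.interval_months == 6.0
        # after the first visit the stable interval applies
        rec2 = recommend(make_patient(size_mm=10.0), INDEX, policy, visit_number=1)
        assert rec2.interval_months == 18.0

    def test_middle_band_schedule(self, policy):
        intervals = [
            recommend(make_patient(size_mm=25.0), INDEX, policy, visit_number=v).interval_months
            for v in range(4)
        ]
        assert intervals == [6.0, 6.0, 12.0, 12.0]

    def test_no_observation_before_date_is_an_error(self, policy):
        with pytest.raises(ValueError, match="no observation"):
            recommend(make_patient(), INDEX - dt.timedelta(days=1), policy)

    def test_rationale_records_policy_checksum_and_rules(self, policy):
        rec = recommend(make_patient(wall_thickened=True), INDEX, policy)
        assert rec.rationale[0].startswith("policy:")
        assert policy.checksum() in rec.rationale[0]
        assert any(line.startswith("rule:") for line in rec.rationale)

    def test_determinism_bitwise_stable(self, policy):
        patient = make_patient(size_mm=22.0, mpd_diameter=6.0)
        a = recommend(patient, INDEX, policy)
        b = recommend(patient, INDEX, policy)
        assert a.model_dump() == b.model_dump()


class TestPolicyLoading:
    def test_default_file_parses_and_covers_sizes(self, policy):
        bands = sorted(policy.size_bands, key=lambda b: b.lower_mm)
        assert bands[0].lower_mm == 0
        assert bands[-1].upper_mm == 30
        assert all(a.upper_mm == b.lower_mm for a, b in zip(bands, bands[1:]))

    def test_overlapping_bands_rejected(self, policy, tmp_path):
        import yaml

        data = policy.model_dump(mode="json")
        data["size_bands"][1]["lower_mm"] = 15
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(data))
        with pytest.raises(Exception, match="overlap"):
            load_policy(path)

    def test_modified_threshold_propagates(self, policy):
        tighter = policy.model_copy(deep=True)
        tighter.thresholds.cyst_wf_mm = 25.0
        fa = assess_features(make_patient(size_mm=26.0), INDEX, tighter)
        assert Wf.CYST_GE_30MM in fa.worrisome_features
        fa_default = assess_features(make_patient(size_mm=26.0), INDEX, policy)
        assert Wf.CYST_GE_30MM not in fa_default.worrisome_features


class TestMonotonicity:
    def test_adding_features_never_deescalates(self, policy):
        """Adding any worrisome feature never lengthens the interval or
        weakens the action; any stigma forces referral for fit patients."""
        rng = np.random.default_rng(0)
        all_wf = list(Wf)
        for _ in range(300):
            base_wf = frozenset(
                w for w in all_wf if rng.random() < 0.25
            )
            size = float(rng.uniform(1, 29))
            base = FeatureAssessment(
                worrisome_features=base_wf, wf_count=len(base_wf)
            )
            rec0 = recommend_from_assessment(base, size, True, policy)
            for w in all_wf:
                if w in base_wf:
                    continue
                grown = frozenset(base_wf | {w})
                fa = FeatureAssessment(worrisome_features=grown, wf_count=len(grown))
                rec1 = recommend_from_assessment(fa, size, True, policy)
                assert (
                    ACTION_INTENSITY[rec1.action] >= ACTION_INTENSITY[rec0.action]
                )
                if rec0.interval_months and rec1.interval_months:
                    assert rec1.interval_months <= rec0.interval_months
            for h in Hrs:
                wf_ok = base_wf - (
                    {Wf.MPD_5_TO_9MM} if h is Hrs.MPD_GE_10MM else set()
                ) - ({Wf.NODULE_LT_5MM} if h is Hrs.ENHANCING_NODULE_GE_5MM else set())
                fa = FeatureAssessment(
                    high_risk_stigmata=frozenset({h}),
                    worrisome_features=frozenset(wf_ok),
                    wf_count=len(wf_ok),
                )
                assert (
                    recommend_from_assessment(fa, size, True, policy).action
                    is Action.SURGERY_REFERRAL
                )
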