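"""New-user cohort derivation: index, adherence, enrolment, outcomes, attrition."""

import numpy as np
import pandas as pd
import pytest

from fmasurv.cohort import (
    AmbiguousIndexError,
    CodeMap,
    StudyWindows,
    apply_attrition,
    assign_index,
    check_continuous_enrolment,
    compute_followup,
    compute_pdc,
    derive_outcome,
    discontinuation_day,
    impute_region,
)
from fmasurv.synthetic import generate_claims

DAY0 = pd.Timestamp("2013-01-01")


def day(offset):
    return DAY0 + pd.Timedelta(days=int(offset))


def fills_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "code", "days_supply"])


def windows():
    return StudyWindows()


class TestAssignIndex:
    def test_single_fill(self):
        f = fills_frame([("p1", "2013-05-01", "RX_DMF", 30)])
        out = assign_index(f, windows(), CodeMap())
        assert out.loc["p1", "index_arm"] == "DMF"
        assert str(out.loc["p1", "index_date"].date()) == "2013-05-01"

    def test_earliest_fill_wins(self):
        f = fills_frame(
            [("p1", "2014-02-01", "RX_DMF", 30), ("p1", "2013-06-01", "RX_TER", 30)]
        )
        out = assign_index(f, windows(), CodeMap())
        assert out.loc["p1", "index_arm"] == "TER"
        assert str(out.loc["p1", "index_date"].date()) == "2013-06-01"

    def test_fill_outside_window_omitted(self):
        f = fills_frame([("p1", "2012-11-01", "RX_DMF", 30)])
        out = assign_index(f, windows(), CodeMap())
        assert "p1" not in out.index

    def test_same_day_tie_is_an_error(self):
        f = fills_frame(
            [("p1", "2013-05-01", "RX_DMF", 30), ("p1", "2013-05-01", "RX_TER", 30)]
        )
        with pytest.raises(AmbiguousIndexError, match="p1"):
            assign_index(f, windows(), CodeMap())


class TestPDC:
    def test_full_year_supply(self):
        f = fills_frame([("p1", day(0), "RX_DMF", 365)])
        assert compute_pdc(f, 0 + (DAY0 - pd.Timestamp("1970-01-01")).days, 365, {"RX_DMF"}) == 1.0

    def test_two_disjoint_90_day_fills(self):
        base = (DAY0 - pd.Timestamp("1970-01-01")).days
        f = fills_frame([("p1", day(0), "RX_DMF", 90), ("p1", day(90), "RX_DMF", 90)])
        assert compute_pdc(f, base, 365, {"RX_DMF"}) == pytest.approx(180 / 365)

    def test_overlapping_fills_union_counting(self):
        base = (DAY0 - pd.Timestamp("1970-01-01")).days
        f = fills_frame([("p1", day(0), "RX_DMF", 90), ("p1", day(45), "RX_DMF", 90)])
        assert compute_pdc(f, base, 365, {"RX_DMF"}) == pytest.approx(135 / 365)

    def test_nonpositive_supply_rejected(self):
        base = (DAY0 - pd.Timestamp("1970-01-01")).days
        f = fills_frame([("p1", day(0), "RX_DMF", 0)])
        with pytest.raises(ValueError):
            compute_pdc(f, base, 365, {"RX_DMF"})


class TestContinuousEnrolment:
    base = (pd.Timestamp("2015-01-01") - pd.Timestamp("1970-01-01")).days

    def span(self, a, b):
        return pd.DataFrame(
            {
                "patient_id": ["p1"] * len(a),
                "start_date": [pd.Timestamp("1970-01-01") + pd.Timedelta(days=x) for x in a],
                "end_date": [pd.Timestamp("1970-01-01") + pd.Timedelta(days=x) for x in b],
            }
        )

    def test_full_coverage(self):
        e = self.span([self.base - 365], [self.base + 365])
        assert check_continuous_enrolment(e, self.base, windows())

    def test_25_day_gap_allowed(self):
        e = self.span(
            [self.base - 365, self.base - 75], [self.base - 101, self.base + 365]
        )
        assert check_continuous_enrolment(e, self.base, windows())

    def test_45_day_gap_rejected(self):
        e = self.span(
            [self.base - 365, self.base - 55], [self.base - 101, self.base + 365]
        )
        assert not check_continuous_enrolment(e, self.base, windows())

    def test_total_gap_mode(self):
        w = StudyWindows(gap_mode="total")
        # two 20-day gaps: each fine per-gap, 40 total exceeds the allowance
        e = self.span(
            [self.base - 365, self.base - 200, self.base - 50],
            [self.base - 221, self.base - 71, self.base + 365],
        )
        assert check_continuous_enrolment(e, self.base, windows())
        assert not check_continuous_enrolment(e, self.base, w)


class TestOutcomes:
    def dx(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "date", "code"])

    def test_t2d_second_diagnosis_dates_event(self):
        d = self.dx([("p1", day(50), "DX_T2D"), ("p1", day(80), "DX_T2D")])
        out = derive_outcome(d, fills_frame([]), CodeMap(), "t2d")
        assert out.loc["p1"] == (day(80) - pd.Timestamp("1970-01-01")).days

    def test_t2d_diagnosis_plus_medication(self):
        d = self.dx([("p1", day(100), "DX_T2D")])
        f = fills_frame([("p1", day(130), "RX_DIAB", 30)])
        out = derive_outcome(d, f, CodeMap(), "t2d")
        assert out.loc["p1"] == (day(130) - pd.Timestamp("1970-01-01")).days

    def test_single_ckd_diagnosis_suffices(self):
        d = self.dx([("p1", day(200), "DX_CKD")])
        out = derive_outcome(d, fills_frame([]), CodeMap(), "ckd")
        assert out.loc["p1"] == (day(200) - pd.Timestamp("1970-01-01")).days

    def test_cvd_is_earliest_component(self):
        d = self.dx([("p1", day(300), "DX_MI"), ("p1", day(150), "DX_STROKE")])
        out = derive_outcome(d, fills_frame([]), CodeMap(), "cvd")
        assert out.loc["p1"] == (day(150) - pd.Timestamp("1970-01-01")).days

    def test_composite_is_earliest_of_components(self):
        d = self.dx([("p1", day(400), "DX_CKD"), ("p1", day(90), "DX_AHF")])
        out = derive_outcome(d, fills_frame([]), CodeMap(), "composite")
        assert out.loc["p1"] == (day(90) - pd.Timestamp("1970-01-01")).days

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            derive_outcome(self.dx([]), fills_frame([]), CodeMap(), "gout")


class TestFollowup:
    base = (pd.Timestamp("2015-01-01") - pd.Timestamp("1970-01-01")).days

    def enrol(self, spans):
        return pd.DataFrame(
            {
                "patient_id": ["p1"] * len(spans),
                "start_date": [pd.Timestamp("1970-01-01") + pd.Timedelta(days=a) for a, _ in spans],
                "end_date": [pd.Timestamp("1970-01-01") + pd.Timedelta(days=b) for _, b in spans],
            }
        )

    def test_censored_at_study_end(self):
        study_end = (pd.Timestamp("2019-12-31") - pd.Timestamp("1970-01-01")).days
        e = self.enrol([(self.base - 365, study_end)])
        t, flag, reason = compute_followup(e, self.base, windows())
        assert (flag, reason) == (0, "study_end")
        assert t == pytest.approx((study_end - self.base) / 365.25)

    def test_disenrollment_gap_over_90_days(self):
        e = self.enrol([(self.base - 365, self.base + 399), (self.base + 520, self.base + 1500)])
        t, flag, reason = compute_followup(e, self.base, windows())
        assert (flag, reason) == (0, "disenrollment")
        assert t == pytest.approx(400 / 365.25)

    def test_on_treatment_censors_before_event(self):
        study_end = (pd.Timestamp("2019-12-31") - pd.Timestamp("1970-01-01")).days
        e = self.enrol([(self.base - 365, study_end)])
        t, flag, reason = compute_followup(
            e, self.base, windows(), event_day=self.base + 350,
            discontinuation_day=self.base + 300, mode="on_treatment",
        )
        assert (flag, reason) == (0, "discontinuation")
        assert t == pytest.approx(300 / 365.25)

    def test_event_before_censoring(self):
        study_end = (pd.Timestamp("2019-12-31") - pd.Timestamp("1970-01-01")).days
        e = self.enrol([(self.base - 365, study_end)])
        t, flag, reason = compute_followup(e, self.base, windows(), event_day=self.base + 100)
        assert (flag, reason) == (1, "event")
        assert t == pytest.approx(100 / 365.25)

    def test_discontinuation_day_from_supply_gap(self):
        f = fills_frame(
            [("p1", day(0), "RX_DMF", 30), ("p1", day(30), "RX_DMF", 30),
             ("p1", day(200), "RX_DMF", 30)]
        )
        base = (DAY0 - pd.Timestamp("1970-01-01")).days
        # coverage ends day 60; gap to day 200 exceeds 60 -> discontinued at 60
        assert discontinuation_day(f, base, {"RX_DMF"}, gap=60) == base + 60


class TestImputeRegion:
    def test_missing_set_to_mode(self):
        df = pd.DataFrame({"region": ["South", "South", "West", None]})
        out = impute_region(df)
        assert out["region"].iloc[3] == "South"

    def test_no_missing_unchanged(self):
        df = pd.DataFrame({"region": ["South", "West"]})
        pd.testing.assert_frame_equal(impute_region(df), df)

    def test_tie_breaks_lexicographically(self):
        df = pd.DataFrame({"region": ["West", "South", "West", "South", None]})
        assert impute_region(df)["region"].iloc[4] == "South"

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_region(pd.DataFrame({"region": [None, None]}))


class TestAttrition:
    def test_hand_walked_ten_patient_fixture(self, claims_fixture_config):
        bundle = generate_claims(claims_fixture_config)
        cohort, report = apply_attrition(bundle)
        nonzero = [s["n_removed"] for s in report.steps if s["n_removed"] > 0]
        assert nonzero == [2, 1, 1, 1]
        assert report.final_n == 5
        by_rule = {s["rule"]: s["n_removed"] for s in report.steps}
        assert by_rule["PDC >= 60%"] == 2
        assert by_rule["continuous enrolment (30-day gap allowed)"] == 1
        assert by_rule["age >= 18 at index"] == 1
        assert by_rule["no prevalent outcome / prior DMT pre-index"] == 1

    def test_report_telescopes(self, claims_fixture_config):
        bundle = generate_claims(claims_fixture_config)
        cohort, report = apply_attrition(bundle)
        for prev, nxt in zip(report.steps, report.steps[1:]):
            assert prev["n_after"] == nxt["n_before"]
        for s in report.steps:
            assert s["n_after"] == s["n_before"] - s["n_removed"]
        assert report.final_n == len(cohort)

    def test_single_ms_diagnosis_removed_at_ms_step(self, claims_fixture_config):
        cfg = claims_fixture_config
        cfg.violations.low_pdc = 0.0
        cfg.violations.under_age = 0.0
        cfg.violations.prevalent_outcome = 0.0
        cfg.violations.enrolment_gap = 0.0
        cfg.violations.single_ms_dx = 0.1
        bundle = generate_claims(cfg)
        _, report = apply_attrition(bundle)
        by_rule = {s["rule"]: s["n_removed"] for s in report.steps}
        assert by_rule[">= 2 MS diagnoses pre-index"] == 1
        assert sum(by_rule.values()) == 1

    def test_followup_positive_and_event_flag_consistent(self, claims_fixture_config):
        bundle = generate_claims(claims_fixture_config)
        cohort, _ = apply_attrition(bundle)
        assert (cohort["time_years"] > 0).all()
        assert set(cohort["event"].unique()) <= {0, 1}

    def test_on_treatment_never_longer_than_itt(self, claims_fixture_config):
        bundle = generate_claims(claims_fixture_config)
        itt, _ = apply_attrition(bundle, mode="itt")
        ot, _ = apply_attrition(bundle, mode="on_treatment")
        merged = itt.merge(ot, on="patient_id", suffixes=("_itt", "_ot"))
        assert (merged["time_years_ot"] <= merged["time_years_itt"] + 1e-12).all()

    def test_missing_table_rejected(self, claims_fixture_config):
        bundle = generate_claims(claims_fixture_config)
        bundle.fills = None
        with pytest.raises(ValueError, match="fills"):
            apply_attrition(bundle)


class TestCodeMap:
    def test_overlapping_drug_classes_rejected(self):
        from fmasurv.synthetic import default_code_vocabulary

        vocab = default_code_vocabulary()
        vocab["dmt"]["TER"] = {"RX_DMF"}
        with pytest.raises(ValueError, match="disjoint"):
            CodeMap(vocab)

    def test_empty_concept_rejected(self):
        from fmasurv.synthetic import default_code_vocabulary

        vocab = default_code_vocabulary()
        vocab["ckd"] = set()
        with pytest.raises(ValueError, match="ckd"):
            CodeMap(vocab)
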