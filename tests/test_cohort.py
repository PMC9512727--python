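"""Eligibility funnel, hierarchical assignment and baseline covariates."""

from __future__ import annotations

import pandas as pd
import pytest

from osteoepi import assign_treatment_group, baseline_covariates, select_cohort
from osteoepi.config import SelectionParams

from conftest import enrolled, make_bundle


def rx(pid, cls, date, supply=30):
    return {"person_id": pid, "drug_class": cls, "fill_date": date,
            "days_supplied": supply}


def dx(pid, code, date, setting="inpatient"):
    return {"person_id": pid, "code": code, "date": date, "setting": setting}


def _select(bundle):
    return select_cohort(bundle, SelectionParams())


class TestFunnel:
    def test_age_boundary_at_index(self):
        # 49.9 years at index -> out; shift birth a year earlier -> in
        young = make_bundle(
            [enrolled("P1", birth="1965-05-15")],
            [rx("P1", "denosumab", "2015-04-01", 180)])
        members, attr = _select(young)
        assert len(members) == 0
        assert attr.loc[attr.criterion == "age_ge_50", "n_excluded"].item() == 1

        old = make_bundle(
            [enrolled("P1", birth="1964-05-15")],
            [rx("P1", "denosumab", "2015-04-01", 180)])
        members, _ = _select(old)
        assert list(members.person_id) == ["P1"]
        assert members.age_at_index.iloc[0] == pytest.approx(50.88, abs=0.01)

    def test_washout_23_months_excludes_25_months_includes(self):
        base = [rx("P1", "denosumab", "2014-06-01", 180)]
        near = make_bundle([enrolled("P1")],
                           base + [rx("P1", "denosumab", "2012-07-01", 180)])
        members, attr = _select(near)
        assert len(members) == 0
        assert attr.loc[attr.criterion == "new_user_washout_24_months",
                        "n_excluded"].item() == 1

        far = make_bundle([enrolled("P1")],
                          base + [rx("P1", "denosumab", "2012-05-01", 180)])
        members, _ = _select(far)
        assert list(members.index_date) == [pd.Timestamp("2014-06-01")]

    def test_cancer_history_excludes(self):
        b = make_bundle(
            [enrolled("P1"), enrolled("P2")],
            [rx("P1", "oral_bisphosphonate", "2014-02-01"),
             rx("P2", "oral_bisphosphonate", "2014-02-01")],
            [dx("P1", "C50.9", "2012-07-01", "outpatient")])
        members, attr = _select(b)
        assert list(members.person_id) == ["P2"]
        assert attr.loc[attr.criterion == "no_exclusion_diagnosis",
                        "n_excluded"].item() == 1

    def test_short_history_excluded(self):
        b = make_bundle(
            [enrolled("P1", start="2014-01-01")],
            [rx("P1", "hrt", "2015-06-01", 90)])
        members, attr = _select(b)
        assert len(members) == 0
        assert attr.loc[attr.criterion == "history_ge_24_months",
                        "n_excluded"].item() == 1

    def test_empty_bundle_gives_empty_cohort_full_attrition(self):
        members, attr = _select(make_bundle())
        assert members.empty
        assert len(attr) == 6
        assert (attr.n_after <= attr.n_before).all()

    def test_missing_column_raises_schema_error(self):
        b = make_bundle([enrolled("P1")], [rx("P1", "hrt", "2015-01-01")])
        b.prescriptions = b.prescriptions.drop(columns=["days_supplied"])
        with pytest.raises(ValueError, match="prescriptions.*days_supplied"):
            _select(b)

    def test_attrition_monotone_and_partition(self, small_bundle):
        members, attr = _select(small_bundle)
        assert (attr.n_after <= attr.n_before).all()
        assert (attr.n_after == attr.n_before - attr.n_excluded).all()
        assert members.person_id.is_unique  # one treatment group per person

    def test_row_order_invariance(self, small_bundle):
        b = small_bundle
        members1, attr1 = _select(b)
        shuffled = make_bundle()
        shuffled.enrollment = b.enrollment.sample(frac=1, random_state=5)
        shuffled.prescriptions = b.prescriptions.sample(frac=1, random_state=6)
        shuffled.diagnoses = b.diagnoses.sample(frac=1, random_state=7)
        shuffled.procedures = b.procedures.sample(frac=1, random_state=8)
        shuffled.code_map = b.code_map
        members2, attr2 = _select(shuffled)
        pd.testing.assert_frame_equal(members1, members2)
        pd.testing.assert_frame_equal(attr1, attr2)


class TestHierarchy:
    def test_denosumab_beats_oral_bp(self):
        fills = pd.DataFrame([rx("P1", "oral_bisphosphonate", "2014-02-01"),
                              rx("P1", "denosumab", "2015-06-01", 180)])
        fills["fill_date"] = pd.to_datetime(fills["fill_date"])
        group, index = assign_treatment_group(fills)
        assert group == "denosumab"
        assert index == pd.Timestamp("2015-06-01")

    def test_single_class(self):
        fills = pd.DataFrame([rx("P1", "hrt", "2016-01-01", 90)])
        fills["fill_date"] = pd.to_datetime(fills["fill_date"])
        assert assign_treatment_group(fills)[0] == "hrt"

    def test_iv_tier_first_filled_subclass_wins(self):
        fills = pd.DataFrame([rx("P1", "iv_ibandronate", "2013-05-01", 90),
                              rx("P1", "iv_zoledronate", "2014-01-01", 365)])
        fills["fill_date"] = pd.to_datetime(fills["fill_date"])
        group, index = assign_treatment_group(fills)
        assert group == "iv_ibandronate"
        assert index == pd.Timestamp("2013-05-01")

    def test_unknown_classes_only_is_not_eligible(self):
        fills = pd.DataFrame([rx("P1", "statin", "2014-01-01")])
        fills["fill_date"] = pd.to_datetime(fills["fill_date"])
        assert assign_treatment_group(fills) is None

    def test_estrogen_only_requires_hysterectomy(self):
        no_hyst = make_bundle([enrolled("P1")], [rx("P1", "estrogen", "2015-01-01", 90)])
        members, _ = _select(no_hyst)
        assert members.empty

        with_hyst = make_bundle(
            [enrolled("P1")], [rx("P1", "estrogen", "2015-01-01", 90)],
            procedures=[{"person_id": "P1", "code": "5-683.0", "date": "2012-03-01"}])
        members, _ = _select(with_hyst)
        assert list(members.treatment_group) == ["hrt"]


class TestBaselineCovariates:
    def _members(self, bundle):
        members, _ = _select(bundle)
        return baseline_covariates(members, bundle)

    def test_no_preindex_claims_all_flags_false(self):
        b = make_bundle([enrolled("P1")], [rx("P1", "denosumab", "2015-06-01", 180)])
        m = self._members(b)
        assert not m[["prior_fracture", "prior_vertebral", "prior_hip",
                      "prior_wrist", "prior_osteoporosis_treatment"]].any().any()

    def test_vertebral_fracture_six_months_before_index(self):
        b = make_bundle(
            [enrolled("P1")], [rx("P1", "denosumab", "2015-06-01", 180)],
            [dx("P1", "S32.0", "2014-12-05")])
        m = self._members(b)
        assert m.prior_fracture.item() and m.prior_vertebral.item()
        assert not m.prior_hip.item()

    def test_other_treatment_in_lookback_sets_prior_treatment(self):
        b = make_bundle(
            [enrolled("P1")],
            [rx("P1", "denosumab", "2015-06-01", 180),
             rx("P1", "raloxifene", "2014-06-01")])
        m = self._members(b)
        assert m.prior_osteoporosis_treatment.item()
        assert m.treatment_group.item() == "denosumab"
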