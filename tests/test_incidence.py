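"""Person-time windowing, rates and own-control IRR estimation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from osteoepi import irr, split_person_time, window_rates
from osteoepi.incidence import (irr_table, person_days_by_window, rate_table,
                                stratified_analysis)


class TestSplitPersonTime:
    def test_400_day_episode(self):
        got = split_person_time(400)
        assert got == {"early": 90, "m4_12": 275, "m13_24": 35,
                       "m25_36": 0, "m37_48": 0}
        assert sum(got.values()) == 400

    def test_exact_early_boundary(self):
        assert split_person_time(90) == {"early": 90, "m4_12": 0, "m13_24": 0,
                                         "m25_36": 0, "m37_48": 0}

    def test_cap_at_48_months(self):
        got = split_person_time(2000)
        assert sum(got.values()) == 1460
        assert got["m37_48"] == 365

    def test_negative_duration_is_hard_error(self):
        with pytest.raises(ValueError):
            split_person_time(-1)
        with pytest.raises(ValueError):
            person_days_by_window(pd.Series([10, -5]))

    def test_vectorised_matches_scalar(self, rng):
        durations = pd.Series(rng.integers(0, 2500, size=50))
        table = person_days_by_window(durations)
        for i, d in durations.items():
            assert table.loc[i].to_dict() == {
                k: float(v) for k, v in split_person_time(int(d)).items()}

    def test_conservation(self, rng):
        durations = pd.Series(rng.integers(0, 3000, size=200))
        total = person_days_by_window(durations).to_numpy().sum()
        assert total == np.minimum(durations, 1460).sum()


class TestWindowRates:
    def test_zero_events(self):
        rates = window_rates(pd.Series([], dtype=object),
                             {"early": 50 * 365.25, "m4_12": 0})
        assert (rates.set_index("window").loc["early", "rate_per_1000py"] == 0)

    def test_simple_arithmetic(self):
        rates = window_rates(pd.Series(["m4_12"] * 10),
                             {"m4_12": 250 * 365.25})
        assert rates.set_index("window").loc["m4_12", "rate_per_1000py"] \
            == pytest.approx(40.0)

    def test_events_without_person_time_is_hard_error(self):
        with pytest.raises(RuntimeError):
            window_rates(pd.Series(["m13_24"]), {"m13_24": 0.0})


class TestIRR:
    def test_equal_rates_give_unity(self):
        res = irr(20, 100.0, 40, 200.0, method="wald")
        assert res["irr"] == pytest.approx(1.0)
        assert res["ci_low"] < 1 < res["ci_high"]

    def test_wald_ci_worked_example(self):
        # 10 events / 100 PY vs 20 events / 100 PY:
        # IRR 0.5, CI = exp(ln 0.5 -/+ 1.96 sqrt(1/10 + 1/20))
        res = irr(20, 100.0, 10, 100.0, method="wald")
        assert res["irr"] == pytest.approx(0.5)
        assert res["ci_low"] == pytest.approx(0.2340, abs=1e-4)
        assert res["ci_high"] == pytest.approx(1.0682, abs=1e-4)

    def test_pct_reduction(self):
        res = irr(100, 100.0, 62, 100.0, method="wald")
        assert res["pct_reduction"] == pytest.approx(38.0)

    def test_symmetry(self):
        a = irr(13, 80.0, 29, 160.0, method="wald")
        b = irr(29, 160.0, 13, 80.0, method="wald")
        assert a["irr"] == pytest.approx(1 / b["irr"])
        assert a["ci_low"] == pytest.approx(1 / b["ci_high"], rel=1e-9)

    def test_exact_symmetry(self):
        a = irr(3, 80.0, 2, 160.0, method="exact")
        b = irr(2, 160.0, 3, 80.0, method="exact")
        assert a["ci_low"] == pytest.approx(1 / b["ci_high"], rel=1e-9)

    def test_zero_early_events_flagged_not_crash(self):
        res = irr(0, 50.0, 4, 100.0)
        assert res["flagged"] and np.isnan(res["irr"])
        assert res["ci_low"] > 0 and np.isinf(res["ci_high"])

    def test_zero_ontx_events_exact_bound(self):
        res = irr(10, 50.0, 0, 100.0)
        assert res["irr"] == 0.0 and res["ci_low"] == 0.0
        assert 0 < res["ci_high"] < np.inf
        assert res["method_used"] == "exact"

    def test_auto_method_switches_on_small_counts(self):
        assert irr(20, 10.0, 4, 10.0)["method_used"] == "exact"
        assert irr(20, 10.0, 5, 10.0)["method_used"] == "wald"

    def test_exact_ci_contains_truth_for_moderate_counts(self):
        res = irr(30, 100.0, 15, 100.0, method="exact")
        assert res["ci_low"] < 0.5 < res["ci_high"]

    def test_wald_coverage_calibration(self):
        """Simulated Poisson window counts at true ratio 0.6: the 95% Wald
        interval covers the truth at close to nominal frequency."""
        rng = np.random.default_rng(2024)
        rate0, py0, py1, r = 0.0876, 1200.0, 2600.0, 0.6
        hits = trials = 0
        for _ in range(500):
            n0 = rng.poisson(rate0 * py0)
            n1 = rng.poisson(rate0 * r * py1)
            if n0 == 0 or n1 == 0:
                continue
            res = irr(n0, py0, n1, py1, method="wald")
            trials += 1
            hits += res["ci_low"] <= r <= res["ci_high"]
        assert trials > 480
        assert 0.93 <= hits / trials <= 0.97


def _toy_cohort():
    episodes = pd.DataFrame({
        "person_id": ["P1", "P2", "P3"],
        "treatment_group": "denosumab",
        "start": pd.to_datetime(["2014-01-01", "2015-01-01", "2016-01-01"]),
        "duration_days": [400, 800, 90],
    })
    events = pd.DataFrame({
        "person_id": ["P1", "P1", "P2", "P3"],
        "site": ["hip", "hip", "clinical_vertebral", "hip"],
        "event_date": pd.to_datetime(
            ["2014-02-01", "2014-08-01", "2016-01-10", "2016-06-01"]),
        "source": "inpatient",
    })
    return episodes, events


class TestTables:
    def test_rate_table_counts_and_windows(self):
        episodes, events = _toy_cohort()
        rates = rate_table(episodes, events).set_index(
            ["fracture_type", "window"])
        # P1: events day 31 (early) and day 212 (m4_12); P2: day 374 (m13_24);
        # P3's event is after their 90-day episode -> dropped
        assert rates.loc[("all", "early"), "events"] == 1
        assert rates.loc[("all", "m4_12"), "events"] == 1
        assert rates.loc[("all", "m13_24"), "events"] == 1
        assert rates.loc[("all", "m37_48"), "events"] == 0
        assert rates.loc[("hip", "early"), "events"] == 1
        assert rates.loc[("clinical_vertebral", "m13_24"), "events"] == 1
        # person-time: early 90+90+90, m4_12 275+275+0 days
        assert rates.loc[("all", "early"), "person_years"] \
            == pytest.approx(270 / 365.25)
        assert rates.loc[("all", "m4_12"), "person_years"] \
            == pytest.approx(550 / 365.25)

    def test_irr_table_shape(self):
        episodes, events = _toy_cohort()
        out = irr_table(rate_table(episodes, events), method="exact")
        assert set(out.fracture_type) <= {"all", "clinical_vertebral", "hip",
                                          "wrist_forearm"}
        assert set(out.window) <= {"m4_12", "m13_24", "m25_36", "m37_48"}
        assert {"N", "irr", "ci_low", "ci_high", "pct_reduction",
                "method_used", "flagged"} <= set(out.columns)

    def test_degenerate_stratification_equals_overall(self):
        episodes, events = _toy_cohort()
        members = pd.DataFrame({"person_id": ["P1", "P2", "P3"],
                                "prior_fracture": False})
        s_rates, s_irrs = stratified_analysis(members, episodes, events,
                                              "prior_fracture", method="exact")
        assert set(s_rates.stratum) == {"no_prior_fracture"}
        overall = rate_table(episodes, events)
        pd.testing.assert_frame_equal(
            s_rates.drop(columns="stratum"), overall)

    def test_stratified_early_rates_recover_frailty_ratio(self):
        """Patients generated with a doubled fracture hazard and a guaranteed
        pre-index fracture: the ratio of early-window rates between the
        prior-fracture and no-prior-fracture strata recovers the 2-fold
        difference within Monte-Carlo error."""
        import osteoepi as oe
        from osteoepi.cohort import normalize_fills
        from osteoepi.episodes import build_episodes
        from osteoepi.fractures import find_fracture_events
        from osteoepi.pipeline import observed_days_supplied

        cfg = oe.SimConfig.single_class(
            "denosumab", n_patients=15000, seed=13,
            prior_fracture_frac=0.3, prior_fracture_hazard_mult=2.0,
            pre_index_rate_mult=0.0)
        b = oe.generate_bundle(cfg)
        members, _ = oe.select_cohort(b)
        members = oe.baseline_covariates(members, b)
        fills = normalize_fills(b.prescriptions, b.procedures, b.code_map)
        episodes = build_episodes(members, fills, observed_days_supplied(fills),
                                  "2018-12-31")
        events = find_fracture_events(b.diagnoses, b.procedures, b.code_map)
        fx = members[members.followup_ok]
        s_rates, _ = stratified_analysis(
            fx, episodes[episodes.person_id.isin(fx.person_id)], events,
            "prior_fracture")
        early = s_rates[(s_rates.window == "early")
                        & (s_rates.fracture_type == "all")].set_index("stratum")
        ratio = (early.loc["prior_fracture", "rate_per_1000py"]
                 / early.loc["no_prior_fracture", "rate_per_1000py"])
        se = ratio * np.sqrt(1 / early.loc["prior_fracture", "events"]
                             + 1 / early.loc["no_prior_fracture", "events"])
        assert abs(ratio - 2.0) < 3 * se

    def test_unknown_stratifier_raises(self):
        episodes, events = _toy_cohort()
        with pytest.raises(ValueError, match="stratifier"):
            stratified_analysis(pd.DataFrame({"person_id": []}), episodes,
                                events, "nope")
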