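"""KPI formulas on hand-computed fixtures plus structural invariants."""

import numpy as np
import pandas as pd
import pytest

from clawbench import kpi
from clawbench.domain import BENCHMARK_GROUPS

YEAR = 2021  # non-leap


def roster(rows):
    frame = pd.DataFrame(rows, columns=["herd_id", "cow_id", "entry_date",
                                        "exit_date", "calving_dates", "dryoff_dates"])
    frame["entry_date"] = pd.to_datetime(frame["entry_date"])
    frame["exit_date"] = pd.to_datetime(frame["exit_date"])
    return frame


def trims(rows):
    frame = pd.DataFrame(rows, columns=["herd_id", "cow_id", "date", "lesion_code",
                                        "zone", "severity", "recorder", "observer_id"])
    frame["date"] = pd.to_datetime(frame["date"])
    frame["severity"] = frame["severity"].astype("Int64")
    return frame


def lactating_roster(herd, n, entry="2021-01-01", calving="2021-01-15"):
    return roster([(herd, f"{herd}C{i}", entry, None, calving, "")
                   for i in range(n)])


class TestMeanCowNumber:
    def test_one_cow_present_all_year(self):
        ros = roster([("H1", "C1", "2021-01-01", None, "", "")])
        assert kpi.mean_cow_number(ros, YEAR)["H1"] == pytest.approx(1.0, abs=1e-12)

    def test_two_half_year_cows_add_to_one(self):
        ros = roster([
            ("H1", "C1", "2021-01-01", "2021-07-02", "", ""),  # 182 days
            ("H1", "C2", "2021-07-02", None, "", ""),          # 183 days
        ])
        assert kpi.mean_cow_number(ros, YEAR)["H1"] == pytest.approx(1.0, abs=1e-12)

    def test_staggered_roster_matches_daily_enumeration(self):
        ros = roster([
            ("H1", "C1", "2020-11-05", "2021-03-10", "", ""),
            ("H1", "C2", "2021-02-01", None, "", ""),
            ("H1", "C3", "2021-06-15", "2021-06-15", "", ""),  # zero-day presence
            ("H1", "C4", "2021-09-01", "2021-12-31", "", ""),
            ("H1", "C5", "2021-01-01", "2022-02-01", "", ""),
        ])
        assert kpi.mean_cow_number(ros, YEAR)["H1"] == pytest.approx(
            daily_enumeration_oracle(ros, YEAR)["H1"], abs=1e-9)

    def test_empty_roster_gives_empty_series(self):
        assert kpi.mean_cow_number(roster([]), YEAR).empty


def daily_enumeration_oracle(rosters, year):
    """Brute force: count present cows day by day and average."""
    start = pd.Timestamp(year, 1, 1)
    end = pd.Timestamp(year + 1, 1, 1)
    ndays = (end - start).days
    out = {}
    for herd, sub in rosters.groupby("herd_id"):
        total = 0
        for day in pd.date_range(start, end - pd.Timedelta(days=1)):
            for _, row in sub.iterrows():
                exit_ = row["exit_date"]
                if row["entry_date"] <= day and (pd.isna(exit_) or day < exit_):
                    total += 1
        out[herd] = total / ndays
    return out


class TestRecodeSeverity:
    def test_mild_records_of_sensitive_groups_dropped(self):
        records = trims([
            ("H1", "C1", "2021-05-01", "SH-D", 4, 1, "trimmer", "T1"),
            ("H1", "C2", "2021-05-01", "DS", 4, 1, "trimmer", "T1"),
            ("H1", "C3", "2021-05-01", "WLD", 4, 1, "trimmer", "T1"),
            ("H1", "C4", "2021-05-01", "HHE", 4, 1, "trimmer", "T1"),
            ("H1", "C5", "2021-05-01", "SU", 4, 1, "trimmer", "T1"),   # kept: UL
            ("H1", "C6", "2021-05-01", "WLD", 4, 3, "trimmer", "T1"),  # kept: WLA
            ("H1", "C7", "2021-05-01", "WLD", 4, None, "farmer", "F1"),  # kept
        ])
        out = kpi.recode_severity(records)
        assert set(out["cow_id"]) == {"C5", "C6", "C7"}
        assert (out.loc[out["cow_id"] == "C6", "group"] == "WLA").all()
        assert (out.loc[out["cow_id"] == "C7", "group"] == "WLA").all()

    def test_sole_ulcer_severity_one_retained(self):
        records = trims([("H1", "C1", "2021-05-01", "SU", 4, 1, "trimmer", "T1")])
        assert len(kpi.recode_severity(records)) == 1


class TestIrLame:
    def make_loco(self, scores, date="2021-06-01"):
        return pd.DataFrame({
            "herd_id": "H1", "cow_id": [f"H1C{i}" for i in range(len(scores))],
            "date": pd.Timestamp(date), "score": scores, "observer_id": "L1",
        })

    def test_worked_example_thresholds(self):
        ros = lactating_roster("H1", 10)
        loco = self.make_loco([1, 1, 1, 2, 2, 3, 3, 4, 5, 1])
        assert kpi.ir_lame(loco, ros, 2, "all_lactating", YEAR)["H1"] == \
            pytest.approx(60.0, abs=1e-9)
        assert kpi.ir_lame(loco, ros, 3, "all_lactating", YEAR)["H1"] == \
            pytest.approx(40.0, abs=1e-9)
        assert kpi.ir_lame(loco, ros, 4, "all_lactating", YEAR)["H1"] == \
            pytest.approx(20.0, abs=1e-9)

    def test_all_sound_herd_is_zero_everywhere(self):
        ros = lactating_roster("H1", 6)
        loco = pd.concat([self.make_loco([1] * 6, d)
                          for d in ("2021-03-01", "2021-06-01", "2021-09-01")])
        for threshold in (2, 3, 4):
            assert kpi.ir_lame(loco, ros, threshold, "all_lactating", YEAR)["H1"] == 0.0

    def test_mean_over_scoring_dates(self):
        ros = lactating_roster("H1", 4)
        loco = pd.concat([
            self.make_loco([1, 1, 1, 1], "2021-03-01"),   # 0%
            self.make_loco([2, 2, 1, 1], "2021-06-01"),   # 50%
        ])
        assert kpi.ir_lame(loco, ros, 2, "all_lactating", YEAR)["H1"] == \
            pytest.approx(25.0, abs=1e-9)

    def test_dry_cows_form_their_own_group(self):
        ros = roster([
            ("H1", "H1C0", "2021-01-01", None, "2021-01-10", ""),           # lactating
            ("H1", "H1C1", "2021-01-01", None, "2021-01-10", "2021-05-01"),  # dry in June
        ])
        loco = self.make_loco([4, 4], "2021-06-01")
        assert kpi.ir_lame(loco, ros, 2, "dry", YEAR)["H1"] == pytest.approx(100.0)
        assert kpi.ir_lame(loco, ros, 2, "all_lactating", YEAR)["H1"] == \
            pytest.approx(100.0)
        # first 100 DIM excludes both (DIM=142) -> never scored -> NaN
        assert np.isnan(kpi.ir_lame(loco, ros, 2, "first_100_dim", YEAR)["H1"])

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="cow group"):
            kpi.ir_lame(self.make_loco([1]), lactating_roster("H1", 1), 2, "heifers")

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            kpi.ir_lame(self.make_loco([1]), lactating_roster("H1", 1), 5)


class TestIrClawl:
    def test_five_cases_in_twenty_cow_herd(self):
        ros = lactating_roster("H1", 20)
        records = trims([("H1", f"H1C{i}", "2021-05-01", "SU", 4, 2, "trimmer", "T1")
                         for i in range(5)])
        analysis = kpi.recode_severity(records)
        assert kpi.ir_clawl(analysis, ros, "UL", YEAR)["H1"] == \
            pytest.approx(25.0, abs=1e-9)

    def test_counting_modes_differ_on_repeat_visits(self):
        ros = lactating_roster("H1", 10)
        records = trims([
            ("H1", "H1C0", "2021-04-01", "SU", 4, 2, "trimmer", "T1"),
            ("H1", "H1C0", "2021-10-01", "SU", 4, 2, "trimmer", "T1"),
        ])
        analysis = kpi.recode_severity(records)
        assert kpi.ir_clawl(analysis, ros, "UL", YEAR, mode="cow-year")["H1"] == \
            pytest.approx(10.0, abs=1e-9)
        assert kpi.ir_clawl(analysis, ros, "UL", YEAR, mode="cow-visit")["H1"] == \
            pytest.approx(20.0, abs=1e-9)

    def test_group_without_records_is_zero(self):
        ros = lactating_roster("H1", 10)
        records = trims([("H1", "H1C0", "2021-04-01", "SU", 4, 2, "trimmer", "T1")])
        analysis = kpi.recode_severity(records)
        assert kpi.ir_clawl(analysis, ros, "TS", YEAR)["H1"] == 0.0


class TestIrAlarm:
    def test_alarm_counts_acute_dd_but_not_heel_erosion(self):
        ros = lactating_roster("H1", 10)
        records = trims([
            ("H1", "H1C0", "2021-04-01", "HHE", 4, 3, "trimmer", "T1"),  # not alarm
            ("H1", "H1C1", "2021-04-01", "M2", 4, None, "trimmer", "T1"),  # alarm
        ])
        analysis = kpi.recode_severity(records)
        assert kpi.ir_alarm(analysis, ros, YEAR)["H1"] == pytest.approx(10.0, abs=1e-9)

    def test_no_alarm_records_gives_zero(self):
        ros = lactating_roster("H1", 10)
        records = trims([("H1", "H1C0", "2021-04-01", "CC", 4, 2, "trimmer", "T1")])
        analysis = kpi.recode_severity(records)
        assert kpi.ir_alarm(analysis, ros, YEAR)["H1"] == 0.0


class TestDdEndemic:
    def make(self, cow_stage_pairs):
        return trims([("H1", cow, "2021-04-01", stage, 4, None, "trimmer", "T1")
                      for cow, stage in cow_stage_pairs])

    def test_two_affected_cows_is_not_endemic(self):
        records = self.make([("C1", "M2"), ("C2", "M2")])
        assert not kpi.dd_endemic(records, year=YEAR)["H1"]

    def test_three_affected_cows_is_endemic(self):
        records = self.make([("C1", "M4"), ("C2", "M4"), ("C3", "M4")])
        assert kpi.dd_endemic(records, year=YEAR)["H1"]

    def test_repeat_records_on_one_cow_do_not_count(self):
        records = self.make([("C1", "M2")] * 5)
        assert not kpi.dd_endemic(records, year=YEAR)["H1"]

    def test_m0_is_not_a_dd_record(self):
        records = self.make([("C1", "M0"), ("C2", "M0"), ("C3", "M0")])
        assert not kpi.dd_endemic(records, year=YEAR)["H1"]


class TestAcrClaw:
    def make(self, reasons):
        return pd.DataFrame({
            "herd_id": "H1", "cow_id": [f"C{i}" for i in range(len(reasons))],
            "date": pd.Timestamp("2021-08-01"), "reason": reasons,
        })

    def test_two_of_ten_culls(self):
        culls = self.make(["CLAW_LIMB"] * 2 + ["FERTILITY"] * 8)
        assert kpi.acr_claw(culls, YEAR)["H1"] == pytest.approx(20.0, abs=1e-9)

    def test_zero_culls_reports_zero(self):
        culls = self.make(["FERTILITY"])
        out = kpi.acr_claw(culls, YEAR, herds=["H1", "H2"])
        assert out["H2"] == 0.0
        assert out["H1"] == 0.0

    def test_all_claw_culls_is_hundred(self):
        culls = self.make(["CLAW_LIMB"] * 4)
        assert kpi.acr_claw(culls, YEAR)["H1"] == pytest.approx(100.0)


class TestSimulatedInvariants:
    ALARM_ELIGIBLE = ("UL", "WLA", "SW", "IP", "HF", "DD")

    def test_cow_visit_mode_dominates_cow_year(self, small_population):
        pop = small_population
        analysis = kpi.recode_severity(pop.trimming)
        for group in BENCHMARK_GROUPS:
            year_mode = kpi.ir_clawl(analysis, pop.rosters, group, pop.config.year)
            visit_mode = kpi.ir_clawl(analysis, pop.rosters, group,
                                      pop.config.year, mode="cow-visit")
            assert (visit_mode >= year_mode - 1e-9).all()

    def test_alarm_bounded_by_union_of_eligible_groups(self, small_population):
        pop = small_population
        analysis = kpi.recode_severity(pop.trimming)
        alarm = kpi.ir_alarm(analysis, pop.rosters, pop.config.year)
        union = sum(kpi.ir_clawl(analysis, pop.rosters, g, pop.config.year)
                    for g in self.ALARM_ELIGIBLE)
        assert (alarm <= union + 1e-9).all()

    def test_full_kpi_table_shape_and_dd_masking(self, small_population):
        pop = small_population
        kpis = kpi.compute_herd_kpis(pop.trimming, pop.locomotion, pop.rosters,
                                     pop.culling, year=pop.config.year)
        assert len(kpis) == pop.truth.shape[0]
        assert kpis.loc[~kpis["dd_endemic"], "ir_dd"].isna().all()
        assert kpis.loc[kpis["dd_endemic"], "ir_dd"].notna().all()
        assert (kpis["acr_claw"].between(0, 100)).all()
        numeric = kpis[[c for c in kpis.columns if c.startswith("ir_")]]
        assert (numeric.fillna(0) >= 0).all().all()
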