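"""The filter cascade: record rules, herd rules, ledger bookkeeping."""

import pandas as pd
import pytest

from clawbench.validation import (
    HERD_RULES,
    RECORD_RULES,
    ValidationConfig,
    filter_herds,
    validate,
    validate_records,
)

CFG = ValidationConfig(year=2021, trained_observers=frozenset({"TOK"}))


class TestRecordRules:
    def test_all_valid_records_pass_with_empty_ledger(self, record_rule_fixture):
        records, rosters = record_rule_fixture
        clean, ledger = validate_records(records.head(17), rosters, CFG)
        assert len(clean) == 17
        assert ledger.records.empty
        pd.testing.assert_frame_equal(clean, records.head(17))

    def test_one_violation_of_each_rule(self, record_rule_fixture):
        records, rosters = record_rule_fixture
        clean, ledger = validate_records(records, rosters, CFG)
        assert len(clean) == 17
        assert len(ledger.records) == 3
        assert set(ledger.records["rule"]) == set(RECORD_RULES)
        assert ledger.n_input_records == 20
        assert ledger.n_accepted_records + ledger.n_rejected_records == 20

    def test_idempotence(self, record_rule_fixture):
        records, rosters = record_rule_fixture
        clean, _ = validate_records(records, rosters, CFG)
        again, ledger = validate_records(clean, rosters, CFG)
        pd.testing.assert_frame_equal(again, clean)
        assert ledger.records.empty

    def test_rules_are_order_independent(self, record_rule_fixture):
        """The accepted set is the complement of the union of violations, so
        shuffling the input changes nothing but row order."""
        records, rosters = record_rule_fixture
        clean, _ = validate_records(records, rosters, CFG)
        shuffled = records.sample(frac=1.0, random_state=7)
        clean2, _ = validate_records(shuffled, rosters, CFG)
        assert set(clean2.index) == set(clean.index)

    def test_empty_input_is_not_an_error(self, record_rule_fixture):
        records, rosters = record_rule_fixture
        clean, ledger = validate_records(records.iloc[0:0], rosters, CFG)
        assert clean.empty and ledger.records.empty
        assert ledger.n_input_records == 0


class TestHerdRules:
    def test_each_rule_catches_its_herd(self, herd_rule_fixture):
        records, rosters = herd_rule_fixture
        included, ledger = filter_herds(records, rosters, CFG)
        assert included == {"HGOOD"}
        first = ledger.herds[ledger.herds["first_failing"]].set_index("herd_id")
        assert first.loc["HTRAIN", "rule"] == "trained-share"
        assert first.loc["HTRIM", "rule"] == "trim-share"
        assert first.loc["HDIAG", "rule"] == "min-diagnoses"
        assert first.loc["HFREE", "rule"] == "lesion-free"
        assert first.loc["HNOROS", "rule"] == "no-roster"
        assert set(ledger.herds["rule"]) <= set(HERD_RULES)

    def test_measured_values_recorded(self, herd_rule_fixture):
        records, rosters = herd_rule_fixture
        _, ledger = filter_herds(records, rosters, CFG)
        herds = ledger.herds.set_index(["herd_id", "rule"])
        assert herds.loc[("HTRAIN", "trained-share"), "measured"].item() == pytest.approx(11 / 12)
        assert herds.loc[("HTRIM", "trim-share"), "measured"].item() == pytest.approx(0.4)
        assert herds.loc[("HDIAG", "min-diagnoses"), "measured"].item() == 4.0

    def test_thresholds_are_inclusive_boundaries(self):
        """A herd exactly at every threshold (share 0.95, 0.50; 5 groups)
        is included — the criteria read 'at least'."""
        rosters = pd.DataFrame([{
            "herd_id": "HB", "cow_id": f"HBC{i}",
            "entry_date": pd.Timestamp("2021-01-01"), "exit_date": pd.NaT,
            "calving_dates": "2021-02-01", "dryoff_dates": "",
        } for i in range(10)])
        rows = []
        codes = ["SU", "WLD", "M2", "IH", "CC"]
        for i in range(5):  # five distinct cows, five groups
            rows.append({"herd_id": "HB", "cow_id": f"HBC{i}",
                         "date": pd.Timestamp("2021-05-10"), "lesion_code": codes[i],
                         "zone": 4, "severity": 2, "recorder": "trimmer",
                         "observer_id": "TOK"})
        # 19 trained + 1 untrained = exactly 95%
        for i in range(14):
            rows.append({"herd_id": "HB", "cow_id": f"HBC{i % 5}",
                         "date": pd.Timestamp("2021-05-10"), "lesion_code": "NL",
                         "zone": 0, "severity": None, "recorder": "trimmer",
                         "observer_id": "TOK"})
        rows.append({"herd_id": "HB", "cow_id": "HBC0",
                     "date": pd.Timestamp("2021-05-10"), "lesion_code": "NL",
                     "zone": 0, "severity": None, "recorder": "trimmer",
                     "observer_id": "TBAD"})
        records = pd.DataFrame(rows)
        records["severity"] = records["severity"].astype("Int64")
        included, ledger = filter_herds(records, rosters, CFG)
        assert included == {"HB"}
        assert ledger.herds.empty

    def test_relaxing_thresholds_never_shrinks_inclusion(self, herd_rule_fixture):
        records, rosters = herd_rule_fixture
        strict, _ = filter_herds(records, rosters, CFG)
        relaxed_cfg = CFG.model_copy(update={
            "trained_share_min": 0.8, "trim_share_min": 0.3,
            "min_distinct_diagnoses": 4, "require_lesion_free": False})
        relaxed, _ = filter_herds(records, rosters, relaxed_cfg)
        assert strict <= relaxed
        assert {"HTRAIN", "HTRIM", "HDIAG", "HFREE"} <= relaxed
        assert "HNOROS" not in relaxed  # no threshold can conjure a roster

    def test_trusting_all_observers_drops_trained_rule(self, herd_rule_fixture):
        records, rosters = herd_rule_fixture
        cfg = CFG.model_copy(update={"trained_observers": None})
        included, _ = filter_herds(records, rosters, cfg)
        assert "HTRAIN" in included


class TestCombinedCascade:
    def test_validate_composes_both_levels(self, herd_rule_fixture):
        records, rosters = herd_rule_fixture
        final, included, ledger = validate(records, rosters, CFG)
        # HNOROS records die at record level (unrostered cows)
        assert set(ledger.records["rule"]) == {"animal-id"}
        assert included == {"HGOOD"}
        assert set(final["herd_id"]) == {"HGOOD"}
        assert ledger.n_input_records == len(records)

    def test_validate_is_idempotent_end_to_end(self, herd_rule_fixture):
        records, rosters = herd_rule_fixture
        final, included, _ = validate(records, rosters, CFG)
        final2, included2, ledger2 = validate(final, rosters, CFG)
        pd.testing.assert_frame_equal(final2, final)
        assert included2 == included
        assert ledger2.records.empty
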