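"""Shared fixtures: simulated populations and a hand-constructed validation
fixture with known ground truth."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from clawbench.simulate import SimulationConfig, simulate_population

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

FIXTURE_YEAR = 2021  # non-leap: mean cow number of a full-year cow is exactly 1.0


@pytest.fixture(scope="session")
def population500():
    """The main synthetic study population: 500 herds under defaults."""
    return simulate_population(SimulationConfig(n_herds=500, seed=2020))


@pytest.fixture(scope="session")
def small_population():
    """A light population for invariant and round-trip checks."""
    return simulate_population(SimulationConfig(n_herds=40, seed=11))


def _roster_row(herd, cow, entry, exit_=None, calvings=(), dryoffs=()):
    return {
        "herd_id": herd, "cow_id": cow,
        "entry_date": pd.Timestamp(entry),
        "exit_date": pd.Timestamp(exit_) if exit_ else pd.NaT,
        "calving_dates": "|".join(calvings),
        "dryoff_dates": "|".join(dryoffs),
    }


def _trim_row(herd, cow, date, code, severity=2, observer="TOK",
              recorder="trimmer", zone=4):
    return {
        "herd_id": herd, "cow_id": cow, "date": pd.Timestamp(date),
        "lesion_code": code, "zone": zone,
        "severity": severity, "recorder": recorder, "observer_id": observer,
    }


@pytest.fixture(scope="session")
def herd_rule_fixture():
    """Six herds, each probing one herd rule (or passing all of them).

    All cows are present the whole of 2021, so each herd's mean cow number
    equals its roster size exactly.  Ground truth:

    * HGOOD  — 10 cows, 6 trimmed, 5 lesion groups, NL documented: included.
    * HTRAIN — 1 of 10 records by an untrained observer (share 0.90 < 0.95).
    * HTRIM  — only 4 of 10 cows trimmed (share 0.40 < 0.50).
    * HDIAG  — only 4 distinct lesion groups.
    * HFREE  — no lesion-free documentation.
    * HNOROS — records but no roster.
    """
    rosters = []
    for herd in ("HGOOD", "HTRAIN", "HTRIM", "HDIAG", "HFREE"):
        for i in range(10):
            rosters.append(_roster_row(herd, f"{herd}C{i}", "2021-01-01",
                                       calvings=("2021-02-01",)))
    rosters = pd.DataFrame(rosters)

    groups5 = ["SU", "WLD", "M2", "IH", "CC"]  # five distinct benchmark groups
    records = []
    # HGOOD: 6 distinct cows, 5 groups + NL
    for i, code in enumerate(groups5):
        records.append(_trim_row("HGOOD", f"HGOODC{i}", "2021-05-10", code))
    records.append(_trim_row("HGOOD", "HGOODC5", "2021-05-10", "NL", severity=None))
    # HTRAIN: same structure, but one record from an ungated observer
    for i, code in enumerate(groups5):
        obs = "TBAD" if i == 0 else "TOK"
        records.append(_trim_row("HTRAIN", f"HTRAINC{i}", "2021-05-10", code,
                                 observer=obs))
        records.append(_trim_row("HTRAIN", f"HTRAINC{i}", "2021-09-10", code))
    records.append(_trim_row("HTRAIN", "HTRAINC5", "2021-05-10", "NL", severity=None))
    records.append(_trim_row("HTRAIN", "HTRAINC6", "2021-05-10", "NL", severity=None))
    # HTRIM: only 4 distinct cows ever trimmed
    for i, code in enumerate(groups5):
        records.append(_trim_row("HTRIM", f"HTRIMC{i % 4}", "2021-05-10", code))
    records.append(_trim_row("HTRIM", "HTRIMC0", "2021-05-10", "NL", severity=None))
    # HDIAG: 6 cows but only 4 groups
    for i, code in enumerate(["SU", "WLD", "M2", "IH", "IH"]):
        records.append(_trim_row("HDIAG", f"HDIAGC{i}", "2021-05-10", code))
    records.append(_trim_row("HDIAG", "HDIAGC5", "2021-05-10", "NL", severity=None))
    # HFREE: everything but no NL documentation
    for i, code in enumerate(groups5):
        records.append(_trim_row("HFREE", f"HFREEC{i}", "2021-05-10", code))
    records.append(_trim_row("HFREE", "HFREEC5", "2021-05-10", "SU"))
    # HNOROS: records for a herd without roster
    for i, code in enumerate(groups5):
        records.append(_trim_row("HNOROS", f"HNOROSC{i}", "2021-05-10", code))
    records.append(_trim_row("HNOROS", "HNOROSC5", "2021-05-10", "NL", severity=None))
    records = pd.DataFrame(records)
    records["severity"] = records["severity"].astype("Int64")
    return records, rosters


@pytest.fixture(scope="session")
def record_rule_fixture():
    """20 records with exactly one violation of each record-level rule.

    Ground truth: 17 accepted; rejections = one unrostered cow-date
    (``animal-id``), one date outside 2021 (``date-window``), one unknown
    lesion code (``lesion-code``).
    """
    # cows rostered from 2020 so the out-of-year record violates only the
    # date-window rule, not the animal-id rule
    rosters = pd.DataFrame([
        _roster_row("H1", f"H1C{i}", "2020-01-01", calvings=("2021-02-01",))
        for i in range(10)
    ] + [_roster_row("H1", "H1C10", "2021-06-01", "2021-08-01",
                     calvings=("2021-06-01",))])
    rows = []
    for i in range(17):
        rows.append(_trim_row("H1", f"H1C{i % 10}", "2021-05-10",
                              ["SU", "WLD", "M2", "IH", "CC", "NL"][i % 6],
                              severity=None if i % 6 == 5 else 2))
    rows.append(_trim_row("H1", "H1C10", "2021-09-10", "SU"))   # cow already gone
    rows.append(_trim_row("H1", "H1C0", "2020-05-10", "SU"))    # outside study year
    rows.append(_trim_row("H1", "H1C1", "2021-05-10", "XX"))    # unknown code
    records = pd.DataFrame(rows)
    records["severity"] = records["severity"].astype("Int64")
    return records, rosters
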