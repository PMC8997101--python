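"""Record-level plausibility checks and herd-level inclusion criteria.

The filter cascade mirrors how national claw-health data are screened before
benchmarking: individual records must belong to a rostered cow at the record
date, fall inside the study year and carry a resolvable lesion code; herds
are then included only if (in this order of reporting)

1. the herd has a roster at all (``no-roster``),
2. at least 95% of its records come from trained recorders — observers that
   passed the reliability gate (``trained-share``),
3. at least 50% of the mean cow number was trimmed during the year's visits
   (``trim-share``),
4. lesion-free cows were documented too (``lesion-free``) — a stream that
   only ever reports lesions is not trusted to be complete,
5. at least five different claw lesions/diagnoses appear (``min-diagnoses``).

Every decision is written to a rejection ledger so that
accepted + rejected = input, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .domain import NO_LESION_CODE, annotate_records, known_codes
from .kpi import mean_cow_number, year_bounds

RECORD_RULES = ("animal-id", "date-window", "lesion-code")
HERD_RULES = ("no-roster", "trained-share", "trim-share", "lesion-free", "min-diagnoses")


class ValidationConfig(BaseModel):
    """Thresholds of the inclusion cascade (all inclusive "at least" bounds)."""

    year: int = 2020
    trained_share_min: float = Field(default=0.95, ge=0.0, le=1.0)
    trim_share_min: float = Field(default=0.50, ge=0.0, le=1.0)
    min_distinct_diagnoses: int = Field(default=5, ge=1)
    require_lesion_free: bool = True
    #: Observer ids that passed the kappa gate / training; ``None`` trusts all.
    trained_observers: Optional[frozenset[str]] = None
    days_basis: Optional[int] = None


@dataclass
class RejectionLedger:
    """Machine-readable account of every rejection.

    ``records``: one row per (rejected record, failed rule).
    ``herds``: one row per (excluded herd, failed rule) with the measured
    value vs threshold; ``first_failing`` marks the rule reported first
    (fixed cascade order for determinism).
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["record_index", "rule"]))
    herds: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["herd_id", "rule", "measured", "threshold", "first_failing"]))
    n_input_records: int = 0
    n_accepted_records: int = 0

    @property
    def n_rejected_records(self) -> int:
        return self.n_input_records - self.n_accepted_records

    def excluded_herds(self) -> set:
        return set(self.herds["herd_id"])

    def summary(self) -> dict:
        return {
            "records_in": self.n_input_records,
            "records_accepted": self.n_accepted_records,
            "records_rejected": self.n_rejected_records,
            "record_rule_counts": self.records["rule"].value_counts().to_dict(),
            "herds_excluded": int(self.herds["herd_id"].nunique()),
            "herd_rule_counts": self.herds.loc[self.herds["first_failing"], "rule"]
                                 .value_counts().to_dict(),
        }


def _presence_mask(records: pd.DataFrame, rosters: pd.DataFrame) -> pd.Series:
    """True where the record's cow is rostered in the record's herd at the
    record date (presence interval [entry, exit))."""
    if rosters.empty:
        return pd.Series(False, index=records.index)
    ros = rosters[["herd_id", "cow_id", "entry_date", "exit_date"]].copy()
    ros["entry_date"] = pd.to_datetime(ros["entry_date"])
    ros["exit_date"] = pd.to_datetime(ros["exit_date"])
    left = records[["herd_id", "cow_id"]].copy()
    left["date"] = pd.to_datetime(records["date"])
    left = left.reset_index(names="_record_index")
    merged = left.merge(ros, on=["herd_id", "cow_id"], how="left", sort=False)
    ok = merged["entry_date"].notna() & (merged["date"] >= merged["entry_date"]) & (
        merged["exit_date"].isna() | (merged["date"] < merged["exit_date"]))
    # a cow may have several roster intervals; any covering interval accepts
    return (ok.groupby(merged["_record_index"]).any()
            .reindex(records.index, fill_value=False))


def validate_records(records: pd.DataFrame, rosters: pd.DataFrame,
                     config: ValidationConfig) -> tuple[pd.DataFrame, RejectionLedger]:
    """Record-level cascade: drops records of unrostered cow-dates, records
    outside the study year and unresolvable lesion codes.

    All rules are evaluated independently (order-independent); accepted
    records are returned unmodified.  Empty input yields empty output and an
    empty ledger.
    """
    ledger = RejectionLedger(n_input_records=len(records))
    if records.empty:
        return records.copy(), ledger
    start, end, _ = year_bounds(config.year)
    dates = pd.to_datetime(records["date"])

    fails = {
        "animal-id": ~_presence_mask(records, rosters),
        "date-window": ~((dates >= start) & (dates < end)),
        "lesion-code": ~records["lesion_code"].isin(known_codes()),
    }
    rows = []
    for rule in RECORD_RULES:  # fixed reporting order
        for idx in records.index[fails[rule]]:
            rows.append({"record_index": idx, "rule": rule})
    if rows:
        ledger.records = pd.DataFrame(rows, columns=["record_index", "rule"])
    rejected = np.zeros(len(records), dtype=bool)
    for mask in fails.values():
        rejected |= mask.to_numpy()
    clean = records.loc[~rejected].copy()
    ledger.n_accepted_records = len(clean)
    return clean, ledger


def _herd_measures(clean: pd.DataFrame, rosters: pd.DataFrame,
                   config: ValidationConfig) -> pd.DataFrame:
    herds = pd.Index(sorted(clean["herd_id"].unique()), name="herd_id")
    mcn = mean_cow_number(rosters, config.year, days_basis=config.days_basis)
    ann = annotate_records(clean, strict=True)

    if config.trained_observers is None:
        trained_share = pd.Series(1.0, index=herds)
    else:
        trained = clean["observer_id"].isin(config.trained_observers)
        trained_share = trained.groupby(clean["herd_id"]).mean().reindex(herds)

    trimmed_cows = clean.groupby("herd_id")["cow_id"].nunique().reindex(herds, fill_value=0)
    trim_share = trimmed_cows / mcn.reindex(herds)

    distinct = (ann[ann["group"].notna()]
                .groupby("herd_id")["group"].nunique().reindex(herds, fill_value=0))
    lesion_free = (clean["lesion_code"] == NO_LESION_CODE).groupby(
        clean["herd_id"]).any().reindex(herds, fill_value=False)

    return pd.DataFrame({
        "has_roster": mcn.reindex(herds).notna() & (mcn.reindex(herds) > 0),
        "trained_share": trained_share,
        "trim_share": trim_share,
        "distinct_diagnoses": distinct,
        "lesion_free_documented": lesion_free,
    }, index=herds)


def filter_herds(clean: pd.DataFrame, rosters: pd.DataFrame,
                 config: ValidationConfig) -> tuple[set, RejectionLedger]:
    """Herd-level inclusion: returns (included herd ids, ledger).

    A herd is included iff it passes every rule; the ledger stores each
    failing rule with the measured value and threshold, the first-failing
    rule flagged per the fixed cascade order.
    """
    ledger = RejectionLedger(n_input_records=len(clean),
                             n_accepted_records=len(clean))
    if clean.empty:
        return set(), ledger
    measures = _herd_measures(clean, rosters, config)

    checks = {
        "no-roster": (measures["has_roster"], 1.0,
                      measures["has_roster"].astype(float)),
        "trained-share": (measures["trained_share"] >= config.trained_share_min,
                          config.trained_share_min, measures["trained_share"]),
        "trim-share": (measures["trim_share"] >= config.trim_share_min,
                       config.trim_share_min, measures["trim_share"]),
        "lesion-free": (measures["lesion_free_documented"] | (not config.require_lesion_free),
                        1.0, measures["lesion_free_documented"].astype(float)),
        "min-diagnoses": (measures["distinct_diagnoses"] >= config.min_distinct_diagnoses,
                          float(config.min_distinct_diagnoses),
                          measures["distinct_diagnoses"].astype(float)),
    }
    rows = []
    included = set()
    for herd in measures.index:
        first = True
        ok = True
        for rule in HERD_RULES:
            passed, threshold, measured = checks[rule]
            if not bool(passed.loc[herd]):
                ok = False
                rows.append({"herd_id": herd, "rule": rule,
                             "measured": float(measured.loc[herd])
                             if pd.notna(measured.loc[herd]) else np.nan,
                             "threshold": threshold, "first_failing": first})
                first = False
        if ok:
            included.add(herd)
    if rows:
        ledger.herds = pd.DataFrame(
            rows, columns=["herd_id", "rule", "measured", "threshold", "first_failing"])
    return included, ledger


def validate(records: pd.DataFrame, rosters: pd.DataFrame,
             config: ValidationConfig) -> tuple[pd.DataFrame, set, RejectionLedger]:
    """Full cascade: record rules, then herd rules on the surviving records.

    Returns (clean records restricted to included herds, included herd set,
    combined ledger).
    """
    clean, rec_ledger = validate_records(records, rosters, config)
    included, herd_ledger = filter_herds(clean, rosters, config)
    ledger = RejectionLedger(
        records=rec_ledger.records, herds=herd_ledger.herds,
        n_input_records=rec_ledger.n_input_records,
        n_accepted_records=rec_ledger.n_accepted_records)
    final = clean[clean["herd_id"].isin(included)].copy()
    return final, included, ledger
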