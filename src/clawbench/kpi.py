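"""Per-herd-year key performance indicators for claw health.

Three KPI families, all expressed in percent at herd level:

* ``IR_Lame`` — lameness incidence risk: for each scoring date, the share of
  scored cows (in a cow group: all lactating, dry, or first 100 days in milk)
  with a locomotion score at or above a threshold (>=2, >=3, >=4); the herd
  value is the mean over the year's scoring dates.  Every lame cow at a
  scoring counts as a new case, since scorings are weeks apart.

* ``IR_ClawL`` — claw-lesion incidence risk per lesion group: new cases of
  the group within the year divided by the mean cow number of the herd
  (total cow-days present / days in year).  In the default ``cow-year``
  counting mode a cow counts once per year per group ("percentage of cattle
  with at least one documented lesion"); in ``cow-visit`` mode each distinct
  cow x visit-date occurrence counts as a new case.  ``IR_alarm`` applies the
  same formula to the union of always-painful 'alarm' lesions.  The DD
  incidence is only meaningful in herds with endemic digital dermatitis
  (more than two affected animals recorded in the year).

* ``ACR_Claw`` — annual culling risk due to claw & limb disorders: culls
  coded claw/limb divided by all culls of the herd-year.  Herds with no
  culls at all report 0.0 (they enter the benchmark distribution at zero).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain import (
    BENCHMARK_GROUPS,
    CLAW_CULL_REASON,
    DD_LESION_STAGES,
    DEFAULT_FARMER_SEVERITY,
    annotate_records,
)

LAMENESS_THRESHOLDS = (2, 3, 4)
COW_GROUPS = ("all_lactating", "dry", "first_100_dim")
COUNTING_MODES = ("cow-year", "cow-visit")
DD_ENDEMIC_MIN_AFFECTED = 3  # "more than two animals" read strictly


def year_bounds(year: int) -> tuple[pd.Timestamp, pd.Timestamp, int]:
    """(start, exclusive end, number of days) of a closed calendar study year."""
    start = pd.Timestamp(year, 1, 1)
    end = pd.Timestamp(year + 1, 1, 1)
    return start, end, (end - start).days


def mean_cow_number(rosters: pd.DataFrame, year: int,
                    days_basis: Optional[int] = None) -> pd.Series:
    """Mean number of cows present per herd within the year.

    Presence is the half-open [entry, exit) interval clipped to the year;
    the value is total cow-days / ``days_basis`` (defaults to the calendar
    length of the year, 365 or 366).
    """
    start, end, ndays = year_bounds(year)
    basis = ndays if days_basis is None else days_basis
    if rosters.empty:
        return pd.Series(dtype=float, name="mean_cow_number")
    entry = pd.to_datetime(rosters["entry_date"])
    exit_ = pd.to_datetime(rosters["exit_date"]).fillna(end)
    lo = entry.clip(lower=start)
    hi = exit_.clip(upper=end)
    days = (hi - lo).dt.days.clip(lower=0)
    out = days.groupby(rosters["herd_id"]).sum() / basis
    return out.rename("mean_cow_number")


def _explode_events(rosters: pd.DataFrame, column: str) -> pd.DataFrame:
    sub = rosters.loc[rosters[column].fillna("") != "", ["herd_id", "cow_id", column]]
    if sub.empty:
        return pd.DataFrame(columns=["herd_id", "cow_id", "event_date"])
    ev = sub.assign(event_date=sub[column].str.split("|")).explode("event_date")
    ev["event_date"] = pd.to_datetime(ev["event_date"]).astype("datetime64[ns]")
    return ev[["herd_id", "cow_id", "event_date"]]


def annotate_cow_status(records: pd.DataFrame, rosters: pd.DataFrame) -> pd.DataFrame:
    """Attach lactation status at each record's date.

    Adds ``last_calving``, ``dim`` (days in milk), ``is_dry`` (the most
    recent lactation event is a dry-off) and ``has_calved`` to any frame with
    ``herd_id``, ``cow_id`` and ``date`` columns.
    """
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).astype("datetime64[ns]")
    base = out[["herd_id", "cow_id", "date"]].reset_index(drop=True)
    pos = np.argsort(base["date"].to_numpy(), kind="stable")
    inv = np.empty_like(pos)
    inv[pos] = np.arange(len(pos))
    sorted_records = base.iloc[pos]
    for label, column in (("last_calving", "calving_dates"),
                          ("last_dryoff", "dryoff_dates")):
        events = _explode_events(rosters, column).sort_values("event_date")
        if events.empty:
            out[label] = pd.NaT
            continue
        merged = pd.merge_asof(
            sorted_records, events,
            left_on="date", right_on="event_date",
            by=["herd_id", "cow_id"], direction="backward")
        out[label] = pd.Series(merged["event_date"].to_numpy()[inv],
                               index=out.index)
    out["has_calved"] = out["last_calving"].notna()
    out["dim"] = (out["date"] - out["last_calving"]).dt.days
    out["is_dry"] = out["last_dryoff"].notna() & (
        out["last_calving"].isna() | (out["last_dryoff"] > out["last_calving"]))
    return out


def _group_mask(status: pd.DataFrame, group: str) -> pd.Series:
    if group == "all_lactating":
        return status["has_calved"] & ~status["is_dry"]
    if group == "dry":
        return status["is_dry"]
    if group == "first_100_dim":
        return (status["has_calved"] & ~status["is_dry"]
                & status["dim"].between(0, 100))
    raise ValueError(f"unknown cow group {group!r}; expected one of {COW_GROUPS}")


def ir_lame(locomotion: pd.DataFrame, rosters: pd.DataFrame,
            threshold: int = 2, group: str = "all_lactating",
            year: Optional[int] = None) -> pd.Series:
    """Lameness incidence risk (%) per herd at one score threshold.

    For each herd scoring date, the lame share among scored cows of the
    group; dates with no scored group member are skipped; herds whose group
    is never scored get NaN.
    """
    if threshold not in LAMENESS_THRESHOLDS:
        raise ValueError(f"threshold must be one of {LAMENESS_THRESHOLDS}")
    loco = locomotion.reset_index(drop=True).copy()
    loco["date"] = pd.to_datetime(loco["date"])
    if year is not None:
        start, end, _ = year_bounds(year)
        loco = loco[(loco["date"] >= start) & (loco["date"] < end)]
    herds = pd.Index(sorted(locomotion["herd_id"].unique()), name="herd_id")
    if loco.empty:
        return pd.Series(np.nan, index=herds, name=f"ir_lame_ge{threshold}_{group}")
    status = annotate_cow_status(loco, rosters)
    member = _group_mask(status, group)
    sub = loco[member]
    if sub.empty:
        return pd.Series(np.nan, index=herds, name=f"ir_lame_ge{threshold}_{group}")
    lame = (sub["score"] >= threshold)
    per_date = sub.assign(lame=lame).groupby(["herd_id", "date"]).agg(
        n=("lame", "size"), n_lame=("lame", "sum"))
    share = 100.0 * per_date["n_lame"] / per_date["n"]
    out = share.groupby(level="herd_id").mean()
    return out.reindex(herds).rename(f"ir_lame_ge{threshold}_{group}")


def recode_severity(records: pd.DataFrame,
                    farmer_default_severity: int = DEFAULT_FARMER_SEVERITY) -> pd.DataFrame:
    """Harmonise trimmer and farmer-app records for KPI computation.

    Drops severity-1 (mild) trimmer records of the severity-sensitive groups
    (sole haemorrhage, double sole, white line disease, heel horn erosion);
    the surviving white-line records are white line abscesses (the WLA
    group).  Farmer-app records carry no severity and pass through under the
    configured severity convention (default: moderate).  Adds the ``group``
    and ``alarm`` annotation columns.
    """
    ann = annotate_records(records, farmer_default_severity=farmer_default_severity)
    if "severity" in ann.columns:
        sev = pd.to_numeric(ann["severity"], errors="coerce")
        drop = (ann["severity_sensitive"] & (ann["recorder"] == "trimmer")
                & (sev == 1))
        ann = ann[~drop]
    return ann.copy()


def _year_lesions(analysis: pd.DataFrame, year: Optional[int]) -> pd.DataFrame:
    sub = analysis[analysis["is_lesion"]].copy()
    sub["date"] = pd.to_datetime(sub["date"])
    if year is not None:
        start, end, _ = year_bounds(year)
        sub = sub[(sub["date"] >= start) & (sub["date"] < end)]
    return sub


def _ir_from_cases(cases: pd.DataFrame, mcn: pd.Series, mode: str, name: str) -> pd.Series:
    if mode not in COUNTING_MODES:
        raise ValueError(f"counting mode must be one of {COUNTING_MODES}")
    if mode == "cow-year":
        num = cases.groupby("herd_id")["cow_id"].nunique()
    else:  # cow-visit: every distinct cow x visit date is a new case
        num = (cases.drop_duplicates(["herd_id", "cow_id", "date"])
               .groupby("herd_id").size())
    num = num.reindex(mcn.index, fill_value=0).astype(float)
    out = 100.0 * num / mcn
    out[mcn <= 0] = np.nan  # undefined denominator, flagged as NaN
    return out.rename(name)


def ir_clawl(analysis: pd.DataFrame, rosters: pd.DataFrame, group: str,
             year: Optional[int] = None, mode: str = "cow-year",
             days_basis: Optional[int] = None) -> pd.Series:
    """Incidence risk (%) of one lesion group per herd.

    ``analysis`` must be severity-recoded (see :func:`recode_severity`).
    Numerator per the counting mode; denominator is the mean cow number.
    """
    if group not in BENCHMARK_GROUPS and group != "other":
        raise ValueError(f"unknown lesion group {group!r}")
    mcn = mean_cow_number(rosters, year if year is not None else _infer_year(analysis),
                          days_basis=days_basis)
    cases = _year_lesions(analysis, year)
    cases = cases[cases["group"] == group]
    return _ir_from_cases(cases, mcn, mode, f"ir_{group.lower()}")


def ir_alarm(analysis: pd.DataFrame, rosters: pd.DataFrame,
             year: Optional[int] = None, mode: str = "cow-year",
             days_basis: Optional[int] = None) -> pd.Series:
    """Incidence risk (%) of painful 'alarm' lesions per herd."""
    mcn = mean_cow_number(rosters, year if year is not None else _infer_year(analysis),
                          days_basis=days_basis)
    cases = _year_lesions(analysis, year)
    cases = cases[cases["alarm"]]
    return _ir_from_cases(cases, mcn, mode, "ir_alarm")


def _infer_year(records: pd.DataFrame) -> int:
    if records.empty:
        raise ValueError("cannot infer study year from an empty record stream")
    return int(pd.to_datetime(records["date"]).dt.year.mode().iloc[0])


def dd_endemic(records: pd.DataFrame,
               min_affected: int = DD_ENDEMIC_MIN_AFFECTED,
               year: Optional[int] = None,
               herds: Optional[Sequence] = None) -> pd.Series:
    """Endemic digital-dermatitis flag per herd.

    True iff at least ``min_affected`` (default 3: strictly more than two)
    distinct cows have any M1..M4.1 record within the year.  Only endemic
    herds contribute to DD benchmarking.
    """
    sub = records.copy()
    sub["date"] = pd.to_datetime(sub["date"])
    if year is not None:
        start, end, _ = year_bounds(year)
        sub = sub[(sub["date"] >= start) & (sub["date"] < end)]
    sub = sub[sub["lesion_code"].isin(DD_LESION_STAGES)]
    counts = sub.groupby("herd_id")["cow_id"].nunique()
    if herds is None:
        herds = sorted(records["herd_id"].unique())
    index = pd.Index(herds, name="herd_id")
    return counts.reindex(index, fill_value=0).ge(min_affected).rename("dd_endemic")


def acr_claw(culling: pd.DataFrame, year: Optional[int] = None,
             herds: Optional[Sequence] = None) -> pd.Series:
    """Annual culling risk (%) due to claw & limb disorders per herd:
    claw/limb-reason culls over all culls.  Zero-cull herds report 0.0."""
    sub = culling.copy()
    if not sub.empty:
        sub["date"] = pd.to_datetime(sub["date"])
        if year is not None:
            start, end, _ = year_bounds(year)
            sub = sub[(sub["date"] >= start) & (sub["date"] < end)]
    if herds is None:
        herds = sorted(culling["herd_id"].unique())
    index = pd.Index(herds, name="herd_id")
    total = sub.groupby("herd_id").size().reindex(index, fill_value=0)
    claw = (sub[sub["reason"] == CLAW_CULL_REASON]
            .groupby("herd_id").size().reindex(index, fill_value=0))
    out = 100.0 * claw / total.where(total > 0, 1)
    return out.astype(float).rename("acr_claw")


def compute_herd_kpis(trimming: pd.DataFrame, locomotion: pd.DataFrame,
                      rosters: pd.DataFrame, culling: pd.DataFrame,
                      year: int, mode: str = "cow-year",
                      farmer_default_severity: int = DEFAULT_FARMER_SEVERITY,
                      dd_min_affected: int = DD_ENDEMIC_MIN_AFFECTED,
                      days_basis: Optional[int] = None) -> pd.DataFrame:
    """The full per-herd KPI set: one row per roster herd.

    Columns: mean cow number; 13 lesion-group incidence risks (``ir_dd`` is
    NaN for non-endemic herds); alarm incidence; the endemic flag; ACR_Claw
    with cull counts; and IR_Lame at thresholds >=2/3/4 for the three cow
    groups (NaN where a herd has no locomotion data for the group).
    """
    herds = pd.Index(sorted(rosters["herd_id"].unique()), name="herd_id")
    mcn = mean_cow_number(rosters, year, days_basis=days_basis).reindex(herds)
    out = pd.DataFrame({"mean_cow_number": mcn}, index=herds)

    analysis = recode_severity(trimming, farmer_default_severity)
    for group in BENCHMARK_GROUPS:
        out[f"ir_{group.lower()}"] = ir_clawl(
            analysis, rosters, group, year=year, mode=mode,
            days_basis=days_basis).reindex(herds)
    out["ir_alarm"] = ir_alarm(analysis, rosters, year=year, mode=mode,
                               days_basis=days_basis).reindex(herds)
    out["dd_endemic"] = dd_endemic(trimming, min_affected=dd_min_affected,
                                   year=year, herds=herds)
    out.loc[~out["dd_endemic"], "ir_dd"] = np.nan  # not applicable: herd DD-free

    for threshold in LAMENESS_THRESHOLDS:
        for group, tag in (("all_lactating", "all"), ("dry", "dry"),
                           ("first_100_dim", "dim100")):
            col = f"ir_lame_ge{threshold}_{tag}"
            if locomotion.empty:
                out[col] = np.nan
            else:
                out[col] = ir_lame(locomotion, rosters, threshold, group,
                                   year=year).reindex(herds)

    out["acr_claw"] = acr_claw(culling, year=year, herds=herds)
    if culling.empty:
        out["n_culls"] = 0
        out["n_claw_culls"] = 0
    else:
        cull = culling.copy()
        cull["date"] = pd.to_datetime(cull["date"])
        start, end, _ = year_bounds(year)
        cull = cull[(cull["date"] >= start) & (cull["date"] < end)]
        out["n_culls"] = cull.groupby("herd_id").size().reindex(herds, fill_value=0)
        out["n_claw_culls"] = (cull[cull["reason"] == CLAW_CULL_REASON]
                               .groupby("herd_id").size().reindex(herds, fill_value=0))
    out.index.name = "herd_id"
    return out
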