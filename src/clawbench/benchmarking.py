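"""Percentile benchmark tables, farm band classification and the MY FARM report.

Each KPI's distribution over the included herds is summarised by min, mean,
SD and the 10th/25th/50th/75th/90th percentiles (linear interpolation between
order statistics — the "type-7" convention; the estimator is fixed and all
band properties are stated relative to it).  Lower is better for every KPI in
scope, so the six contiguous bands run from best (<= P10) to worst (> P90);
boundary values fall into the better band, matching the inclusive
"good <= 10th percentile" reading.  The traditional three labels are attached
secondarily: good (<= P10), moderate (>= P25 and < P50), poor (>= P50) — the
(P10, P25) interval deliberately carries no label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

PERCENTILES = (10, 25, 50, 75, 90)
BAND_NAMES = ("<=P10", "(P10,P25]", "(P25,P50]", "(P50,P75]", "(P75,P90]", ">P90")
NOT_EVALUABLE = "not evaluable"

#: KPI column -> human-readable report row, in report order.
DEFAULT_KPI_LABELS: dict[str, str] = {
    "ir_alarm": "'Alarm' lesions",
    "ir_ts": "Thin sole",
    "ir_hf": "Horn fissure",
    "ir_ds": "Double sole",
    "ir_cc": "Corkscrew claw",
    "ir_sh": "Sole haemorrhage",
    "ir_wla": "White line abscess",
    "ir_ul": "Ulcers (sole, toe, bulb, toe necrosis)",
    "ir_cd": "Concave dorsal wall",
    "ir_ip": "Interdigital phlegmon",
    "ir_dd": "Digital dermatitis (endemic herds)",
    "ir_sw": "Swelling of coronet/bulb",
    "ir_ih": "Interdigital hyperplasia",
    "ir_hhe": "Heel horn erosion",
    "ir_lame_ge2_all": "Lameness LSC>=2, lactating cows",
    "ir_lame_ge3_all": "Lameness LSC>=3, lactating cows",
    "ir_lame_ge4_all": "Lameness LSC>=4, lactating cows",
    "ir_lame_ge2_dry": "Lameness LSC>=2, dry cows",
    "ir_lame_ge3_dry": "Lameness LSC>=3, dry cows",
    "ir_lame_ge4_dry": "Lameness LSC>=4, dry cows",
    "ir_lame_ge2_dim100": "Lameness LSC>=2, first 100 DIM",
    "ir_lame_ge3_dim100": "Lameness LSC>=3, first 100 DIM",
    "ir_lame_ge4_dim100": "Lameness LSC>=4, first 100 DIM",
    "acr_claw": "Annual culling risk, claw & limb",
}


@dataclass(frozen=True)
class BenchmarkTable:
    """Percentile grid of one KPI over the included herds."""

    kpi: str
    n_herds: int
    min: float
    mean: float
    sd: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    max: float
    note: str = ""
    empty: bool = False

    def percentile(self, q: int) -> float:
        return getattr(self, f"p{q}")

    def as_row(self) -> dict:
        return {"kpi": self.kpi, "n_herds": self.n_herds, "min": self.min,
                "mean": self.mean, "sd": self.sd, "p10": self.p10,
                "p25": self.p25, "median": self.p50, "p75": self.p75,
                "p90": self.p90, "max": self.max, "note": self.note,
                "empty": self.empty}


@dataclass(frozen=True)
class FarmBand:
    """One farm's position relative to a benchmark table."""

    kpi: str
    value: float
    band: str          # one of BAND_NAMES or "not evaluable"
    band_index: int    # 1 (best) .. 6 (worst); 0 when not evaluable
    label: Optional[str]  # good / moderate / poor / None


def build_benchmark(values: pd.Series, kpi: str, note: str = "") -> BenchmarkTable:
    """Percentile grid of one KPI; NaNs (not-applicable herds) are excluded.

    With fewer than two defined values the row is flagged empty.
    """
    vals = pd.Series(values).astype(float).dropna().to_numpy()
    if len(vals) < 2:
        return BenchmarkTable(kpi, len(vals), *([float("nan")] * 9),
                              note=note or "insufficient data", empty=True)
    pcts = np.percentile(vals, PERCENTILES, method="linear")
    return BenchmarkTable(
        kpi=kpi, n_herds=len(vals),
        min=float(vals.min()), mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        p10=float(pcts[0]), p25=float(pcts[1]), p50=float(pcts[2]),
        p75=float(pcts[3]), p90=float(pcts[4]),
        max=float(vals.max()), note=note)


def build_benchmark_tables(kpis: pd.DataFrame,
                           kpi_columns: Optional[Sequence[str]] = None
                           ) -> dict[str, BenchmarkTable]:
    """Benchmark every KPI column of a per-herd KPI frame.

    The DD row is restricted to endemic herds via its NaN convention
    (non-endemic herds carry NaN in ``ir_dd``); the restriction is noted.
    """
    if kpi_columns is None:
        kpi_columns = [c for c in DEFAULT_KPI_LABELS if c in kpis.columns]
    tables = {}
    for col in kpi_columns:
        note = "endemic herds only" if col == "ir_dd" else ""
        tables[col] = build_benchmark(kpis[col], col, note=note)
    return tables


def tables_to_frame(tables: Mapping[str, BenchmarkTable]) -> pd.DataFrame:
    """Flat frame of benchmark rows, mirroring the published column order
    (Mean, 10th, 25th, Median, 75th, 90th)."""
    frame = pd.DataFrame([t.as_row() for t in tables.values()])
    return frame[["kpi", "n_herds", "min", "mean", "sd", "p10", "p25",
                  "median", "p75", "p90", "max", "note", "empty"]]


def classify_farm(value: float, table: BenchmarkTable) -> FarmBand:
    """Deterministic band assignment; boundary values go to the better
    (lower) band.  Undefined values (NaN, or an empty table) are not
    evaluable."""
    if table.empty or value is None or (isinstance(value, float) and np.isnan(value)):
        return FarmBand(table.kpi, float("nan"), NOT_EVALUABLE, 0, None)
    value = float(value)
    cuts = (table.p10, table.p25, table.p50, table.p75, table.p90)
    index = 1 + sum(value > c for c in cuts)
    if value <= table.p10:
        label = "good"
    elif table.p25 <= value < table.p50:
        label = "moderate"
    elif value >= table.p50:
        label = "poor"
    else:
        label = None  # the unlabeled (P10, P25) interval
    return FarmBand(table.kpi, value, BAND_NAMES[index - 1], index, label)


def my_farm_report(herd_id: str, kpis: pd.DataFrame,
                   tables: Mapping[str, BenchmarkTable]) -> pd.DataFrame:
    """The benchmark table with an additional MY FARM comparison column.

    One row per KPI: population min/mean/percentiles plus the farm's own
    value, its band and its label.  The farm must appear in the KPI frame
    (it need not be part of the benchmark population).  The DD row of a
    DD-free farm reads "not applicable (herd DD-free)".
    """
    if herd_id not in kpis.index:
        raise KeyError(f"herd {herd_id!r} not present in the KPI table")
    farm = kpis.loc[herd_id]
    rows = []
    for col, table in tables.items():
        value = float(farm[col]) if col in farm.index else float("nan")
        band = classify_farm(value, table)
        note = table.note
        if col == "ir_dd" and "dd_endemic" in farm.index and not bool(farm["dd_endemic"]):
            note = "not applicable (herd DD-free)"
        rows.append({
            "kpi": col,
            "label": DEFAULT_KPI_LABELS.get(col, col),
            "n_herds": table.n_herds,
            "min": table.min, "mean": table.mean,
            "p10": table.p10, "p25": table.p25, "median": table.p50,
            "p75": table.p75, "p90": table.p90,
            "my_farm": band.value,
            "band": band.band if note != "not applicable (herd DD-free)"
                    else NOT_EVALUABLE,
            "class": band.label,
            "note": note,
        })
    return pd.DataFrame(rows)


def render_report_markdown(report: pd.DataFrame, herd_id: str) -> str:
    """Human-readable MY FARM report; values rounded to one decimal at
    rendering only."""
    lines = [f"# Claw-health benchmark report — MY FARM: {herd_id}", ""]
    header = ("| KPI | n | Mean | 10th | 25th | Median | 75th | 90th "
              "| MY FARM | Band | Class |")
    lines.append(header)
    lines.append("|" + "---|" * 11)

    def fmt(x: object) -> str:
        if isinstance(x, float):
            return "—" if np.isnan(x) else f"{x:.1f}"
        return str(x)

    for _, row in report.iterrows():
        lines.append("| " + " | ".join([
            row["label"], str(row["n_herds"]), fmt(row["mean"]), fmt(row["p10"]),
            fmt(row["p25"]), fmt(row["median"]), fmt(row["p75"]), fmt(row["p90"]),
            fmt(row["my_farm"]), str(row["band"]),
            str(row["class"]) if row["class"] else "—",
        ]) + " |")
    lines.append("")
    lines.append("Bands: <=P10 best in class; boundary values fall to the "
                 "better band. Labels: good <=P10, moderate >=P25 and <P50, "
                 "poor >=P50.")
    return "\n".join(lines) + "\n"
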