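#!/usr/bin/env python
"""Compute the per-herd KPI table for the included herds.

Lameness incidence risks (LSC >= 2/3/4 for lactating, dry and first-100-DIM
cows), the 13 lesion-group incidence risks, the alarm-lesion incidence, the
endemic-DD flag and the annual claw/limb culling risk.  Writes
results/herd_kpis.csv.
"""

from clawbench.io import read_stream, write_frame
from clawbench.kpi import compute_herd_kpis

YEAR = 2020
RAW, OUT = "results/raw", "results"


def main() -> None:
    clean, _ = read_stream(f"{OUT}/clean_records.csv", "trimming")
    rosters, _ = read_stream(f"{RAW}/rosters.csv", "roster")
    locomotion, _ = read_stream(f"{RAW}/locomotion.csv", "locomotion")
    culling, _ = read_stream(f"{RAW}/culling.csv", "culling")
    with open(f"{OUT}/included_herds.txt") as fh:
        included = {line.strip() for line in fh if line.strip()}

    rosters = rosters[rosters["herd_id"].isin(included)]
    locomotion = locomotion[locomotion["herd_id"].isin(included)]
    culling = culling[culling["herd_id"].isin(included)]

    kpis = compute_herd_kpis(clean, locomotion, rosters, culling, year=YEAR)
    write_frame(kpis.reset_index(), f"{OUT}/herd_kpis.csv")
    print(f"KPIs for {len(kpis)} herds "
          f"({int(kpis['dd_endemic'].sum())} endemic-DD)")
    for col in ("ir_alarm", "ir_ul", "ir_dd", "acr_claw", "ir_lame_ge2_all"):
        series = kpis[col].dropna()
        print(f"  {col}: mean {series.mean():.1f}%  median {series.median():.1f}%")


if __name__ == "__main__":
    main()
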