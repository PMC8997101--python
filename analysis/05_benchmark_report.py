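#!/usr/bin/env python
"""Build the percentile benchmark tables and a MY FARM report.

Each KPI is summarised over the included herds by min, mean, SD and the
10th/25th/50th/75th/90th percentiles; a sample farm is classified into the
six percentile bands with the good/moderate/poor labels attached.  Writes
results/benchmark.csv and results/my_farm_report.{csv,md}.
"""

import pandas as pd

from clawbench.benchmarking import (build_benchmark_tables, my_farm_report,
                                    render_report_markdown, tables_to_frame)
from clawbench.io import write_frame

OUT = "results"


def main() -> None:
    kpis = pd.read_csv(f"{OUT}/herd_kpis.csv").set_index("herd_id")
    tables = build_benchmark_tables(kpis)
    write_frame(tables_to_frame(tables), f"{OUT}/benchmark.csv")

    alarm = tables["ir_alarm"]
    print(f"benchmark over {alarm.n_herds} herds — 'alarm' lesions: "
          f"mean {alarm.mean:.1f}%, P10 {alarm.p10:.1f}%, median {alarm.p50:.1f}%, "
          f"P90 {alarm.p90:.1f}%")
    dd = tables["ir_dd"]
    print(f"digital dermatitis ({dd.note}): n={dd.n_herds}, "
          f"P10 {dd.p10:.1f}%, median {dd.p50:.1f}%, P90 {dd.p90:.1f}%")

    farm = kpis.index[0]
    report = my_farm_report(farm, kpis, tables)
    write_frame(report, f"{OUT}/my_farm_report.csv")
    markdown = render_report_markdown(report, farm)
    with open(f"{OUT}/my_farm_report.md", "w") as fh:
        fh.write(markdown)
    good = (report["band"] == "<=P10").sum()
    print(f"MY FARM column for {farm}: {good} of {len(report)} KPIs in the "
          f"best-in-class band (report: {OUT}/my_farm_report.md)")


if __name__ == "__main__":
    main()
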