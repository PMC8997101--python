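#!/usr/bin/env python
"""Run the validation cascade on the simulated streams.

Record-level plausibility rules, then herd inclusion (trained-recorder share
>= 95%, trimmed share >= 50%, >= 5 distinct diagnoses, lesion-free
documentation).  Writes the clean records, both rejection ledgers and the
included-herd list to results/.
"""

from clawbench.io import read_stream, write_frame, write_stream
from clawbench.validation import ValidationConfig, validate

YEAR = 2020
RAW, OUT = "results/raw", "results"


def main() -> None:
    records, _ = read_stream(f"{RAW}/trimming.csv", "trimming")
    rosters, _ = read_stream(f"{RAW}/rosters.csv", "roster")
    with open(f"{OUT}/trained_observers.txt") as fh:
        trained = frozenset(line.strip() for line in fh if line.strip())
    # farmer-app recorders are registry members by training
    trained = trained | set(records.loc[records["recorder"] == "farmer",
                                        "observer_id"])
    cfg = ValidationConfig(year=YEAR, trained_observers=frozenset(trained))
    clean, included, ledger = validate(records, rosters, cfg)

    write_stream(clean, f"{OUT}/clean_records.csv", "trimming")
    write_frame(ledger.records, f"{OUT}/ledger_records.csv")
    write_frame(ledger.herds, f"{OUT}/ledger_herds.csv")
    with open(f"{OUT}/included_herds.txt", "w") as fh:
        fh.write("\n".join(sorted(included)) + "\n")

    summary = ledger.summary()
    print(f"records: {summary['records_accepted']}/{summary['records_in']} accepted")
    print(f"herds included: {len(included)} "
          f"({summary['herds_excluded']} excluded)")
    for rule, count in sorted(summary["herd_rule_counts"].items()):
        print(f"  first-failing {rule}: {count}")


if __name__ == "__main__":
    main()
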