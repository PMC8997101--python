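#!/usr/bin/env python
"""Observer reliability exams and the kappa >= 0.61 gate.

Simulates the two interobserver tests feeding the trained-observer registry:
the trimmers' lesion-picture exam (50 items) and the locomotion scorers'
video exam (50 items, 5-point scale, scored both on the full scale and with
the (12)(3)(45) category merge).  Writes per-observer kappas and the passed
registry to results/.
"""

import os

from clawbench.io import write_frame
from clawbench.reliability import gate_observers, observer_kappas
from clawbench.simulate import adjacent_confusion, simulate_raters

SEED = 2020
N_TRIMMERS, N_SCORERS, N_ITEMS = 32, 24, 50
OUT = "results"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)

    exam = simulate_raters(N_TRIMMERS, N_ITEMS, adjacent_confusion(5, 0.25),
                           seed=SEED + 1)
    exam["observer_id"] = exam["observer_id"].str.replace("OBS", "T")
    trimmer_kappas = observer_kappas(exam, categories=[1, 2, 3, 4, 5])
    passed, failed = gate_observers(
        dict(zip(trimmer_kappas["observer_id"], trimmer_kappas["kappa"])))
    trimmer_kappas["passed"] = trimmer_kappas["observer_id"].isin(passed)
    write_frame(trimmer_kappas, f"{OUT}/trimmer_kappas.csv")
    with open(f"{OUT}/trained_observers.txt", "w") as fh:
        fh.write("\n".join(sorted(passed)) + "\n")
    print(f"trimmer exam: mean kappa {trimmer_kappas['kappa'].mean():.2f} "
          f"(min {trimmer_kappas['kappa'].min():.2f}, "
          f"max {trimmer_kappas['kappa'].max():.2f}); "
          f"{len(passed)}/{N_TRIMMERS} pass the >=0.61 gate")

    video = simulate_raters(N_SCORERS, N_ITEMS, adjacent_confusion(5, 0.30),
                            seed=SEED + 2,
                            reference_probs=(0.617, 0.242, 0.088, 0.043, 0.010))
    plain = observer_kappas(video, categories=[1, 2, 3, 4, 5])
    merged = observer_kappas(video, merge="12|3|45", categories=[1, 2, 3, 4, 5])
    scorers = plain.merge(merged[["observer_id", "kappa"]], on="observer_id",
                          suffixes=("_unmerged", "_merged"))
    write_frame(scorers, f"{OUT}/scorer_kappas.csv")
    print(f"scorer video exam: mean kappa {plain['kappa'].mean():.2f} unmerged "
          f"-> {merged['kappa'].mean():.2f} with the (12)(3)(45) merge")


if __name__ == "__main__":
    main()
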