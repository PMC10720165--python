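"""Quantify every cohort study through the full pipeline.

Regenerates the seeded cohort of 02_simulate_cohort.py and runs, per study:
pyruvate-derived sensitivity maps -> Roemer combination -> per-voxel
constant-phase correction -> windowed AUC and AUC-SNR maps -> pyruvate
SNR >= 200 mask -> AUC ratios -> inputless k_PL/k_PB on the mean myocardial
timecourses.  Reports the LV-myocardium summary per study.

Writes results/cohort_metrics.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hpcardiac.phantom import generate_paired_cohort
from hpcardiac.pipeline import quantify_study

ROOT = Path(__file__).resolve().parents[1]
SEED = 20230


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=SEED)
    args = parser.parse_args()

    pairs = generate_paired_cohort(5, seed=args.seed)
    rows = []
    for pair in pairs:
        for state, study in (("fasted", pair.fasted), ("fed", pair.fed)):
            q = quantify_study(study)
            row = {"subject": pair.subject_id, "state": state,
                   "glucose_mg_dl": round(pair.glucose_fasted if state ==
                                          "fasted" else pair.glucose_fed, 1)}
            row.update({k: round(v, 5) for k, v in q.metrics.items()})
            rows.append(row)
            print(f"{pair.subject_id} {state}: k_PL {q.metrics['k_pl']:.4f} "
                  f"k_PB {q.metrics['k_pb']:.4f} bic/pyr "
                  f"{q.metrics['bicarbonate_pyruvate']:.4f}")
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "cohort_metrics.csv", index=False)
    print("\nwrote results/cohort_metrics.csv")


if __name__ == "__main__":
    main()
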