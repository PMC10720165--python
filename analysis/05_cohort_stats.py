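"""Fed-vs-fasted statistics over the quantified cohort.

Reads results/cohort_metrics.csv (from 03_quantify_cohort.py) and runs, per
13C measure: a paired two-sided t-test between states, and the Pearson
correlation of the per-study LV-myocardium value with blood glucose.

Writes results/cohort_stats.csv.
"""

from pathlib import Path

import pandas as pd

from hpcardiac.regional import paired_ttest, pearson_corr

ROOT = Path(__file__).resolve().parents[1]
METRICS = ["pyruvate_snr", "lactate_snr", "bicarbonate_snr",
           "lactate_pyruvate", "bicarbonate_pyruvate", "bicarbonate_lactate",
           "k_pl", "k_pb"]


def main() -> None:
    df = pd.read_csv(ROOT / "results" / "cohort_metrics.csv")
    fasted = df[df.state == "fasted"].set_index("subject")
    fed = df[df.state == "fed"].set_index("subject")
    subjects = fasted.index

    rows = []
    for metric in METRICS:
        t, dof, p = paired_ttest(fasted.loc[subjects, metric],
                                 fed.loc[subjects, metric])
        r, rp = pearson_corr(df["glucose_mg_dl"], df[metric])
        rows.append({"metric": metric, "t": round(t, 3), "df": dof,
                     "p_paired": round(p, 4), "pearson_r_glucose": round(r, 3),
                     "p_corr": round(rp, 4)})
    stats = pd.DataFrame(rows)
    stats.to_csv(ROOT / "results" / "cohort_stats.csv", index=False)
    print(stats.to_string(index=False))
    best = stats.loc[stats.pearson_r_glucose.idxmax()]
    print(f"\nStrongest glucose correlation: {best.metric} "
          f"(r = {best.pearson_r_glucose}).")


if __name__ == "__main__":
    main()
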