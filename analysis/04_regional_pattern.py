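"""Regional 16-segment analysis on a phantom with an apical-lateral hotspot.

Renders a fed-state study whose apical-lateral segment (AHA segment 16) has
1.5x elevated conversion rates, fits voxelwise k_PL/k_PB maps inside the
pyruvate-SNR mask, and summarizes them per AHA segment.  The hotspot should
surface as the maximal segment-16 mean.

Writes results/segment_means.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hpcardiac.phantom import (AcquisitionProtocol, AIFModel,
                               TissueKineticsSpec, build_geometry,
                               make_coil_array, render_dynamic_study)
from hpcardiac.pipeline import quantify_study
from hpcardiac.regional import assign_aha16, segment_means

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    geo = build_geometry()
    kin = TissueKineticsSpec(segment_multipliers={16: 1.5}).fed()
    coils = make_coil_array(geo.shape, seed=args.seed)
    study = render_dynamic_study(geo, kin, AIFModel(), coils,
                                 AcquisitionProtocol(seed=args.seed))
    q = quantify_study(study, fit_voxel_maps=True)
    segs = assign_aha16(geo.myocardial_mask, geo.lv_centers,
                        geo.rv_insertion_deg, geo.slice_levels)

    table = pd.DataFrame({
        "k_pl": segment_means(q.metrics["k_pl_map"], segs),
        "k_pb": segment_means(q.metrics["k_pb_map"], segs),
        "bic_pyr": segment_means(q.ratios["bicarbonate_pyruvate"], segs),
    })
    (ROOT / "results").mkdir(exist_ok=True)
    table.round(5).to_csv(ROOT / "results" / "segment_means.csv")
    print(table.round(4).to_string())
    print(f"\nmax k_PB segment: {table['k_pb'].idxmax()} "
          "(16 = apical lateral, the simulated hotspot)")


if __name__ == "__main__":
    main()
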