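"""Effective in-plane resolution of the 22 ms spiral readout per metabolite.

The single-shot spiral acquires outer k-space late in the readout, so T2*
decay apodizes the high frequencies and broadens the PSF.  This driver
computes the radial PSF for each metabolite's myocardial T2* and tabulates
the relative FWHM and effective resolution.

Writes results/psf_resolution.csv.
"""

from pathlib import Path

import pandas as pd

from hpcardiac.psf import NOMINAL_RES_MM, T2STAR_MS, metabolite_psf_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for met, res in metabolite_psf_table().items():
        rows.append({
            "metabolite": met,
            "t2star_ms": T2STAR_MS[met],
            "nominal_res_mm": NOMINAL_RES_MM[met],
            "relative_fwhm": round(res.relative_fwhm, 4),
            "effective_res_mm": round(res.effective_resolution_mm, 2),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "psf_resolution.csv", index=False)
    print(df.to_string(index=False))
    print("\nLactate (shortest T2*) blurs the most; pyruvate keeps nearly "
          "its nominal 6 mm resolution.")


if __name__ == "__main__":
    main()
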