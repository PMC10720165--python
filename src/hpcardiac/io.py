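"""NIfTI / CSV / JSON persistence for studies, maps and cohort manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import METABOLITES, SubjectPair, SyntheticStudy


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_map(path, volume: np.ndarray, voxel_size_mm=(3.0, 3.0, 21.0)) -> None:
    """Save a (slices, ny, nx) map as NIfTI (x, y, z axis order)."""
    vol = np.moveaxis(np.asarray(volume), 0, -1)  # -> (ny, nx, slices)
    nib.save(nib.Nifti1Image(vol.astype(np.float32),
                             _affine(voxel_size_mm)), str(path))


def save_study(study: SyntheticStudy, out_dir) -> None:
    """Write a study as NIfTI volumes plus a JSON sidecar.

    One file per metabolite per channel with frames on the 4th dimension
    (real and imaginary parts as separate files to stay within the plain
    NIfTI float model), the label map, ground-truth rate maps, and a sidecar
    with the acquisition protocol and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = study.geometry.voxel_size_mm
    n_ch = study.coils.n_channels
    for m, met in enumerate(METABOLITES):
        for c in range(n_ch):
            series = study.data[m, :, :, :, :, c]  # (n_t, slices, ny, nx)
            vol = np.moveaxis(series, (0, 1), (-1, -2))  # (ny, nx, slices, t)
            for part, arr in (("real", vol.real), ("imag", vol.imag)):
                nib.save(
                    nib.Nifti1Image(arr.astype(np.float32), _affine(vox)),
                    str(out / f"{met}_ch{c:02d}_{part}.nii.gz"))
    save_map(out / "labels.nii.gz", study.geometry.label_map, vox)
    save_map(out / "k_pl_truth.nii.gz", study.k_pl_truth, vox)
    save_map(out / "k_pb_truth.nii.gz", study.k_pb_truth, vox)
    sidecar = {
        "protocol": asdict(study.protocol),
        "seed": study.seed,
        "aif": asdict(study.aif),
        "slice_levels": list(study.geometry.slice_levels),
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2))


def save_cohort_manifest(pairs: list[SubjectPair], out_dir, path) -> pd.DataFrame:
    """Cohort manifest CSV: one row per (subject, state) study."""
    rows = []
    for pair in pairs:
        for state in ("fasted", "fed"):
            rows.append({
                "subject": pair.subject_id,
                "state": state,
                "glucose_mg_dl": pair.glucose_fasted if state == "fasted"
                else pair.glucose_fed,
                "non_responder": pair.non_responder,
                "path": str(Path(out_dir) / f"{pair.subject_id}_{state}"),
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
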