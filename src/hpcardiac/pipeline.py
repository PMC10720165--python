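"""End-to-end study processing: combine, phase, quantify, fit, summarize.

Glue over the module stack so that analysis drivers, tests and the cohort
statistics all process a study identically:

    multi-channel complex dynamics
      -> pyruvate-derived sensitivity maps -> Roemer combination
      -> per-voxel constant-phase correction -> signed real dynamics
      -> AUC / AUC-SNR / pyruvate-SNR mask / AUC ratios
      -> inputless kinetic rates (ROI level and/or voxel maps)
      -> LV-myocardium summary metrics
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (MetaboliteTimecourses, RelaxationTimes, fit_inputless,
                       fit_rate_maps)
from .phantom import SyntheticStudy
from .quantify import (AUCWindow, auc_maps, auc_snr_map, estimate_noise,
                       pyruvate_mask, ratio_maps)
from .recon import SensitivityMaps, estimate_sensitivities, phase_correct, \
    roemer_combine


@dataclass
class StudyQuantification:
    """All derived maps and summary metrics for one dynamic study."""

    real_images: np.ndarray  # (3, n_frames, n_slices, ny, nx)
    sensitivity: SensitivityMaps
    phase_maps: np.ndarray  # (3, n_slices, ny, nx)
    auc: dict
    snr: dict
    noise_sigma: dict
    mask: np.ndarray
    ratios: dict
    metrics: dict  # LV-myocardium summary values


def combine_and_phase(study: SyntheticStudy, window: AUCWindow | None = None):
    """Roemer-combine the channels and phase the dynamics to real images.

    Sensitivities are estimated from the complex pyruvate AUC per channel
    (the highest-SNR data available in a 13C study).
    """
    window = window or AUCWindow()
    data = study.data  # (3, n_t, n_slices, ny, nx, n_ch)
    n_t = data.shape[1]
    sl = window.frame_slice("pyruvate", n_t)
    channel_auc = np.moveaxis(data[0, sl].sum(axis=0), -1, 0)
    sens = estimate_sensitivities(channel_auc)

    channels_first = np.moveaxis(data, -1, 0)  # (n_ch, 3, n_t, ...)
    combined = roemer_combine(channels_first, sens)
    phases = np.empty((3,) + combined.shape[2:])
    real = np.empty(combined.shape)
    for m in range(3):
        phases[m], real[m] = phase_correct(combined[m], axis=0)
    return real, sens, phases


def quantify_study(
    study: SyntheticStudy,
    snr_threshold: float = 200.0,
    window: AUCWindow | None = None,
    fit_voxel_maps: bool = False,
    relax: RelaxationTimes | None = None,
) -> StudyQuantification:
    """Run the full quantification chain on one synthetic study.

    LV-myocardium summary metrics (means over the myocardial mask restricted
    to the pyruvate-SNR mask) cover the per-study measures used in the
    fed/fasted comparison: metabolite AUC-SNRs, the three AUC ratios, and
    the inputless kinetic rates fitted to the mean myocardial timecourses.
    Set ``fit_voxel_maps`` for voxelwise k_PL/k_PB maps as well.
    """
    window = window or AUCWindow()
    relax = relax or RelaxationTimes()
    real, sens, phases = combine_and_phase(study, window)

    auc = auc_maps(real, window)
    background = ~study.geometry.body_mask
    noise = {met: estimate_noise(real[m], frame_index=-1,
                                 background_mask=background)
             for m, met in enumerate(("pyruvate", "lactate", "bicarbonate"))}
    snr = {met: auc_snr_map(auc[met], noise[met], window.n_frames(met))
           for met in auc}
    mask = pyruvate_mask(snr["pyruvate"], snr_threshold)
    ratios = ratio_maps(auc["lactate"], auc["bicarbonate"], auc["pyruvate"],
                        mask)

    myo = study.geometry.myocardial_mask & mask
    flips = study.protocol.flip_schedule()
    metrics = {}
    for met in snr:
        metrics[f"{met}_snr"] = float(np.mean(snr[met][myo])) if myo.any() else np.nan
    for name, rmap in ratios.items():
        vals = rmap[myo]
        vals = vals[np.isfinite(vals)]
        metrics[name] = float(vals.mean()) if vals.size else np.nan
    if myo.any():
        roi_tc = MetaboliteTimecourses(
            s_pyruvate=real[0][:, myo].mean(axis=1),
            s_lactate=real[1][:, myo].mean(axis=1),
            s_bicarbonate=real[2][:, myo].mean(axis=1),
        )
        fit = fit_inputless(roi_tc, relax, flips)
        metrics["k_pl"] = fit.k_pl
        metrics["k_pb"] = fit.k_pb
    else:
        metrics["k_pl"] = metrics["k_pb"] = np.nan

    quant = StudyQuantification(
        real_images=real, sensitivity=sens, phase_maps=phases, auc=auc,
        snr=snr, noise_sigma={met: n.sigma for met, n in noise.items()},
        mask=mask, ratios=ratios, metrics=metrics,
    )
    if fit_voxel_maps:
        k_pl_map, k_pb_map = fit_rate_maps(real, myo, relax, flips)
        quant.metrics["k_pl_map"] = k_pl_map
        quant.metrics["k_pb_map"] = k_pb_map
    return quant
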