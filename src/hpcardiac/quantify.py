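"""AUC, AUC-SNR, masked metabolite-ratio and coil-corrected maps.

All quantification operates on the signed real channel of phased dynamic
images: rectifying to magnitude would bias low-SNR measurements (most
importantly bicarbonate), whereas the real channel preserves zero-mean
Gaussian noise.  Per-metabolite AUC windows restrict the temporal sum to
frames with observable signal so the sum does not accumulate extra noise.

Frame windows are 1-based inclusive in configuration (the 5th to 20th
time-points of a 30-frame series sum 16 frames) and converted to 0-based
Python slices internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METABOLITES = ("pyruvate", "lactate", "bicarbonate")


@dataclass(frozen=True)
class AUCWindow:
    """Per-metabolite frame windows, 1-based inclusive."""

    pyruvate: tuple[int, int] = (1, 25)
    lactate: tuple[int, int] = (1, 30)
    bicarbonate: tuple[int, int] = (5, 20)

    def window(self, metabolite: str) -> tuple[int, int]:
        return getattr(self, metabolite)

    def n_frames(self, metabolite: str) -> int:
        first, last = self.window(metabolite)
        return last - first + 1

    def frame_slice(self, metabolite: str, n_t: int) -> slice:
        first, last = self.window(metabolite)
        if not (1 <= first <= last <= n_t):
            raise ValueError(
                f"{metabolite} window {first}..{last} exceeds {n_t} frames")
        return slice(first - 1, last)


@dataclass(frozen=True)
class NoiseEstimate:
    sigma: float
    source_frame: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("noise sigma must be positive (got a degenerate "
                             "constant noise frame?)")


def auc_maps(images: np.ndarray, window: AUCWindow | None = None) -> dict:
    """Windowed temporal sums of the real dynamics, per metabolite.

    ``images`` has shape (3, n_frames, *spatial) ordered (pyruvate, lactate,
    bicarbonate).  The AUC is a plain frame sum over the metabolite's window
    (no frame-interval weighting; the SNR definition's sqrt(n) normalization
    assumes unweighted summation).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim < 2 or images.shape[0] != 3:
        raise ValueError("images must be (3, n_frames, *spatial)")
    window = window or AUCWindow()
    n_t = images.shape[1]
    return {
        met: images[m, window.frame_slice(met, n_t)].sum(axis=0)
        for m, met in enumerate(METABOLITES)
    }


def estimate_noise(images_one_metabolite: np.ndarray, frame_index: int = -1,
                   background_mask: np.ndarray | None = None) -> NoiseEstimate:
    """Noise sigma from a single post-decay frame of the real dynamics.

    ``sigma`` is the spatial standard deviation of the real image at
    ``frame_index`` (default: last frame), over ``background_mask`` if given
    (e.g. everything outside the body), else the whole field of view.
    """
    images = np.asarray(images_one_metabolite, dtype=float)
    frame = images[frame_index]
    if background_mask is not None:
        frame = frame[np.asarray(background_mask, dtype=bool)]
    sigma = float(np.std(frame))
    n = images.shape[0]
    return NoiseEstimate(sigma=sigma,
                         source_frame=int(frame_index) % n)


def auc_snr_map(auc: np.ndarray, noise: NoiseEstimate, n_frames: int) -> np.ndarray:
    """AUC-SNR: ``|AUC| / (sigma * sqrt(n_frames))``.

    The sqrt(n) factor accounts for noise averaging over the summed frames.
    """
    if noise.sigma <= 0:
        raise ValueError("noise sigma must be positive")
    return np.abs(np.asarray(auc, dtype=float)) / (noise.sigma * np.sqrt(n_frames))


def pyruvate_mask(snr_map: np.ndarray, threshold: float = 200.0) -> np.ndarray:
    """Voxels meeting the minimum pyruvate AUC-SNR threshold.

    The nominal threshold is ~200; it is configurable per study (the
    per-subject adjustment is a manual override, not an algorithm).
    """
    return np.asarray(snr_map, dtype=float) >= threshold


def ratio_maps(auc_lactate, auc_bicarbonate, auc_pyruvate, mask) -> dict:
    """Signed metabolite AUC ratios inside the pyruvate-SNR mask.

    Returns lactate/pyruvate, bicarbonate/pyruvate and bicarbonate/lactate
    maps with NaN outside the mask.  Signs are preserved — a small negative
    bicarbonate AUC (noise) yields a negative ratio rather than a rectified
    one.
    """
    mask = np.asarray(mask, dtype=bool)
    out = {}
    pairs = {
        "lactate_pyruvate": (auc_lactate, auc_pyruvate),
        "bicarbonate_pyruvate": (auc_bicarbonate, auc_pyruvate),
        "bicarbonate_lactate": (auc_bicarbonate, auc_lactate),
    }
    for name, (num, den) in pairs.items():
        num = np.asarray(num, dtype=float)
        den = np.asarray(den, dtype=float)
        r = np.full(num.shape, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            r[mask] = num[mask] / den[mask]
        out[name] = r
    return out


def coil_correct(image: np.ndarray, sensitivity_magnitude: np.ndarray,
                 mask: np.ndarray) -> np.ndarray:
    """Divide out the receive-coil shading inside a mask; NaN elsewhere."""
    image = np.asarray(image, dtype=float)
    field = np.asarray(sensitivity_magnitude, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if np.any(field[mask] <= 0):
        raise ValueError("sensitivity field must be positive inside the mask")
    out = np.full(image.shape, np.nan)
    out[mask] = image[mask] / field[mask]
    return out
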