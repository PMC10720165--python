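"""AHA 16-segment regional analysis and fed/fasted cohort statistics.

The left-ventricular myocardium is divided into the American Heart
Association 16-segment model: 6 basal, 6 mid-cavity and 4 apical segments
(the apical-cap segment 17 of the 17-segment standard is not used here).
Segments are angular sectors about the LV center, measured from the
RV-insertion reference angle, anterior segment first, proceeding
counterclockwise in the standard short-axis display convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

#: segment label offsets per slice level and sector width in degrees
_LEVELS = {"basal": (1, 6, 60.0), "mid": (7, 6, 60.0), "apical": (13, 4, 90.0)}


@dataclass
class AHASegments:
    """Integer label map 1..16 over myocardial voxels (0 elsewhere)."""

    labels: np.ndarray  # (n_slices, ny, nx) int
    slice_levels: tuple[str, ...]
    rv_insertion_deg: float


def assign_aha16(
    myocardial_mask: np.ndarray,
    lv_centers: np.ndarray,
    rv_insertion_deg: float,
    slice_levels,
) -> AHASegments:
    """Assign AHA 16-segment labels to a per-slice myocardial mask.

    Parameters
    ----------
    myocardial_mask : boolean ndarray, (n_slices, ny, nx)
    lv_centers : ndarray, (n_slices, 2)
        LV center per slice as (row, col) voxel coordinates.
    rv_insertion_deg : float
        Reference angle (degrees, counterclockwise from the +x image axis
        with anterior up) at which the anterior segment starts.
    slice_levels : sequence of "basal" | "mid" | "apical", one per slice.

    A slice with an empty mask simply receives no labels.
    """
    mask = np.asarray(myocardial_mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("myocardial_mask must be (n_slices, ny, nx)")
    lv_centers = np.asarray(lv_centers, dtype=float)
    levels = tuple(slice_levels)
    if len(levels) != mask.shape[0] or lv_centers.shape != (mask.shape[0], 2):
        raise ValueError("need one slice level and one LV center per slice")
    for lvl in levels:
        if lvl not in _LEVELS:
            raise ValueError(f"unknown slice level {lvl!r}")

    labels = np.zeros(mask.shape, dtype=np.int16)
    ny, nx = mask.shape[1:]
    yy, xx = np.mgrid[0:ny, 0:nx]
    for s, lvl in enumerate(levels):
        if not mask[s].any():
            continue
        base, n_sectors, width = _LEVELS[lvl]
        cy, cx = lv_centers[s]
        # anterior is up in the image (-y row direction); counterclockwise in
        # display means increasing mathematical angle with y flipped
        theta = np.degrees(np.arctan2(-(yy - cy), xx - cx))
        sector = np.floor(((theta - rv_insertion_deg) % 360.0) / width)
        sector = np.clip(sector.astype(int), 0, n_sectors - 1)
        labels[s][mask[s]] = base + sector[mask[s]]
    return AHASegments(labels=labels, slice_levels=levels,
                       rv_insertion_deg=float(rv_insertion_deg))


def segment_means(value_map: np.ndarray, segments: AHASegments) -> pd.Series:
    """Mean of defined (non-NaN) voxels per AHA segment.

    Returns a 16-entry Series indexed by segment number; a segment with no
    defined voxels is NaN.
    """
    value_map = np.asarray(value_map, dtype=float)
    if value_map.shape != segments.labels.shape:
        raise ValueError("value map and segment labels must share a grid")
    out = pd.Series(np.nan, index=pd.RangeIndex(1, 17, name="segment"),
                    name="mean")
    for seg in range(1, 17):
        vals = value_map[segments.labels == seg]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out.loc[seg] = vals.mean()
    return out


def paired_ttest(fasted, fed):
    """Paired two-sided Student's t-test on per-subject differences.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` on the
    differences ``d = fed - fasted`` (sample sd, ddof=1) and the p-value from
    the t-distribution with ``n - 1`` degrees of freedom.  Identical pairs
    give ``t = 0, p = 1``.
    """
    fasted = np.asarray(fasted, dtype=float)
    fed = np.asarray(fed, dtype=float)
    if fasted.shape != fed.shape or fasted.ndim != 1 or fasted.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = fed - fasted
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * _stats.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p)


def pearson_corr(x, y):
    """Pearson product-moment correlation with a two-sided t-test p-value.

    ``r`` is the standard sample correlation; the p-value uses
    ``t = r * sqrt((n-2)/(1-r^2))`` with ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    n = x.size
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt(np.sum(dx ** 2) * np.sum(dy ** 2))
    if denom == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.sum(dx * dy) / denom)
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * _stats.t.sf(abs(t), df=n - 2)
    return r, float(p)
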