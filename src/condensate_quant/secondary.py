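"""Auxiliary quantifications: FRAP curve normalisation, two-channel
co-localisation, line transects, semi-quantitative intensity levels, and the
Mann–Whitney U group comparison."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .core import FlatTraceError, VolumetricImage, ZeroVarianceError

__all__ = [
    "FrapTrace",
    "ColocResult",
    "IntensityLevel",
    "normalize_frap",
    "pearson_colocalization",
    "transect_profile",
    "integrated_intensity",
    "compare_groups",
]

log = logging.getLogger(__name__)


@dataclass
class FrapTrace:
    time_index: np.ndarray
    raw: np.ndarray
    normalised: np.ndarray  # min -> 0, max -> 1 exactly
    n_prebleach: int
    bleach_fraction: float  # fractional signal drop at the bleach frame
    excluded: bool  # True if the bleach removed < 50 % of the pre-bleach signal


def normalize_frap(
    raw_trace: np.ndarray, n_prebleach: int = 5, min_bleach_fraction: float = 0.5
) -> FrapTrace:
    """Affine-normalise a recovery curve: maximum to 1, minimum to 0.

    Traces whose signal dropped by less than ``min_bleach_fraction`` of the
    pre-bleach mean at the bleach frame are flagged ``excluded`` (the study's
    inclusion rule), not rejected.
    """
    raw = np.asarray(raw_trace, dtype=float)
    if raw.ndim != 1 or raw.size <= n_prebleach + 1:
        raise ValueError(f"trace must be 1D with > n_prebleach+1 points, got {raw.shape}")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise FlatTraceError("flat trace: max == min, normalisation undefined")
    pre = float(raw[:n_prebleach].mean())
    drop = (pre - float(raw[n_prebleach])) / pre if pre > 0 else 0.0
    return FrapTrace(
        time_index=np.arange(raw.size),
        raw=raw,
        normalised=(raw - lo) / (hi - lo),
        n_prebleach=n_prebleach,
        bleach_fraction=drop,
        excluded=drop < min_bleach_fraction,
    )


@dataclass
class ColocResult:
    pearson_r: float
    p_value: float
    n_voxels: int
    mask_used: str


def _coloc_mask(ch1: VolumetricImage, ch2: VolumetricImage, mask) -> tuple[np.ndarray, str]:
    if mask is None or (isinstance(mask, str) and mask == "otsu-union"):
        # whole-image correlations are inflated by the shared dark background;
        # default to the union of per-channel Otsu foregrounds
        m = (ch1.data > threshold_otsu(ch1.data)) | (ch2.data > threshold_otsu(ch2.data))
        return m, "otsu-union"
    if isinstance(mask, str) and mask == "whole-image":
        return np.ones(ch1.shape, dtype=bool), "whole-image"
    if isinstance(mask, np.ndarray):
        if mask.shape != ch1.shape:
            raise ValueError("custom mask shape does not match the images")
        return mask.astype(bool), "custom"
    raise ValueError(f"unknown mask {mask!r}")


def pearson_colocalization(
    ch1: VolumetricImage,
    ch2: VolumetricImage,
    mask: Union[None, str, np.ndarray] = None,
) -> ColocResult:
    """Pixelwise Pearson correlation of the two channels inside a mask."""
    if ch1.shape != ch2.shape:
        raise ValueError(f"channel grids differ: {ch1.shape} vs {ch2.shape}")
    m, name = _coloc_mask(ch1, ch2, mask)
    n = int(m.sum())
    if n < 10:
        raise ValueError(f"mask has only {n} voxels (need >= 10)")
    a, b = ch1.data[m], ch2.data[m]
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError("a channel has zero variance inside the mask")
    r, p = stats.pearsonr(a, b)
    return ColocResult(pearson_r=float(r), p_value=float(p), n_voxels=n, mask_used=name)


def transect_profile(
    ch1: VolumetricImage,
    ch2: VolumetricImage,
    start: tuple[int, int],
    end: tuple[int, int],
    z: int = 0,
    interpolate: bool = False,
) -> dict[str, np.ndarray]:
    """Paired intensities along a line in one z-plane.

    Default sampling is nearest-voxel on ``max(|Δy|, |Δx|) + 1`` steps
    (reproducible integer geometry); ``interpolate=True`` switches to linear
    interpolation at the same sample positions.
    """
    if ch1.shape != ch2.shape:
        raise ValueError("channel grids differ")
    (y0, x0), (y1, x1) = start, end
    nz, ny, nx = ch1.shape
    for (y, x) in (start, end):
        if not (0 <= y < ny and 0 <= x < nx) or not 0 <= z < nz:
            raise ValueError(f"endpoint (z={z}, y={y}, x={x}) outside grid {ch1.shape}")
    n = int(max(abs(y1 - y0), abs(x1 - x0))) + 1
    if n == 1:
        raise ValueError("degenerate zero-length transect")
    ys = np.linspace(y0, y1, n)
    xs = np.linspace(x0, x1, n)
    if interpolate:
        coords = np.vstack([ys, xs])
        v1 = ndimage.map_coordinates(ch1.data[z], coords, order=1)
        v2 = ndimage.map_coordinates(ch2.data[z], coords, order=1)
    else:
        yi, xi = np.round(ys).astype(int), np.round(xs).astype(int)
        v1, v2 = ch1.data[z, yi, xi], ch2.data[z, yi, xi]
    dist = np.hypot((ys - y0) * ch1.voxel_size[1], (xs - x0) * ch1.voxel_size[2])
    return {"distance_um": dist, "ch1": v1, "ch2": v2}


@dataclass
class IntensityLevel:
    integrated_intensity_per_slice: float
    background_roi_mean: float
    n_slices: int
    channel: str
    roi_corner: tuple[int, int]


def integrated_intensity(
    img: VolumetricImage,
    background_roi: Optional[tuple[int, int]] = None,
    roi_size: int = 10,
) -> IntensityLevel:
    """Semi-quantitative protein level: z sum projection, background
    subtraction from a 10 × 10 pixel ROI mean, total intensity normalised by
    the slice count.

    ``background_roi`` is the (y, x) corner of the ROI on the projection; by
    default the image corner with the lowest mean is used (the manual ROI
    choice made reproducible).
    """
    proj = img.data.sum(axis=0)
    ny, nx = proj.shape
    if roi_size > min(ny, nx):
        raise ValueError(f"ROI size {roi_size} exceeds projection shape {proj.shape}")
    if background_roi is None:
        corners = [(0, 0), (0, nx - roi_size), (ny - roi_size, 0), (ny - roi_size, nx - roi_size)]
        background_roi = min(
            corners, key=lambda c: proj[c[0] : c[0] + roi_size, c[1] : c[1] + roi_size].mean()
        )
    y0, x0 = background_roi
    if not (0 <= y0 <= ny - roi_size and 0 <= x0 <= nx - roi_size):
        raise ValueError(f"ROI corner {background_roi} puts the ROI outside the projection")
    roi = proj[y0 : y0 + roi_size, x0 : x0 + roi_size]
    roi_mean = float(roi.mean())
    if proj.std() > 0 and roi.mean() > threshold_otsu(proj):
        log.warning("background ROI at %s overlaps detected signal", background_roi)
    corrected = np.clip(proj - roi_mean, 0.0, None)
    n_slices = img.shape[0]
    return IntensityLevel(
        integrated_intensity_per_slice=float(corrected.sum()) / n_slices,
        background_roi_mean=roi_mean,
        n_slices=n_slices,
        channel=img.channel,
        roi_corner=(int(y0), int(x0)),
    )


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def compare_groups(values_a, values_b) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U test with tie correction; returns the U
    statistic of group a, the p-value and significance stars
    (*** p<0.001, ** p<0.01, * p<0.05, n.s. otherwise)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"each group needs n >= 3, got {a.size} and {b.size}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    stars = next((s for thr, s in _STARS if res.pvalue < thr), "n.s.")
    return float(res.statistic), float(res.pvalue), stars
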