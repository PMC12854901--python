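"""Core containers and exceptions shared across the pipeline.

Intensities are arbitrary fluorescence units (a.u.) stored as nonnegative
floats; axis order is (z, y, x) throughout, with voxel dimensions in μm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class CondensateQuantError(Exception):
    """Base class for pipeline errors."""


class PlacementError(CondensateQuantError):
    """Condensate placement by rejection sampling exhausted its attempt cap."""


class DegenerateHistogramError(CondensateQuantError):
    """Histogram has zero total weight (all-zero image)."""


class ThresholdOrderError(CondensateQuantError):
    """Condensate threshold does not exceed the nucleus threshold."""


class NoConvergedFitError(CondensateQuantError):
    """No Gaussian-sum fit converged for any candidate component count."""


class InsufficientVarianceError(CondensateQuantError):
    """A correlation was requested on a column with zero variance."""


class FlatTraceError(CondensateQuantError):
    """A FRAP trace cannot be normalised because max == min."""


class ZeroVarianceError(CondensateQuantError):
    """Pearson correlation is undefined for a zero-variance channel."""


@dataclass
class VolumetricImage:
    """A single-channel 3D fluorescence stack.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Nonnegative voxel intensities, a.u.
    voxel_size : (float, float, float)
        Voxel edge lengths in μm, ordered (z, y, x).
    channel : str
        Free-text channel label (e.g. ``"mClover3"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "ch1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z,y,x) array, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return math.prod(self.voxel_size)

    def with_data(self, data: np.ndarray) -> "VolumetricImage":
        """Copy of this image with replaced intensity data."""
        return VolumetricImage(data=data, voxel_size=self.voxel_size, channel=self.channel)
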