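"""Core in-memory containers shared by the imaging pipeline.

Conventions: axis order is (z, y, x), indices are 0-based, voxel spacing is
given in micrometers as (dz, dy, dx).  All geometry is computed in pixel
units unless a value is explicitly documented as micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Default voxel spacing in micrometers (dz, dy, dx): 0.2 um optical
#: sectioning with 0.1 um lateral pixels.
DEFAULT_SPACING = (0.2, 0.1, 0.1)


@dataclass
class VoxelStack:
    """A single-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        Non-negative intensities on a ``(nz, ny, nx)`` grid.
    spacing
        Voxel edge lengths in micrometers, ordered ``(dz, dy, dx)``.
    channel
        Free-form channel label (e.g. ``"dapi"``, ``"sig"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one z-plane")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def plane(self, z: int) -> np.ndarray:
        """Return one z-plane as a 2D array (a view)."""
        return self.data[z]


@dataclass
class BinaryMask3D:
    """A boolean grid congruent with a parent :class:`VoxelStack`."""

    data: np.ndarray
    provenance: str = ""  # "nucleus" | "signal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def plane(self, z: int) -> "BinaryMask2D":
        return BinaryMask2D(self.data[z], provenance=self.provenance, z_index=z)


@dataclass
class BinaryMask2D:
    """One z-plane worth of a boolean mask."""

    data: np.ndarray
    provenance: str = ""
    z_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class Ellipse2D:
    """An oriented ellipse in pixel coordinates.

    ``theta`` is the angle (radians) of the ``a`` semi-axis measured from the
    +x (column) axis toward the +y (row) axis.
    """

    cy: float
    cx: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"ellipse semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def area(self) -> float:
        return np.pi * self.a * self.b

    def normalized_radius_sq(self, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        """(u/a)^2 + (v/b)^2 in the ellipse's own frame; <= 1 means inside."""
        dy = np.asarray(y, dtype=float) - self.cy
        dx = np.asarray(x, dtype=float) - self.cx
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2

    def contains(self, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.normalized_radius_sq(y, x) <= 1.0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Pixel-center membership mask on a grid of the given (ny, nx) shape."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.contains(yy, xx)

    def scaled(self, factor: float) -> "Ellipse2D":
        """Concentric, co-oriented ellipse with semi-axes scaled by ``factor``."""
        return Ellipse2D(self.cy, self.cx, self.a * factor, self.b * factor, self.theta)


@dataclass
class ZoneSet:
    """Three disjoint equal-area concentric elliptical zones of a nuclear slice.

    Ordered (central, intermediate, peripheral); the union is the interior of
    the fitted outer ellipse, clipped to the grid.
    """

    central: np.ndarray
    intermediate: np.ndarray
    peripheral: np.ndarray
    ellipse: Ellipse2D

    def __post_init__(self) -> None:
        for m in (self.central, self.intermediate, self.peripheral):
            if m.shape != self.central.shape:
                raise ValueError("zone masks must share one grid")
        if np.any(self.central & self.intermediate) or np.any(self.central & self.peripheral) or np.any(
            self.intermediate & self.peripheral
        ):
            raise ValueError("zones must be disjoint")

    @property
    def masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.central, self.intermediate, self.peripheral

    @property
    def union(self) -> np.ndarray:
        return self.central | self.intermediate | self.peripheral

    def areas(self) -> tuple[int, int, int]:
        return tuple(int(m.sum()) for m in self.masks)


@dataclass
class LineProfile:
    """Interpolated intensities sampled along a line segment.

    ``distances`` are pixel distances from the first endpoint, strictly
    increasing; endpoints are (y, x) pixel coordinates.
    """

    distances: np.ndarray
    values: np.ndarray
    start: tuple[float, float]
    end: tuple[float, float]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances.size != self.values.size:
            raise ValueError("distances and values must align")
        if self.distances.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.distances[-1] - self.distances[0])


@dataclass
class QuantResult:
    """Per-nucleus quantification summary.

    ``zone_fractions`` is ``None`` when the nucleus failed the ellipticity QC
    gate (such nuclei are excluded from the radial-zone readout) or when no
    signal intersected the zones on the chosen slice.
    """

    nucleus_id: str
    volume_fraction: float
    zone_fractions: Optional[tuple[float, float, float]]
    enrichment_ratio: float
    intensity_ratio: float
    slice_used: int
    qc_pass: bool
    qc_score: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.volume_fraction <= 1.0):
            raise ValueError("volume fraction must be in [0, 1]")
        if self.zone_fractions is not None:
            p = np.asarray(self.zone_fractions, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("zone fractions must be non-negative and sum to 1")
        if self.enrichment_ratio < 1.0 - 1e-12:
            raise ValueError("enrichment ratio is >= 1 by construction")
        if self.intensity_ratio <= 0:
            raise ValueError("intensity ratio must be positive")
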