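"""Ring-array geometry and in-plane imaging grids.

The transducer is a circle of point-like elements surrounding the target; the
center of the ring is the origin of the Cartesian coordinate system. Element 0
sits at ``start_angle`` (default: the positive x-axis) and indices increase
counter-clockwise. All lengths are millimetres, times seconds, frequencies Hz;
sound speeds cross the API in m/s and are converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = ["RingArray", "ImagingGrid", "element_positions", "make_grid"]

# tolerance used to absorb float fuzz in pixel-count arithmetic
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class RingArray:
    """Geometry and acquisition parameters of a circular transducer array.

    Parameters
    ----------
    n_elements : int
        Number of elements on the ring (>= 3).
    radius : float
        Ring radius in mm.
    center_frequency : float
        Pulse center frequency in Hz.
    sampling_frequency : float
        RF sampling frequency in Hz.
    start_angle : float, optional
        Angle of element 0 in radians, counter-clockwise from +x.
    """

    n_elements: int
    radius: float
    center_frequency: float
    sampling_frequency: float
    start_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.n_elements < 3:
            raise ValueError(f"n_elements must be >= 3, got {self.n_elements}")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.center_frequency <= 0 or self.sampling_frequency <= 0:
            raise ValueError("frequencies must be positive")

    @property
    def element_angles(self) -> np.ndarray:
        """Angles of all elements, radians, shape (N,)."""
        return self.start_angle + 2.0 * np.pi * np.arange(self.n_elements) / self.n_elements

    @property
    def element_positions(self) -> np.ndarray:
        """(x, y) positions of all elements in mm, shape (N, 2)."""
        ang = self.element_angles
        return np.column_stack([self.radius * np.cos(ang), self.radius * np.sin(ang)])

    @property
    def pitch(self) -> float:
        """Adjacent-element center-to-center arc pitch, mm (2*pi*R/N)."""
        return 2.0 * np.pi * self.radius / self.n_elements

    @property
    def chord_pitch(self) -> float:
        """Adjacent-element straight-line (chord) distance, mm."""
        return 2.0 * self.radius * np.sin(np.pi / self.n_elements)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_elements": int(self.n_elements),
            "radius_mm": float(self.radius),
            "center_frequency_hz": float(self.center_frequency),
            "sampling_frequency_hz": float(self.sampling_frequency),
            "start_angle_rad": float(self.start_angle),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RingArray":
        return cls(
            n_elements=int(d["n_elements"]),
            radius=float(d["radius_mm"]),
            center_frequency=float(d["center_frequency_hz"]),
            sampling_frequency=float(d["sampling_frequency_hz"]),
            start_angle=float(d.get("start_angle_rad", 0.0)),
        )


def element_positions(array: RingArray) -> np.ndarray:
    """(x, y) element positions in mm, element i at start_angle + 2*pi*i/N."""
    return array.element_positions


@dataclass(frozen=True)
class ImagingGrid:
    """Regular in-plane pixel grid (pixel centers), row-major.

    Row index increases with y, column index with x. ``depth_z`` is the
    out-of-plane coordinate shared by every pixel of the slice.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    pixel_spacing: float
    depth_z: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if self.x_max < self.x_min:
            raise ValueError("x_max must be >= x_min")
        if self.y_max < self.y_min:
            raise ValueError("y_max must be >= y_min")

    @property
    def n_cols(self) -> int:
        return int(np.floor((self.x_max - self.x_min) / self.pixel_spacing + _GRID_EPS)) + 1

    @property
    def n_rows(self) -> int:
        return int(np.floor((self.y_max - self.y_min) / self.pixel_spacing + _GRID_EPS)) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def xs(self) -> np.ndarray:
        return self.x_min + self.pixel_spacing * np.arange(self.n_cols)

    @property
    def ys(self) -> np.ndarray:
        return self.y_min + self.pixel_spacing * np.arange(self.n_rows)

    def pixel_centers(self) -> np.ndarray:
        """All pixel-center (x, y) coordinates, shape (n_rows*n_cols, 2), row-major."""
        xx, yy = np.meshgrid(self.xs, self.ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def to_dict(self) -> dict[str, Any]:
        return {
            "extents_mm": [self.x_min, self.x_max, self.y_min, self.y_max],
            "pixel_spacing_mm": float(self.pixel_spacing),
            "depth_z_mm": float(self.depth_z),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ImagingGrid":
        x0, x1, y0, y1 = (float(v) for v in d["extents_mm"])
        return cls(x0, x1, y0, y1, float(d["pixel_spacing_mm"]), float(d.get("depth_z_mm", 0.0)))


def make_grid(
    x_min: float,
    x_max: float,
    y_min: float,
    y_max: float,
    pixel_spacing: float,
    depth_z: float = 0.0,
    ring_radius: float | None = None,
) -> ImagingGrid:
    """Build an :class:`ImagingGrid` of pixel centers.

    If ``ring_radius`` is given, every grid corner must lie strictly inside the
    ring; the offending bound is named in the error otherwise.
    """
    grid = ImagingGrid(x_min, x_max, y_min, y_max, pixel_spacing, depth_z)
    if ring_radius is not None:
        for name, (cx, cy) in {
            "x_min/y_min": (x_min, y_min),
            "x_min/y_max": (x_min, y_max),
            "x_max/y_min": (x_max, y_min),
            "x_max/y_max": (x_max, y_max),
        }.items():
            if np.hypot(cx, cy) >= ring_radius:
                raise ValueError(
                    f"grid corner {name} = ({cx}, {cy}) mm lies outside the ring "
                    f"of radius {ring_radius} mm"
                )
    return grid
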