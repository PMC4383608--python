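"""Image-grid and projection-geometry containers.

Conventions used throughout the package:

* Images are 2-D ``float`` arrays of shape ``(ny, nx)``; row index increases
  downwards, column index to the right.
* Physical coordinates place the origin at the grid centre, with
  ``x = (col - (nx-1)/2) * pixel_size`` (mm, rightwards) and
  ``y = ((ny-1)/2 - row) * pixel_size`` (mm, upwards).
* Projection angles are in degrees, counter-clockwise; the detector
  coordinate of a point is ``s = x*cos(theta) + y*sin(theta)`` measured from
  the central ray.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError

__all__ = ["ImageGrid", "ProjectionGeometry", "Sinogram"]


@dataclass(frozen=True)
class ImageGrid:
    """A square pixel grid with a circular reconstruction support.

    The support mask Omega is the circle inscribed in the grid; pixels whose
    centre falls outside it are excluded from reconstruction.
    """

    nx: int
    ny: int
    pixel_size: float = 1.0  # mm / pixel

    def __post_init__(self) -> None:
        if self.nx != self.ny:
            raise ContractViolationError(f"grid must be square, got {self.nx}x{self.ny}")
        if self.nx < 2 or self.pixel_size <= 0:
            raise ContractViolationError("grid needs nx >= 2 and pixel_size > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def fov(self) -> float:
        """Field-of-view width in mm."""
        return self.nx * self.pixel_size

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centres, each shape (ny, nx)."""
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pixel_size
        y = ((self.ny - 1) / 2.0 - np.arange(self.ny)) * self.pixel_size
        return np.meshgrid(x, y)

    @property
    def support_mask(self) -> np.ndarray:
        """Boolean Omega mask: the inscribed circle of the grid."""
        xx, yy = self.coords()
        r = self.nx * self.pixel_size / 2.0
        return xx * xx + yy * yy <= r * r

    def validate_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self.shape:
            raise ContractViolationError(
                f"image shape {image.shape} does not match grid {self.shape}"
            )
        return image


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam sampling: a set of view angles and a 1-D detector."""

    angles: tuple[float, ...]
    n_detector_bins: int
    detector_spacing: float = 1.0  # mm / bin

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles)
        if len(angles) == 0:
            raise ContractViolationError("need at least one projection angle")
        if len(set(angles)) != len(angles):
            raise ContractViolationError("projection angles must be unique")
        if any(a < 0 or a >= 360 for a in angles):
            raise ContractViolationError("angles must lie in [0, 360)")
        if self.n_detector_bins < 2 or self.detector_spacing <= 0:
            raise ContractViolationError("invalid detector configuration")
        object.__setattr__(self, "angles", angles)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_detector_bins)

    def bin_offsets(self) -> np.ndarray:
        """Detector bin centre coordinates s (mm) relative to the central ray."""
        return (np.arange(self.n_detector_bins) - (self.n_detector_bins - 1) / 2.0) * (
            self.detector_spacing
        )

    def check_covers(self, grid: ImageGrid) -> None:
        """Raise if the detector truncates the grid diagonal."""
        diag = math.hypot(grid.nx, grid.ny) * grid.pixel_size
        if self.n_detector_bins * self.detector_spacing < diag - self.detector_spacing:
            raise ContractViolationError(
                "detector too short for the image diagonal (data would be truncated)"
            )

    @classmethod
    def for_grid(
        cls, grid: ImageGrid, angles: "np.ndarray | tuple[float, ...] | list[float]"
    ) -> "ProjectionGeometry":
        """Default detector for a grid: ceil(sqrt(2)*nx) bins at pixel pitch."""
        n_bins = math.ceil(math.sqrt(2.0) * grid.nx)
        return cls(tuple(float(a) for a in angles), n_bins, grid.pixel_size)


@dataclass
class Sinogram:
    """Line-integral data for one phase: ``values[angle, bin]`` plus the
    noise bound sigma used by the discrepancy stopping rule."""

    geometry: ProjectionGeometry
    values: np.ndarray
    sigma: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ContractViolationError(
                f"sinogram values {self.values.shape} do not match geometry "
                f"{self.geometry.shape}"
            )
        if self.sigma < 0:
            raise ContractViolationError("sigma must be non-negative")

    def copy(self) -> "Sinogram":
        return Sinogram(self.geometry, self.values.copy(), self.sigma)
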