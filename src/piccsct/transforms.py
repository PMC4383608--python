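"""Sparsifying transforms and their adjoints.

Three choices for the prior-term transform T2 of the PICCS penalty
``alpha * ||T2(u - u_p)||_1``:

* ``unitary``  — identity (penalise the difference image directly),
* ``gradient`` — forward differences, i.e. TV of the difference image,
* ``wavelet``  — orthonormal multi-level symmlet-8 decomposition.

The forward-difference pair (grad / grad_adjoint) is also the TV operator
D used by the sparsity term of the objective. All operators expose
``apply`` / ``adjoint`` and are exercised by randomised dot-product tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ConfigurationError, ContractViolationError
from .grid import ImageGrid

__all__ = [
    "GradientField",
    "TransformChoice",
    "grad",
    "grad_adjoint",
    "wavelet_forward",
    "wavelet_inverse",
    "identity_transform",
    "LinearTransform",
    "IdentityTransform",
    "GradientTransform",
    "WaveletTransform",
    "make_transform",
]

_WAVELET = "sym8"


@dataclass
class GradientField:
    """Forward differences of an image: gx along columns, gy along rows."""

    gx: np.ndarray
    gy: np.ndarray

    def __post_init__(self) -> None:
        self.gx = np.asarray(self.gx, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        if self.gx.shape != self.gy.shape:
            raise ContractViolationError("gx and gy must have the same shape")


@dataclass(frozen=True)
class TransformChoice:
    """Named prior-term transform plus its wavelet depth where relevant."""

    name: str = "wavelet"
    wavelet_levels: int = 4

    def __post_init__(self) -> None:
        if self.name not in ("unitary", "gradient", "wavelet"):
            raise ConfigurationError(f"unknown transform {self.name!r}")
        if self.name == "wavelet" and self.wavelet_levels < 1:
            raise ConfigurationError("wavelet_levels must be >= 1")


def grad(image: np.ndarray) -> GradientField:
    """Forward first differences with replicate (Neumann) boundary.

    The difference at the last column/row is zero, so a constant image has
    zero gradient and D^T D is the standard 5-point Neumann Laplacian.
    """
    image = np.asarray(image, dtype=float)
    gx = np.zeros_like(image)
    gy = np.zeros_like(image)
    gx[:, :-1] = image[:, 1:] - image[:, :-1]
    gy[:-1, :] = image[1:, :] - image[:-1, :]
    return GradientField(gx, gy)


def grad_adjoint(field: GradientField) -> np.ndarray:
    """Exact transpose of :func:`grad` (a negative divergence)."""
    gx, gy = field.gx, field.gy
    out = np.zeros_like(gx)
    # d/du[:, j] of sum_j (u[:, j+1] - u[:, j]) gx[:, j]
    out[:, 0] -= gx[:, 0]
    out[:, 1:-1] += gx[:, :-2] - gx[:, 1:-1]
    out[:, -1] += gx[:, -2]
    out[0, :] -= gy[0, :]
    out[1:-1, :] += gy[:-2, :] - gy[1:-1, :]
    out[-1, :] += gy[-2, :]
    return out


def _padded_size(n: int, levels: int) -> int:
    block = 2**levels
    return ((n + block - 1) // block) * block


def wavelet_forward(image: np.ndarray, levels: int = 4) -> np.ndarray:
    """Orthonormal symmlet-8 decomposition, flattened to a vector.

    Periodised filtering keeps the transform exactly orthonormal; grids
    whose side is not a multiple of ``2**levels`` are symmetrically
    zero-padded first (the pad sits outside the circular support, so it is
    inert for reconstruction), making the coefficient vector slightly
    longer than the pixel count for such grids.
    """
    image = np.asarray(image, dtype=float)
    if levels < 1 or 2**levels > max(image.shape):
        raise ConfigurationError(f"invalid wavelet level count {levels}")
    ny, nx = image.shape
    py, px = _padded_size(ny, levels), _padded_size(nx, levels)
    if (py, px) != (ny, nx):
        top = (py - ny) // 2
        left = (px - nx) // 2
        padded = np.zeros((py, px))
        padded[top : top + ny, left : left + nx] = image
        image = padded
    coeffs = pywt.wavedec2(image, _WAVELET, mode="periodization", level=levels)
    arr, _ = pywt.coeffs_to_array(coeffs)
    return arr.ravel()


def wavelet_inverse(coeffs: np.ndarray, grid: ImageGrid, levels: int = 4) -> np.ndarray:
    """Inverse (== adjoint, by orthonormality) of :func:`wavelet_forward`."""
    coeffs = np.asarray(coeffs, dtype=float)
    ny, nx = grid.shape
    py, px = _padded_size(ny, levels), _padded_size(nx, levels)
    if coeffs.size != py * px:
        raise ContractViolationError(
            f"coefficient length {coeffs.size} does not match padded grid {py}x{px}"
        )
    # rebuild the coeffs_to_array slice structure for this shape
    template = pywt.wavedec2(
        np.zeros((py, px)), _WAVELET, mode="periodization", level=levels
    )
    _, slices = pywt.coeffs_to_array(template)
    rebuilt = pywt.array_to_coeffs(coeffs.reshape(py, px), slices, output_format="wavedec2")
    image = pywt.waverec2(rebuilt, _WAVELET, mode="periodization")
    top = (py - ny) // 2
    left = (px - nx) // 2
    return image[top : top + ny, left : left + nx]


def identity_transform(image: np.ndarray) -> np.ndarray:
    """The unitary choice: T2 = I."""
    return np.asarray(image, dtype=float)


class LinearTransform:
    """Interface: ``apply`` maps an image to its coefficient vector,
    ``adjoint`` maps coefficients back to an image."""

    def apply(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def adjoint(self, coeffs: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class IdentityTransform(LinearTransform):
    def __init__(self, grid: ImageGrid):
        self.grid = grid

    def apply(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(image, dtype=float).ravel().copy()

    def adjoint(self, coeffs: np.ndarray) -> np.ndarray:
        return np.asarray(coeffs, dtype=float).reshape(self.grid.shape)


class GradientTransform(LinearTransform):
    """T2 = D: coefficient vector is (gx, gy) stacked."""

    def __init__(self, grid: ImageGrid):
        self.grid = grid

    def apply(self, image: np.ndarray) -> np.ndarray:
        g = grad(np.asarray(image, dtype=float).reshape(self.grid.shape))
        return np.concatenate([g.gx.ravel(), g.gy.ravel()])

    def adjoint(self, coeffs: np.ndarray) -> np.ndarray:
        n = self.grid.n_pixels
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.size != 2 * n:
            raise ContractViolationError("gradient coefficient vector has wrong length")
        gx = coeffs[:n].reshape(self.grid.shape)
        gy = coeffs[n:].reshape(self.grid.shape)
        return grad_adjoint(GradientField(gx, gy))


class WaveletTransform(LinearTransform):
    def __init__(self, grid: ImageGrid, levels: int = 4):
        if 2**levels > grid.nx:
            raise ConfigurationError(
                f"wavelet_levels={levels} too deep for a {grid.nx}-pixel grid"
            )
        self.grid = grid
        self.levels = levels

    def apply(self, image: np.ndarray) -> np.ndarray:
        return wavelet_forward(
            np.asarray(image, dtype=float).reshape(self.grid.shape), self.levels
        )

    def adjoint(self, coeffs: np.ndarray) -> np.ndarray:
        return wavelet_inverse(coeffs, self.grid, self.levels)


def make_transform(choice: TransformChoice, grid: ImageGrid) -> LinearTransform:
    """Instantiate the T2 operator named by ``choice`` on ``grid``."""
    if choice.name == "unitary":
        return IdentityTransform(grid)
    if choice.name == "gradient":
        return GradientTransform(grid)
    return WaveletTransform(grid, choice.wavelet_levels)
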