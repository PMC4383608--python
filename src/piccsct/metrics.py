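"""Quantitative image-quality metrics for gated-CT reconstructions.

The suite mirrors standard low-dose CT evaluation practice: contrast as
peak-to-valley on line profiles, noise as the coefficient of variation in
soft-tissue ROIs, contrast-to-noise ratio of small lung structures,
mean-square error against a reference inside region masks, and motion
recovery as the displacement between per-phase profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ContractViolationError, DegenerateInputError
from .grid import ImageGrid

__all__ = [
    "RegionMask",
    "Profile",
    "mse_in_mask",
    "coefficient_of_variation",
    "cnr",
    "peak_to_valley",
    "extract_profile",
    "motion_displacement",
    "place_oval_rois",
]


@dataclass
class RegionMask:
    """A named boolean pixel set used for ROI statistics."""

    name: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not self.pixels.any():
            raise ContractViolationError(f"mask {self.name!r} is empty")

    @property
    def size(self) -> int:
        return int(self.pixels.sum())


@dataclass
class Profile:
    """Intensity samples along a straight segment between two pixel points."""

    start: tuple[float, float]  # (row, col)
    end: tuple[float, float]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise ContractViolationError("a profile needs at least 2 samples")

    @property
    def spacing(self) -> float:
        """Distance between consecutive samples, in pixels."""
        length = np.hypot(
            self.end[0] - self.start[0], self.end[1] - self.start[1]
        )
        return float(length) / (self.samples.size - 1)


def _masked(img: np.ndarray, mask: RegionMask) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.shape != mask.pixels.shape:
        raise ContractViolationError("image and mask shapes differ")
    return img[mask.pixels]


def mse_in_mask(img: np.ndarray, reference: np.ndarray, mask: RegionMask) -> float:
    """Mean squared difference over the mask pixels."""
    a = _masked(img, mask)
    b = _masked(np.asarray(reference, dtype=float), mask)
    return float(np.mean((a - b) ** 2))


def coefficient_of_variation(img: np.ndarray, mask: RegionMask) -> float:
    """Sample standard deviation divided by the mean inside the mask."""
    vals = _masked(img, mask)
    mean = vals.mean()
    if mean == 0:
        raise DegenerateInputError("CoV undefined for a zero-mean ROI")
    return float(vals.std(ddof=1) / mean)


def cnr(
    img: np.ndarray,
    vessel: RegionMask,
    lung: RegionMask,
    noise_roi: RegionMask,
) -> float:
    """Contrast-to-noise ratio of a vessel against lung background.

    ``|mean(vessel) - mean(lung)| / sd(noise_roi)`` with the sample (n-1)
    standard deviation; the noise ROI is a uniform soft-tissue region.
    """
    sd = _masked(img, noise_roi).std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("CNR undefined for zero noise")
    return float(abs(_masked(img, vessel).mean() - _masked(img, lung).mean()) / sd)


def peak_to_valley(profile: Profile, mode: str = "ratio") -> float:
    """Contrast of a profile: max/min (``ratio``) or max - min (``difference``)."""
    s = profile.samples
    if mode == "ratio":
        if s.min() <= 0:
            raise DegenerateInputError("PV ratio needs a strictly positive profile")
        return float(s.max() / s.min())
    if mode == "difference":
        return float(s.max() - s.min())
    raise ContractViolationError(f"unknown peak-to-valley mode {mode!r}")


def extract_profile(
    img: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    n_samples: int = 100,
) -> Profile:
    """Bilinear samples at equally spaced points on the segment start-end.

    Coordinates are (row, col) pixel positions; both endpoints must lie
    inside the image.
    """
    img = np.asarray(img, dtype=float)
    for pt in (start, end):
        if not (0 <= pt[0] <= img.shape[0] - 1 and 0 <= pt[1] <= img.shape[1] - 1):
            raise ContractViolationError(f"profile endpoint {pt} outside the image")
    if n_samples < 2:
        raise ContractViolationError("need at least 2 samples")
    rows = np.linspace(start[0], end[0], n_samples)
    cols = np.linspace(start[1], end[1], n_samples)
    samples = map_coordinates(img, np.vstack([rows, cols]), order=1, mode="nearest")
    return Profile(tuple(start), tuple(end), samples)


def motion_displacement(
    profile_a: Profile, profile_b: Profile, pixel_size: float = 1.0
) -> float:
    """Displacement (mm) between two equally sampled profiles.

    A coarse integer shift from the cross-correlation of the
    mean-subtracted profiles (search restricted to a quarter of the
    profile length), refined to sub-sample precision by minimising the
    mean squared mismatch between profile b and the linearly interpolated,
    shifted profile a over their overlap; the result is converted to mm
    through the profile sample spacing and the pixel size.
    """
    a = profile_a.samples - profile_a.samples.mean()
    b = profile_b.samples - profile_b.samples.mean()
    if a.size != b.size or abs(profile_a.spacing - profile_b.spacing) > 1e-9:
        raise ContractViolationError("profiles must share their sampling")
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise DegenerateInputError("flat profiles carry no displacement information")
    n = a.size
    corr = np.correlate(b, a, mode="full")
    lags = np.arange(corr.size) - (n - 1)
    corr[np.abs(lags) > n // 4] = -np.inf
    k0 = float(lags[int(np.argmax(corr))])

    xs = np.arange(n, dtype=float)

    def mismatch(d: float) -> float:
        valid = (xs - d >= 0) & (xs - d <= n - 1)
        a_shifted = np.interp(xs[valid] - d, xs, a)
        return float(np.mean((b[valid] - a_shifted) ** 2))

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        mismatch, bounds=(k0 - 2.0, k0 + 2.0), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x * profile_a.spacing * pixel_size)


def place_oval_rois(
    region: np.ndarray,
    grid: ImageGrid,
    n_rois: int = 3,
    roi_area_mm2: float = 12.48,
    seed: int = 0,
    max_tries: int = 2000,
) -> list[RegionMask]:
    """Seeded placement of oval ROIs fully inside a region mask.

    The default area, 12.48 mm^2, corresponds to a 312-pixel oval on a
    0.2 mm grid; holding the physical area fixed keeps the ROI statistics
    comparable across grid resolutions. Ovals have a 4:3 axis ratio and
    are drawn without overlap.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ContractViolationError("region mask is empty")
    px = grid.pixel_size
    area_px = roi_area_mm2 / (px * px)
    # semi-axes a:b = 4:3 with pi*a*b = area
    b = np.sqrt(area_px * 3.0 / (4.0 * np.pi))
    a = 4.0 * b / 3.0
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(region)
    yy, xx = np.mgrid[0 : grid.ny, 0 : grid.nx]
    taken = np.zeros_like(region)
    rois: list[RegionMask] = []
    for _ in range(max_tries):
        if len(rois) == n_rois:
            break
        i = rng.integers(rows.size)
        cy, cx = rows[i], cols[i]
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        oval = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if oval.sum() < 0.5 * area_px:
            continue
        if np.all(region[oval]) and not np.any(taken[oval]):
            taken |= oval
            rois.append(RegionMask(f"soft_roi_{len(rois)}", oval))
    if len(rois) < n_rois:
        raise DegenerateInputError(
            f"could not place {n_rois} ROIs of {roi_area_mm2} mm^2 in the region"
        )
    return rois
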