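"""Calibrated 3D volumes and the filtering primitives shared by the pipeline.

Conventions
-----------
Arrays are indexed ``[x, y, z]`` with 0-based voxel indices; the physical
position of a voxel centre is ``index * spacing``.  Calibration is given in
micrometres per voxel and is typically anisotropic (``dz >= dx``), which every
distance-aware primitive here takes into account.  Filter neighbourhoods are
clipped at the volume border: no padding values are invented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "Calibration",
    "Volume",
    "LabelVolume",
    "Seed",
    "median_filter_3d",
    "bandpass_filter_3d",
    "distance_map_background",
    "local_maxima_3d",
]

#: FWHM of a Gaussian is 2.355 sigma; used to map a size band onto DoG sigmas.
FWHM_FACTOR = 2.355

UINT16_MAX = 65535.0


@dataclass(frozen=True)
class Calibration:
    """Physical voxel spacing in micrometres along x, y, z."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"calibration {name} must be finite and > 0, got {v}")

    @property
    def anisotropy(self) -> float:
        """Ratio dz/dx; > 1 for typical confocal stacks."""
        return self.dz / self.dx

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)


@dataclass
class Volume:
    """A scalar 3D image with voxel calibration.

    ``values`` has shape (nx, ny, nz).  Channels of a multi-channel stack are
    held as separate ``Volume`` instances sharing one :class:`Calibration`.
    """

    values: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume expects a 3D array, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"degenerate shape {self.values.shape}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("Volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "Volume":
        return Volume(values, self.calibration)


@dataclass
class LabelVolume:
    """Integer-labelled 3D grid; 0 is background."""

    values: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("LabelVolume expects a 3D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("LabelVolume values must be integers")
        if self.values.size and self.values.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present."""
        u = np.unique(self.values)
        return u[u > 0]


class Seed(NamedTuple):
    """A detected local maximum used to initiate local segmentation."""

    position: tuple[int, int, int]
    intensity: float


def _check_radii(radii: Sequence[int]) -> tuple[int, int, int]:
    if len(radii) != 3:
        raise ValueError("radii must be a 3-tuple (rx, ry, rz)")
    out = []
    for r in radii:
        if int(r) != r or r < 0:
            raise ValueError(f"radii must be non-negative integers, got {radii}")
        out.append(int(r))
    return tuple(out)  # type: ignore[return-value]


def _clipped_median_slab(values: np.ndarray, radii, region, out, chunk_voxels=150_000):
    """Exact median over border-clipped boxes for ``region`` (a slice tuple).

    Uses a NaN-padded sliding-window view so out-of-volume positions never
    contribute; processed in chunks along x to bound memory.
    """
    rx, ry, rz = radii
    padded = np.pad(
        values.astype(np.float32),
        ((rx, rx), (ry, ry), (rz, rz)),
        constant_values=np.nan,
    )
    win = sliding_window_view(padded, (2 * rx + 1, 2 * ry + 1, 2 * rz + 1))
    sub = win[region]
    nx = sub.shape[0]
    per_x = max(1, int(np.prod(sub.shape[1:3])))
    step = max(1, chunk_voxels // per_x)
    for x0 in range(0, nx, step):
        block = sub[x0 : x0 + step]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[region][x0 : x0 + step] = np.nanmedian(block, axis=(3, 4, 5))


def median_filter_3d(vol: Volume, radii: Sequence[int]) -> Volume:
    """3D box median filter with per-axis radii and border-clipped windows.

    Each output voxel is the median of the input over the axis-aligned box of
    half-sizes ``(rx, ry, rz)`` intersected with the volume.  For clipped
    (even-count) border windows the median is the mean of the two central
    values.
    """
    rx, ry, rz = _check_radii(radii)
    v = vol.values
    if rx == ry == rz == 0:
        return vol.with_values(v.astype(np.float32))
    # Interior voxels see full windows, so the (fast) scipy filter is exact
    # there regardless of its border mode; the border shell is then redone
    # with truly clipped windows.
    out = ndimage.median_filter(
        v, size=(2 * rx + 1, 2 * ry + 1, 2 * rz + 1), mode="nearest"
    ).astype(np.float32)
    nx, ny, nz = v.shape
    slabs = []
    if rx > 0:
        slabs += [np.s_[: min(rx, nx), :, :], np.s_[max(nx - rx, 0) :, :, :]]
    if ry > 0:
        slabs += [np.s_[:, : min(ry, ny), :], np.s_[:, max(ny - ry, 0) :, :]]
    if rz > 0:
        slabs += [np.s_[:, :, : min(rz, nz)], np.s_[:, :, max(nz - rz, 0) :]]
    for sl in slabs:
        _clipped_median_slab(v, (rx, ry, rz), sl, out)
    return vol.with_values(out)


def bandpass_filter_3d(
    vol: Volume, size_min: float, size_max: float, rescale: bool = True
) -> Volume:
    """Size-selective difference-of-Gaussians enhancement.

    The pass band ``[size_min, size_max]`` is in XY voxels and is mapped onto
    the two Gaussian sigmas through the FWHM relation
    ``sigma = size / (2 * 2.355)``; the z sigma is scaled by ``dx/dz`` so the
    kernel is physically isotropic.  Negative responses are clamped to zero
    and, when ``rescale`` is true, the result is linearly mapped onto the
    16-bit range so the volume minimum lands on 0 and the maximum on 65535.
    """
    if not (0 < size_min < size_max):
        raise ValueError(f"need 0 < size_min < size_max, got {size_min}, {size_max}")
    cal = vol.calibration
    zscale = cal.dx / cal.dz
    v = vol.values.astype(np.float32)
    s_lo = size_min / (2 * FWHM_FACTOR)
    s_hi = size_max / (2 * FWHM_FACTOR)
    dog = ndimage.gaussian_filter(v, (s_lo, s_lo, s_lo * zscale)) - ndimage.gaussian_filter(
        v, (s_hi, s_hi, s_hi * zscale)
    )
    if not rescale:
        return vol.with_values(dog)
    np.maximum(dog, 0.0, out=dog)
    lo, hi = float(dog.min()), float(dog.max())
    if hi <= lo:
        warnings.warn("band-pass response is constant; returning zeros")
        return vol.with_values(np.zeros_like(dog))
    return vol.with_values((dog - lo) * (UINT16_MAX / (hi - lo)))


def distance_map_background(labels: LabelVolume) -> Volume:
    """Calibrated Euclidean distance (µm) from each background voxel to the
    nearest labelled voxel; labelled voxels hold 0.

    Anisotropy in z enters through the calibrated sampling of the distance
    transform.
    """
    lab = labels.values
    if not np.any(lab > 0):
        raise ValueError("distance map needs at least one labelled voxel")
    cal = labels.calibration
    d = ndimage.distance_transform_edt(lab == 0, sampling=(cal.dx, cal.dy, cal.dz))
    return Volume(d.astype(np.float32), cal)


def ellipsoid_offsets(radius: float, anisotropy: float) -> np.ndarray:
    """Boolean structuring element for a ball of ``radius`` XY voxels whose z
    extent is shrunk by the calibration anisotropy (dz/dx)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    rz = max(radius / anisotropy, 0.0)
    nz = int(np.floor(rz))
    rr = int(np.floor(radius))
    x, y, z = np.mgrid[-rr : rr + 1, -rr : rr + 1, -nz : nz + 1]
    return (x * x + y * y + (z * anisotropy) ** 2) <= radius * radius + 1e-9


def local_maxima_3d(vol: Volume, radius: float, threshold: float) -> list[Seed]:
    """Seeds at voxels that reach ``threshold`` and are maximal within an
    anisotropy-aware ball of ``radius`` XY voxels.

    A connected plateau of equal-valued maxima collapses to its
    lexicographically smallest (x, y, z) coordinate, so a constant volume
    yields exactly one seed (if above threshold).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    v = vol.values
    fp = ellipsoid_offsets(radius, vol.calibration.anisotropy)
    mx = ndimage.maximum_filter(v, footprint=fp, mode="constant", cval=-np.inf)
    cand = (v >= threshold) & (v >= mx)
    if not cand.any():
        return []
    comp, n = ndimage.label(cand, structure=np.ones((3, 3, 3), bool))
    coords = np.argwhere(cand)  # raster order == lexicographic in (x, y, z)
    ids = comp[tuple(coords.T)]
    _, first = np.unique(ids, return_index=True)
    picks = coords[np.sort(first)]
    order = np.lexsort((picks[:, 2], picks[:, 1], picks[:, 0]))
    return [
        Seed(tuple(int(c) for c in picks[i]), float(v[tuple(picks[i])])) for i in order
    ]
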