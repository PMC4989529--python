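"""Cube denoising and radiometric calibration.

The preprocessing chain mirrors the acquisition realities of pushbroom
hyperspectral cameras: small (≤4 px) artifacts are removed with a 3×3×3
median filter spanning spatial and spectral neighbours; the spectrally
outermost bands carry the strongest sensor noise, so an adaptive variant
grows the in-plane median mask from 3×3 at mid-band to 7×7 at the band
edges; finally raw counts are normalized between a dark (shuttered) and a
white (uniform reflectance standard) reference acquisition, producing the
calibrated cube L_C with values in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cube_io import HyperCube
from .errors import ConfigError, DimensionError

__all__ = [
    "MedianMaskSchedule",
    "median3d",
    "median3d_array",
    "adaptive_median",
    "plane_sizes",
    "calibrate",
    "standard_pipeline",
]


@dataclass(frozen=True)
class MedianMaskSchedule:
    """Band-dependent in-plane median mask sizes.

    ``edge_size`` applies at the first and last band, ``mid_size`` at the
    central band, with linear interpolation (rounded to the nearest odd
    integer) in between.  The spectral extent of the mask is fixed.
    """

    edge_size: int = 7
    mid_size: int = 3
    spectral_extent: int = 3

    def __post_init__(self) -> None:
        for name in ("edge_size", "mid_size", "spectral_extent"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ConfigError(f"{name} must be an odd integer >= 1, got {v}")
        if self.edge_size < self.mid_size:
            raise ConfigError(
                f"edge_size ({self.edge_size}) must be >= mid_size ({self.mid_size})"
            )


def _check_mask(mask, shape) -> tuple:
    mask = tuple(int(m) for m in mask)
    if len(mask) != 3:
        raise ConfigError(f"mask must be a (rows, cols, bands) triple, got {mask}")
    for m, dim in zip(mask, shape):
        if m < 1 or m % 2 == 0:
            raise ConfigError(f"mask dimensions must be odd and >= 1, got {mask}")
        if m > dim:
            raise ConfigError(f"mask {mask} exceeds cube dimensions {shape}")
    return mask


def median3d_array(values: np.ndarray, mask=(3, 3, 3)) -> np.ndarray:
    """3D median filter on a bare array with replicate (edge) padding."""
    mask = _check_mask(mask, values.shape)
    return ndimage.median_filter(values, size=mask, mode="nearest")


def median3d(cube: HyperCube, mask=(3, 3, 3)) -> HyperCube:
    """Median-filter a cube voxelwise over a ``rows × cols × bands`` mask.

    Each voxel is replaced by the median of its (replicate-padded)
    neighbourhood; with the default 3×3×3 mask this removes isolated
    artifacts up to ~4 px while leaving flat regions untouched.
    """
    return HyperCube(cube.header, median3d_array(cube.values, mask))


def plane_sizes(schedule: MedianMaskSchedule, bands: int) -> list:
    """Per-band in-plane mask sizes: edge_size at bands 0 and I−1, mid_size
    at the centre, linear in band index and rounded to the nearest odd."""
    if bands == 1:
        return [schedule.mid_size]
    center = (bands - 1) / 2.0
    sizes = []
    for i in range(bands):
        s = schedule.mid_size + (schedule.edge_size - schedule.mid_size) * abs(i - center) / center
        odd = 1 + 2 * int(round((s - 1) / 2.0))
        sizes.append(max(1, odd))
    return sizes


def adaptive_median(cube: HyperCube, schedule: MedianMaskSchedule = MedianMaskSchedule()) -> HyperCube:
    """Band-adaptive median filter: larger in-plane masks at the noisy band
    edges, smaller at mid-band; spectral extent fixed by the schedule."""
    vals = cube.values
    bands = vals.shape[2]
    half = schedule.spectral_extent // 2
    sizes = plane_sizes(schedule, bands)
    out = np.empty_like(vals)
    for i, s in enumerate(sizes):
        lo, hi = max(0, i - half), min(bands, i + half + 1)
        slab = vals[:, :, lo:hi]
        pad = (half - (i - lo), half - (hi - 1 - i))
        if any(pad):
            slab = np.pad(slab, ((0, 0), (0, 0), pad), mode="edge")
        filt = ndimage.median_filter(slab, size=(s, s, slab.shape[2]), mode="nearest")
        out[:, :, i] = filt[:, :, slab.shape[2] // 2]
    return HyperCube(cube.header, out)


def calibrate(cube: HyperCube, dark: HyperCube, white: HyperCube) -> HyperCube:
    """Dark/white normalization: ``L_C = (L − L_DARK)/(L_WHITE − L_DARK)``.

    Output is clipped to [0, 1].  Pixels where white equals dark are set to 0
    and counted in a single ``RuntimeWarning``.
    """
    if not (cube.shape == dark.shape == white.shape):
        raise DimensionError(
            f"cube/dark/white shapes differ: {cube.shape}, {dark.shape}, {white.shape}"
        )
    denom = white.values - dark.values
    bad = denom == 0
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"calibrate: {n_bad} voxels have white == dark; output set to 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (cube.values - dark.values) / denom
    out[bad] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    header = cube.header.replace(dtype_code="float32")
    return HyperCube(header, out)


def standard_pipeline(raw: HyperCube, dark: HyperCube, white: HyperCube, mask=(3, 3, 3)) -> HyperCube:
    """Median filtering followed by dark/white calibration (raw → L_C)."""
    return calibrate(median3d(raw, mask), dark, white)
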