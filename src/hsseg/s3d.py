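"""3D segmentation (S3D) over the whole spectral sequence.

The reference spectrum is taken as the per-band mean over a user-marked ROI
inside the target object.  A signed difference volume against that spectrum
is median-filtered in 3D (full 3×3×3 neighbourhood, so spectral neighbours
participate and no in-plane direction is privileged), aggregated per pixel
into a percent-scale error map

    L_S(m,n) = 100 · mean_i |L_V(m,n,i)| / mean_i L_PAT(i)

(mean absolute deviation as a percentage of the mean reference level),
smoothed with an in-plane median window, and finally thresholded *from
above*: a pixel belongs to level k when its error is at most p_rk percent.
Successive thresholds (e.g. 30, 20, 10 %) give nested acceptance regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cube_io import HyperCube
from .errors import ConfigError, DegenerateInputError
from .preprocess import median3d_array
from .spectra import ReferenceSpectrum

__all__ = [
    "RoiRect",
    "extract_pattern_from_roi",
    "difference_volume",
    "median_filter_volume",
    "aggregate_error",
    "s3d_segment",
]


@dataclass(frozen=True)
class RoiRect:
    """Rectangular ROI in 0-based, half-open coordinates."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise DegenerateInputError(f"ROI {self} is empty")
        if min(self.row_start, self.col_start) < 0:
            raise ConfigError(f"ROI {self} has negative bounds")

    def check_within(self, shape) -> None:
        if self.row_end > shape[0] or self.col_end > shape[1]:
            raise ConfigError(f"ROI {self} exceeds image shape {shape[:2]}")

    @property
    def slices(self) -> tuple:
        return (slice(self.row_start, self.row_end), slice(self.col_start, self.col_end))


def extract_pattern_from_roi(cube: HyperCube, roi: RoiRect) -> ReferenceSpectrum:
    """Per-band arithmetic mean of the cube over the ROI pixels."""
    roi.check_within(cube.shape)
    region = cube.values[roi.slices]
    values = region.reshape(-1, cube.shape[2]).mean(axis=0)
    return ReferenceSpectrum(values=values, wavelengths=cube.wavelengths)


def difference_volume(cube: HyperCube, pattern: ReferenceSpectrum) -> np.ndarray:
    """Signed per-voxel difference against the reference spectrum."""
    pattern.require_bands(cube.shape[2])
    return cube.values - pattern.values


def median_filter_volume(vol: np.ndarray) -> np.ndarray:
    """3×3×3 median filter of the difference volume (replicate padding)."""
    return median3d_array(np.asarray(vol, dtype=np.float64), (3, 3, 3))


def aggregate_error(vol: np.ndarray, pattern: ReferenceSpectrum, plane_window: int = 29) -> np.ndarray:
    """Collapse a difference volume to a percent-scale 2D error map.

    Per pixel: mean absolute deviation across bands, expressed as a percent
    of the mean reference level, then smoothed with an in-plane
    ``plane_window``-square median filter (replicate padding).
    ``plane_window=1`` disables the smoothing.  The default 29 suits
    full-size (≈700×520) frames; scale it down with the frame.
    """
    vol = np.asarray(vol, dtype=np.float64)
    level = float(np.mean(pattern.values))
    if level == 0:
        raise ConfigError("mean reference level is zero; percent scale undefined")
    if plane_window < 1 or plane_window % 2 == 0:
        raise ConfigError(f"plane_window must be odd and >= 1, got {plane_window}")
    err = 100.0 * np.mean(np.abs(vol), axis=2) / abs(level)
    if plane_window > 1:
        err = ndimage.median_filter(err, size=(plane_window, plane_window), mode="nearest")
    return err


def s3d_segment(
    cube: HyperCube,
    roi: RoiRect,
    thresholds=(30.0, 20.0, 10.0),
    *,
    plane_window: int = 29,
    volume_median: bool = True,
    return_details: bool = False,
):
    """Full S3D chain; returns a multi-level label map.

    ``thresholds`` must be strictly decreasing percentages in (0, 100).
    The returned integer map counts, per pixel, how many thresholds the
    pixel satisfies: 0 = rejected everywhere, k = accepted down to the k-th
    (stricter) threshold — so ``labels >= k`` is the binary mask at
    threshold k and the levels nest by construction.
    ``volume_median=False`` skips the 3D median stage (useful on noiseless
    data where it would only round object corners).
    """
    thresholds = [float(t) for t in thresholds]
    if any(not 0 < t < 100 for t in thresholds):
        raise ConfigError(f"thresholds must lie in (0, 100), got {thresholds}")
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigError(f"thresholds must be strictly decreasing, got {thresholds}")
    pattern = extract_pattern_from_roi(cube, roi)
    vol = difference_volume(cube, pattern)
    if volume_median:
        vol = median_filter_volume(vol)
    err = aggregate_error(vol, pattern, plane_window=plane_window)
    labels = np.zeros(err.shape, dtype=np.uint8)
    for level, t in enumerate(thresholds, start=1):
        labels[err <= t] = level
    if return_details:
        return labels, {"pattern": pattern, "volume": vol, "error": err}
    return labels
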