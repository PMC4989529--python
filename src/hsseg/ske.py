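"""Fast segmentation by emissivity-curve matching (SKE).

Each pixel's measured spectrum is compared band-by-band against a reference
emissivity curve L_PAT(i).  The chain is purely per-pixel:

1. relative difference  L_D(m,n,i) = (L(m,n,i) − L_PAT(i)) / L_PAT(i)
2. per-pixel count L_R(m,n) of bands where the tolerance p_r is exceeded
   (|L_D| ≥ p_r by default; see ``literal_rule`` below)
3. grey-level error map  L_V = 1 − |L_R| / max|L_R|  (1 = perfect match,
   0 = worst match in the image)
4. binarization: foreground = pixels with L_V ≥ threshold.

Because the on-disk BIL layout stores whole image rows contiguously, the
same chain applied to the first row(s) of a cube (``read_partial_rows``)
gives a screening segmentation after reading a tiny fraction of the file.
Note the normalization in step 3 is taken over the rows analysed: a
partial-row mask matches the corresponding rows of the full-image mask
whenever the maximal mismatch count is represented among those rows (e.g.
whenever they contain fully mismatching background).

The reference curve must live in the same radiometric space as the cube
being analysed (raw counts against raw cubes, calibrated reflectance in
[0, 1] against calibrated cubes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube_io import HyperCube
from .errors import ConfigError
from .spectra import ReferenceSpectrum

__all__ = [
    "MismatchCountMap",
    "GreyErrorMap",
    "relative_difference",
    "count_mismatches",
    "error_to_grey",
    "ske_segment",
]


@dataclass(frozen=True)
class MismatchCountMap:
    """Per-pixel count of bands whose relative difference exceeds tolerance."""

    counts: np.ndarray
    tolerance: float
    bands_used: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.min() < 0 or c.max() > self.bands_used:
            raise ConfigError(
                f"counts must lie in [0, {self.bands_used}], got "
                f"[{c.min()}, {c.max()}]"
            )
        object.__setattr__(self, "counts", c.astype(np.int64))


@dataclass(frozen=True)
class GreyErrorMap:
    """Grey-level match map in [0, 1]; 1 = perfect match, 0 = maximal error."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.min() < 0 or v.max() > 1:
            raise ConfigError("grey error map values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def relative_difference(cube: HyperCube, pattern: ReferenceSpectrum) -> np.ndarray:
    """Per-voxel relative difference against the reference curve."""
    pattern.require_bands(cube.shape[2])
    zero = np.flatnonzero(pattern.values == 0)
    if zero.size:
        raise ConfigError(
            f"reference spectrum is zero at band(s) {zero.tolist()}; "
            "relative difference is undefined there"
        )
    return (cube.values - pattern.values) / pattern.values


def count_mismatches(diff: np.ndarray, p_r: float, *, literal_rule: bool = False) -> MismatchCountMap:
    """Count, per pixel, the bands whose difference exceeds the tolerance.

    With ``literal_rule=False`` (default) a band counts when ``|L_D| >= p_r``
    — a symmetric exceedance test, so both over- and under-emission relative
    to the reference are flagged.  ``literal_rule=True`` switches to the
    one-sided signed rule ``L_D < p_r`` for cross-checking against
    implementations that count that way.
    """
    if p_r <= 0:
        raise ConfigError(f"tolerance p_r must be positive, got {p_r}")
    diff = np.asarray(diff, dtype=np.float64)
    if literal_rule:
        flags = diff < p_r
    else:
        flags = np.abs(diff) >= p_r
    counts = flags.sum(axis=2)
    return MismatchCountMap(counts=counts, tolerance=float(p_r), bands_used=diff.shape[2])


def error_to_grey(counts: MismatchCountMap) -> GreyErrorMap:
    """Normalize mismatch counts to a grey map, 1 = no mismatch.

    If no pixel mismatches anywhere, the map is all ones (zero mismatches is
    the minimum possible error).
    """
    c = np.abs(counts.counts).astype(np.float64)
    top = c.max()
    if top == 0:
        return GreyErrorMap(np.ones_like(c))
    return GreyErrorMap(1.0 - c / top)


def ske_segment(
    cube: HyperCube,
    pattern: ReferenceSpectrum,
    p_r: float = 0.1,
    bin_threshold: float = 0.6,
    *,
    literal_rule: bool = False,
    return_details: bool = False,
):
    """Full SKE chain: relative difference → mismatch counts → grey map →
    binary mask of pixels matching the reference curve.

    Accepts full cubes or the partial cubes produced by
    ``cube_io.read_partial_rows`` (the screening fast path).  Returns a 2D
    boolean mask; with ``return_details=True`` also the intermediate maps.
    """
    if not 0 < bin_threshold <= 1:
        raise ConfigError(f"bin_threshold must be in (0, 1], got {bin_threshold}")
    diff = relative_difference(cube, pattern)
    counts = count_mismatches(diff, p_r, literal_rule=literal_rule)
    grey = error_to_grey(counts)
    mask = grey.values >= bin_threshold
    if return_details:
        return mask, {"diff": diff, "counts": counts, "grey": grey}
    return mask
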