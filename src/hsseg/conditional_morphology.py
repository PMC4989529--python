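"""Conditional erosion/dilation for stabilizing per-band binary masks.

Per-band binarization of a hyperspectral sequence is unstable at the band
edges, where sensor noise adds spurious components frame to frame.  The
stabilizer gates standard morphology on a local brightness mean

    p_c(m,n,i) = mean of the normalized band i over an M_S × N_S window

and, per pixel,

* **conditional erosion**: copy the mask where ``p_c < p_dc``; elsewhere
  take the minimum of the mask over the structuring element — so spurious
  specks sitting in bright surroundings are eaten away;
* **conditional dilation**: copy the mask where ``p_c > p_ec``; elsewhere
  take the maximum over the structuring element — so holes in dark
  surroundings are filled.

With the default gates ``p_ec = p_dc = 0.5`` this combination suppresses
band-edge noise without destroying the true object, provided the object is
*dark* against a *bright* background in the normalized cube (then the
erosion branch acts on the background and the dilation branch inside the
object).  For the opposite polarity, invert the band before computing p_c.

The default 17×17 structuring element suits full-size (≈700×520) frames;
scale it with the frame, keeping it at least twice the expected noise
component size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cube_io import HyperCube
from .errors import ConfigError, DimensionError, RangeError

__all__ = [
    "MorphParams",
    "local_mean",
    "conditional_erosion",
    "conditional_dilation",
    "stabilize_stack",
]


@dataclass(frozen=True)
class MorphParams:
    """Structuring-element size (M_S × N_S) and the two gate thresholds."""

    mask_rows: int = 17
    mask_cols: int = 17
    p_ec: float = 0.5
    p_dc: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mask_rows", "mask_cols"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ConfigError(f"{name} must be an odd positive integer, got {v}")
        for name in ("p_ec", "p_dc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

    @property
    def size(self) -> tuple:
        return (self.mask_rows, self.mask_cols)


def local_mean(band: np.ndarray, params: MorphParams) -> np.ndarray:
    """Windowed mean p_c of a normalized band (replicate padding).

    The band must already be normalized to [0, 1] (calibrated reflectance,
    or raw counts divided by the full scale).
    """
    band = np.asarray(band, dtype=np.float64)
    if band.min() < -1e-9 or band.max() > 1 + 1e-9:
        raise RangeError(
            f"band values must be normalized to [0, 1]; got "
            f"[{band.min():.4g}, {band.max():.4g}]"
        )
    return ndimage.uniform_filter(band, size=params.size, mode="nearest")


def _check_pair(mask: np.ndarray, p_c: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != np.asarray(p_c).shape:
        raise DimensionError(f"mask shape {mask.shape} != p_c shape {np.asarray(p_c).shape}")
    return mask.astype(bool)


def conditional_erosion(mask: np.ndarray, p_c: np.ndarray, params: MorphParams) -> np.ndarray:
    """Erode only where the local mean is high (``p_c >= p_dc``)."""
    mask = _check_pair(mask, p_c)
    eroded = ndimage.minimum_filter(mask, size=params.size, mode="nearest")
    return np.where(np.asarray(p_c) < params.p_dc, mask, eroded)


def conditional_dilation(mask: np.ndarray, p_c: np.ndarray, params: MorphParams) -> np.ndarray:
    """Dilate only where the local mean is low (``p_c <= p_ec``)."""
    mask = _check_pair(mask, p_c)
    dilated = ndimage.maximum_filter(mask, size=params.size, mode="nearest")
    return np.where(np.asarray(p_c) > params.p_ec, mask, dilated)


def stabilize_stack(
    masks: np.ndarray,
    cube: HyperCube,
    params: MorphParams = MorphParams(),
    *,
    order=("erosion", "dilation"),
) -> np.ndarray:
    """Apply conditional erosion then dilation to every band's mask.

    ``masks`` is a boolean ``(rows, cols, bands)`` stack; ``cube`` supplies
    the normalized brightness from which each band's p_c is computed.  Bands
    are processed independently, in order.
    """
    masks = np.asarray(masks)
    if masks.shape != cube.shape:
        raise DimensionError(
            f"mask stack shape {masks.shape} != cube shape {cube.shape}"
        )
    for op in order:
        if op not in ("erosion", "dilation"):
            raise ConfigError(f"unknown operation {op!r} in order")
    out = np.empty(masks.shape, dtype=bool)
    for i in range(masks.shape[2]):
        p_c = local_mean(cube.values[:, :, i], params)
        m = masks[:, :, i].astype(bool)
        for op in order:
            if op == "erosion":
                m = conditional_erosion(m, p_c, params)
            else:
                m = conditional_dilation(m, p_c, params)
        out[:, :, i] = m
    return out
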