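"""Hierarchical segmentation (SH).

The cube is first reduced to 1/8 resolution by block-mean pooling (which
also suppresses noise), then every low-resolution pixel is described by a
small feature vector: the absolute deviations of its spectrum from the
reference curve at the curve's strongest local maxima (three by default).
The feature cloud is partitioned by k-means for K = 2..5 classes and the
class count is chosen automatically by minimizing a dispersion criterion —
by default the mean over classes of the standard error of the class mean
(per-class RMS spread about the centroid divided by √n_k).  Unlike the raw
within-class spread, this criterion *rises* when k-means needlessly splits
a coherent cluster, so it bottoms out at the natural class count.

The winning labels are upsampled to full resolution; the object class (the
cluster whose centroid is nearest the origin, i.e. best matches the
reference curve) is re-binarized band by band at full resolution, the
per-band masks are stabilized against band-edge noise with conditional
erosion/dilation, and the final mask is the per-pixel majority vote across
bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .conditional_morphology import MorphParams, stabilize_stack
from .cube_io import CubeHeader, HyperCube
from .errors import ConfigError, DegenerateInputError, DimensionError
from .s3d import RoiRect, extract_pattern_from_roi
from .spectra import ReferenceSpectrum

__all__ = [
    "FeatureStack",
    "ClusteringResult",
    "downsample_cube",
    "find_local_maxima",
    "extract_features",
    "cluster_pixels",
    "select_class_count",
    "upsample_labels",
    "sh_segment",
]

_CRITERIA = ("sem", "std", "mse")


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel mismatch features |L(m,n,i_k) − L_PAT(i_k)| at peak bands."""

    features: np.ndarray  # (rows, cols, F), non-negative
    peak_bands: tuple

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        if f.ndim != 3:
            raise DimensionError(f"features must be (rows, cols, F), got {f.shape}")
        if f.min() < 0:
            raise ConfigError("features are absolute differences and must be >= 0")
        pb = tuple(int(b) for b in self.peak_bands)
        if any(b >= a for a, b in zip(pb[1:], pb)):
            raise ConfigError(f"peak_bands must be strictly increasing, got {pb}")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "peak_bands", pb)

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    @property
    def matrix(self) -> np.ndarray:
        return self.features.reshape(-1, self.n_features)


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray  # (rows, cols) int
    K: int
    dispersion: float
    centroids: np.ndarray  # (K, F)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.max() >= self.K or lab.min() < 0:
            raise ConfigError(f"labels must lie in [0, {self.K}), got max {lab.max()}")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")


def downsample_cube(cube: HyperCube, factor: int = 8) -> HyperCube:
    """Block-mean pooling over ``factor × factor`` in-plane blocks per band.

    Trailing partial blocks are averaged over their actual extent, so any
    frame size is accepted.
    """
    if factor < 1:
        raise ConfigError(f"factor must be >= 1, got {factor}")
    rows, cols, bands = cube.shape
    if factor > min(rows, cols):
        raise ConfigError(f"factor {factor} exceeds in-plane size {rows}x{cols}")
    if factor == 1:
        return cube
    r_edges = np.arange(0, rows, factor)
    c_edges = np.arange(0, cols, factor)
    sums = np.add.reduceat(np.add.reduceat(cube.values, r_edges, axis=0), c_edges, axis=1)
    r_sizes = np.diff(np.append(r_edges, rows))
    c_sizes = np.diff(np.append(c_edges, cols))
    counts = np.outer(r_sizes, c_sizes)[:, :, None]
    vals = sums / counts
    header = CubeHeader(
        lines=len(r_edges),
        samples=len(c_edges),
        bands=bands,
        wavelengths=cube.header.wavelengths,
        dtype_code="float32",
        byte_order=cube.header.byte_order,
        interleave=cube.header.interleave,
        dynamic_range_bits=cube.header.dynamic_range_bits,
    )
    return HyperCube(header, vals)


def find_local_maxima(pattern: ReferenceSpectrum, count: int = 3) -> list:
    """Bands of the strongest interior local maxima of the reference curve.

    An interior band i qualifies when ``pattern[i−1] < pattern[i] >=
    pattern[i+1]`` (the leftmost sample of a plateau qualifies).  Maxima are
    ranked by curve value, the top ``count`` returned in ascending band
    order; if fewer exist, all are returned with a warning.
    """
    v = pattern.values
    if v.size < 3:
        raise DegenerateInputError("pattern needs at least 3 bands to have interior maxima")
    interior = np.arange(1, v.size - 1)
    is_max = (v[interior - 1] < v[interior]) & (v[interior] >= v[interior + 1])
    candidates = interior[is_max]
    if candidates.size == 0:
        raise DegenerateInputError(
            "reference curve has no interior local maximum (monotone curve?); "
            "select feature bands manually"
        )
    if candidates.size < count:
        warnings.warn(
            f"only {candidates.size} local maxima available (requested {count})",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(-v[candidates], kind="stable")
    top = candidates[order[:count]]
    return sorted(int(b) for b in top)


def extract_features(cube_small: HyperCube, pattern: ReferenceSpectrum, peak_bands) -> FeatureStack:
    """Absolute spectral deviations at the peak bands, per pixel."""
    pattern.require_bands(cube_small.shape[2])
    peak_bands = [int(b) for b in peak_bands]
    if any(not 0 <= b < cube_small.shape[2] for b in peak_bands):
        raise ConfigError(f"peak_bands {peak_bands} out of range for {cube_small.shape[2]} bands")
    feats = np.abs(cube_small.values[:, :, peak_bands] - pattern.values[peak_bands])
    return FeatureStack(features=feats, peak_bands=tuple(peak_bands))


def _dispersion(X: np.ndarray, labels: np.ndarray, centers: np.ndarray, criterion: str) -> float:
    if criterion not in _CRITERIA:
        raise ConfigError(f"criterion must be one of {_CRITERIA}, got {criterion!r}")
    vals = []
    for k in range(centers.shape[0]):
        idx = labels == k
        n_k = int(idx.sum())
        if n_k == 0:
            continue
        msd = float(np.mean(np.sum((X[idx] - centers[k]) ** 2, axis=1)))
        if criterion == "mse":
            vals.append(msd)
        elif criterion == "std":
            vals.append(np.sqrt(msd))
        else:  # sem: standard error of the class mean
            vals.append(np.sqrt(msd) / np.sqrt(n_k))
    return float(np.mean(vals))


def cluster_pixels(
    features: FeatureStack,
    K: int,
    *,
    seed: int = 0,
    n_init: int = 10,
    criterion: str = "sem",
) -> ClusteringResult:
    """Partition feature space into K classes by multi-restart k-means.

    ``dispersion`` is the class-count selection criterion evaluated on the
    fitted partition; see module docstring for the available criteria.
    """
    from sklearn.cluster import KMeans

    if not 2 <= K <= 5:
        raise ConfigError(f"K must be in [2, 5], got {K}")
    X = features.matrix
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < K:
        raise DegenerateInputError(
            f"only {n_distinct} distinct feature vectors; cannot form {K} classes"
        )
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    flat_labels = km.fit_predict(X)
    disp = _dispersion(X, flat_labels, km.cluster_centers_, criterion)
    labels = flat_labels.reshape(features.features.shape[:2])
    return ClusteringResult(labels=labels, K=K, dispersion=disp, centroids=km.cluster_centers_)


def select_class_count(
    features: FeatureStack,
    *,
    k_range=(2, 5),
    seed: int = 0,
    n_init: int = 10,
    criterion: str = "sem",
) -> ClusteringResult:
    """Cluster for each K in ``k_range`` and keep the dispersion-minimal
    result; ties break toward the smaller K."""
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if not 2 <= k_min <= k_max <= 5:
        raise ConfigError(f"k_range must satisfy 2 <= kmin <= kmax <= 5, got {k_range}")
    n_distinct = np.unique(features.matrix, axis=0).shape[0]
    k_max = min(k_max, n_distinct)
    if k_max < k_min:
        raise DegenerateInputError(
            f"only {n_distinct} distinct feature vectors; cannot form {k_min} classes"
        )
    best = None
    for K in range(k_min, k_max + 1):
        res = cluster_pixels(features, K, seed=seed, n_init=n_init, criterion=criterion)
        if best is None or res.dispersion < best.dispersion:
            best = res
    return best


def upsample_labels(labels: np.ndarray, target_shape, factor: int = 8) -> np.ndarray:
    """Nearest-neighbour (blockwise) expansion of a label map."""
    labels = np.asarray(labels)
    out = np.repeat(np.repeat(labels, factor, axis=0), factor, axis=1)
    if out.shape[0] < target_shape[0] or out.shape[1] < target_shape[1]:
        raise DimensionError(
            f"labels {labels.shape} × factor {factor} cannot cover {target_shape}"
        )
    return out[: target_shape[0], : target_shape[1]]


def _band_thresholds(
    small: HyperCube, pattern: ReferenceSpectrum, labels: np.ndarray, object_class: int, K: int
) -> np.ndarray:
    """Midpoint, per band, between the object class's mean absolute deviation
    from the reference curve and the mean deviation of all other pixels
    (one-vs-rest decision boundary)."""
    d = np.abs(small.values - pattern.values)  # (h, w, I)
    obj = labels == object_class
    mu_obj = d[obj].mean(axis=0)
    mu_rest = d[~obj].mean(axis=0)
    return (mu_obj + mu_rest) / 2.0


def sh_segment(
    cube: HyperCube,
    pattern: ReferenceSpectrum = None,
    roi: RoiRect = None,
    *,
    factor: int = 8,
    n_features: int = 3,
    k_range=(2, 5),
    seed: int = 0,
    criterion: str = "sem",
    stabilize: bool = True,
    morph: MorphParams = None,
    return_details: bool = False,
):
    """Full hierarchical chain; returns a 2D boolean object mask.

    Supply either an explicit reference spectrum or an ROI to average it
    from.  The cube should be calibrated (values in [0, 1]) so the
    conditional-morphology brightness gates are meaningful; pass
    ``stabilize=False`` to skip that stage.  ``morph`` defaults to the
    17×17 element with 0.5 gates; scale the element down for small frames.
    """
    if (pattern is None) == (roi is None):
        raise ConfigError("supply exactly one of pattern or roi")
    if pattern is None:
        pattern = extract_pattern_from_roi(cube, roi)
    pattern.require_bands(cube.shape[2])
    if morph is None:
        morph = MorphParams()

    small = downsample_cube(cube, factor)
    peaks = find_local_maxima(pattern, n_features)
    feats = extract_features(small, pattern, peaks)
    clustering = select_class_count(feats, k_range=k_range, seed=seed, criterion=criterion)

    object_class = int(np.argmin(np.linalg.norm(clustering.centroids, axis=1)))
    labels_full = upsample_labels(clustering.labels, cube.shape[:2], factor)

    taus = _band_thresholds(small, pattern, clustering.labels, object_class, clustering.K)
    stack = np.abs(cube.values - pattern.values) <= taus  # (rows, cols, bands)
    if stabilize:
        stack = stabilize_stack(stack, cube, morph)
    mask = stack.sum(axis=2) * 2 > cube.shape[2]  # majority vote across bands

    if return_details:
        return mask, {
            "pattern": pattern,
            "peak_bands": peaks,
            "clustering": clustering,
            "object_class": object_class,
            "labels_full": labels_full,
            "band_thresholds": taus,
            "stack": stack,
        }
    return mask
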