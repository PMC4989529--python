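"""Hierarchical segmentation: pooling, peak finding, clustering, class-count
selection and the composed pipeline."""

import numpy as np
import pytest

from hsseg import RoiRect, metrics, preprocess, sh, synth
from hsseg.cube_io import CubeHeader, HyperCube
from hsseg.errors import ConfigError, DegenerateInputError
from hsseg.sh import (FeatureStack, cluster_pixels, downsample_cube, extract_features,
                      find_local_maxima, select_class_count, sh_segment, upsample_labels)
from hsseg.spectra import ReferenceSpectrum

from conftest import TEST_MORPH


def cube_from(values):
    values = np.asarray(values, dtype=np.float64)
    header = CubeHeader(lines=values.shape[0], samples=values.shape[1],
                        bands=values.shape[2], dtype_code="float32")
    return HyperCube(header, values)


def spectrum(values):
    values = np.asarray(values, dtype=np.float64)
    return ReferenceSpectrum(values=values, wavelengths=np.linspace(0.4, 1.0, values.size))


def blob_features(rng, centers, n_per=80, sigma=0.01):
    """Gaussian blobs in feature space, arranged onto a pixel grid."""
    pts, labels = [], []
    for k, c in enumerate(centers):
        pts.append(rng.normal(c, sigma, size=(n_per, len(c))))
        labels += [k] * n_per
    X = np.clip(np.concatenate(pts), 0.0, None)
    labels = np.array(labels)
    perm = rng.permutation(len(X))
    X, labels = X[perm], labels[perm]
    side = int(np.sqrt(len(X)))
    X = X[: side * side]
    labels = labels[: side * side]
    feats = FeatureStack(X.reshape(side, side, -1), peak_bands=tuple(range(X.shape[1])))
    return feats, labels.reshape(side, side)


THREE_BLOBS = [[0.05, 0.05, 0.05], [0.75, 0.1, 0.1], [0.1, 0.75, 0.75]]


def best_agreement(pred, truth, K):
    """Max label agreement over all K! relabelings."""
    from itertools import permutations

    best = 0.0
    for perm in permutations(range(K)):
        mapped = np.vectorize(lambda v: perm[v])(pred)
        best = max(best, np.mean(mapped == truth))
    return best


class TestDownsample:
    def test_factor_one_is_identity(self, rng):
        cube = cube_from(rng.random((5, 5, 3)))
        assert downsample_cube(cube, 1) is cube

    def test_constant_block_mean(self):
        cube = cube_from(np.full((8, 8, 2), 0.3))
        out = downsample_cube(cube, 8)
        assert out.shape == (1, 1, 2)
        np.testing.assert_allclose(out.values, 0.3)

    def test_two_half_blocks(self):
        vals = np.zeros((16, 16, 1))
        vals[8:, :, :] = 1.0
        out = downsample_cube(cube_from(vals), 8)
        np.testing.assert_array_equal(out.values[:, :, 0], [[0, 0], [1, 1]])

    def test_partial_trailing_blocks_use_actual_extent(self):
        vals = np.ones((10, 8, 1))
        vals[8:, :, :] = 5.0  # trailing 2-row block
        out = downsample_cube(cube_from(vals), 8)
        np.testing.assert_allclose(out.values[:, :, 0], [[1.0], [5.0]])

    def test_factor_too_large(self, rng):
        with pytest.raises(ConfigError):
            downsample_cube(cube_from(rng.random((4, 4, 2))), 8)


class TestFindLocalMaxima:
    def test_simple_maxima(self):
        assert find_local_maxima(spectrum([0, 1, 0, 2, 0]), 2) == [1, 3]

    def test_ranked_then_sorted_by_band(self):
        assert find_local_maxima(spectrum([0, 3, 0, 2, 0, 1, 0]), 3) == [1, 3, 5]

    def test_plateau_takes_leftmost(self):
        assert find_local_maxima(spectrum([0, 2, 2, 0, 1, 0]), 2) == [1, 4]

    def test_monotone_pattern_rejected(self):
        with pytest.raises(DegenerateInputError, match="maximum"):
            find_local_maxima(spectrum([0.1, 0.2, 0.3, 0.4]))

    def test_fewer_maxima_warns_and_returns_all(self):
        with pytest.warns(RuntimeWarning, match="local maxima"):
            out = find_local_maxima(spectrum([0, 1, 0, 0, 0]), 3)
        assert out == [1]


class TestExtractFeatures:
    def test_matching_pixel_zero_vector(self):
        pat = np.array([0.2, 0.5, 0.3, 0.7])
        cube = cube_from(np.broadcast_to(pat, (2, 2, 4)).copy())
        feats = extract_features(cube, spectrum(pat), [1, 3])
        np.testing.assert_array_equal(feats.features, 0.0)

    def test_deviation_at_one_peak_and_sign_invariance(self):
        pat = np.array([0.2, 0.5, 0.3, 0.7])
        vals = np.broadcast_to(pat, (1, 1, 4)).copy()
        vals[0, 0, 1] += 0.2
        up = extract_features(cube_from(vals), spectrum(pat), [1, 3])
        vals[0, 0, 1] -= 0.4
        down = extract_features(cube_from(vals), spectrum(pat), [1, 3])
        np.testing.assert_allclose(up.features[0, 0], [0.2, 0.0])
        np.testing.assert_allclose(up.features, down.features)

    def test_commutes_with_downsampling_on_blockwise_constant(self, rng):
        """On blockwise-constant cubes, pooling then extracting equals
        extracting then pooling (exactly)."""
        blocks = rng.uniform(0.1, 0.9, (3, 3, 4))
        vals = np.repeat(np.repeat(blocks, 4, axis=0), 4, axis=1)
        pat = spectrum(rng.uniform(0.2, 0.8, 4))
        small = downsample_cube(cube_from(vals), 4)
        a = extract_features(small, pat, [0, 2]).features
        full = extract_features(cube_from(vals), pat, [0, 2]).features
        b = full[::4, ::4]
        np.testing.assert_allclose(a, b)


class TestClustering:
    def test_two_point_masses_perfect_split(self):
        feats = FeatureStack(
            np.array([[[0.0] * 3, [1.0] * 3]] * 4), peak_bands=(0, 1, 2))
        res = cluster_pixels(feats, 2)
        assert res.dispersion == 0.0
        assert len(np.unique(res.labels[:, 0])) == 1
        assert res.labels[0, 0] != res.labels[0, 1]

    def test_identical_vectors_degenerate(self):
        feats = FeatureStack(np.full((3, 3, 3), 0.5), peak_bands=(0, 1, 2))
        with pytest.raises(DegenerateInputError, match="distinct"):
            cluster_pixels(feats, 2)

    def test_three_blobs_recovered(self, rng):
        feats, truth = blob_features(rng, THREE_BLOBS)
        res = cluster_pixels(feats, 3, seed=0)
        assert best_agreement(res.labels, truth, 3) >= 0.99

    def test_permutation_invariance_of_partition(self, rng):
        feats, truth = blob_features(rng, THREE_BLOBS)
        res = cluster_pixels(feats, 3, seed=0)
        flat = feats.matrix
        perm = rng.permutation(flat.shape[0])
        shuffled = FeatureStack(flat[perm].reshape(feats.features.shape),
                                peak_bands=feats.peak_bands)
        res2 = cluster_pixels(shuffled, 3, seed=0)
        assert res2.dispersion == pytest.approx(res.dispersion, rel=1e-9)
        assert best_agreement(res2.labels.ravel().reshape(res.labels.shape),
                              res.labels.ravel()[perm].reshape(res.labels.shape), 3) == 1.0


class TestSelectClassCount:
    def test_three_blobs_select_three(self, rng):
        feats, _ = blob_features(rng, THREE_BLOBS)
        best = select_class_count(feats, seed=0)
        assert best.K == 3
        # direct oracle: chosen dispersion minimizes over all K
        disps = {K: cluster_pixels(feats, K, seed=0).dispersion for K in range(2, 6)}
        assert best.dispersion == min(disps.values())
        assert best.dispersion <= disps[best.K] + 1e-15

    def test_two_blobs_select_two(self, rng):
        feats, _ = blob_features(rng, [[0.05, 0.05, 0.05], [0.7, 0.7, 0.7]], n_per=120)
        assert select_class_count(feats, seed=0).K == 2


class TestUpsample:
    def test_blockwise_expansion_and_majority_roundtrip(self, rng):
        labels = rng.integers(0, 3, (2, 2))
        up = upsample_labels(labels, (16, 16), 8)
        assert up.shape == (16, 16)
        np.testing.assert_array_equal(up[::8, ::8], labels)
        # every 8x8 block is constant, so decimation == majority
        np.testing.assert_array_equal(up[4::8, 4::8], labels)

    def test_factor_one_identity(self, rng):
        labels = rng.integers(0, 4, (3, 5))
        np.testing.assert_array_equal(upsample_labels(labels, (3, 5), 1), labels)


class TestShSegment:
    def test_zero_noise_exact_recovery(self, noiseless_phantom, noiseless_calibrated):
        ph = noiseless_phantom
        mask = sh_segment(noiseless_calibrated, pattern=ph.spectra[1],
                          morph=TEST_MORPH, stabilize=False, seed=0)
        np.testing.assert_array_equal(mask, ph.truth == 1)

    def test_phantom_recovery(self, default_phantom, calibrated_cube):
        ph = default_phantom
        mask = sh_segment(calibrated_cube, pattern=ph.spectra[1],
                          morph=TEST_MORPH, seed=0)
        assert metrics.balanced_accuracy(mask, ph.truth == 1) >= 95.0

    def test_roi_variant_matches_pattern_variant_closely(self, default_phantom, calibrated_cube):
        ph = default_phantom
        m_roi = sh_segment(calibrated_cube, roi=RoiRect(40, 56, 40, 56),
                           morph=TEST_MORPH, seed=0)
        assert metrics.balanced_accuracy(m_roi, ph.truth == 1) >= 95.0

    def test_stabilization_improves_noisy_band_masks(self):
        """Heavy band-edge noise: stabilized per-band masks beat raw ones."""
        spec = synth.PhantomSpec(seed=7, noise_sigma_mid=0.03, noise_edge_gain=6.0,
                                 artifact_count=0)
        ph = synth.render_phantom(spec)
        cal = preprocess.calibrate(ph.raw, ph.dark, ph.white)
        truth = ph.truth == 1
        _, with_stab = sh_segment(cal, pattern=ph.spectra[1], morph=TEST_MORPH,
                                  stabilize=True, seed=0, return_details=True)
        _, without = sh_segment(cal, pattern=ph.spectra[1], morph=TEST_MORPH,
                                stabilize=False, seed=0, return_details=True)
        acc = lambda stack: np.mean([
            metrics.balanced_accuracy(stack[:, :, i], truth)
            for i in range(stack.shape[2])
        ])
        assert acc(with_stab["stack"]) >= acc(without["stack"])

    def test_requires_exactly_one_reference(self, calibrated_cube, default_phantom):
        with pytest.raises(ConfigError):
            sh_segment(calibrated_cube)
        with pytest.raises(ConfigError):
            sh_segment(calibrated_cube, pattern=default_phantom.spectra[1],
                       roi=RoiRect(0, 2, 0, 2))
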