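"""Texture matrices vs brute-force oracles, partition invariants, and the
70-feature panel."""

import itertools

import numpy as np
import pytest

import oracles
from pcgstack import glcm, gldm, glrlm, glszm, quantize, texture_features
from pcgstack.errors import InvalidConfigError, InvalidInputError
from pcgstack.texture import (DIRECTIONS, FEATURE_NAMES, QuantizedImage,
                              compute_all_matrices, extract_texture_features,
                              feature_vector)


def all_binary_3x3():
    for bits in itertools.product((1, 2), repeat=9):
        yield QuantizedImage(np.array(bits).reshape(3, 3), 2)


class TestQuantize:
    def test_constant_image_all_level_one(self):
        q = quantize(np.full((3, 3), 0.7), 8)
        assert np.all(q.levels == 1)

    def test_linear_ramp_equal_occupancy(self):
        ramp = np.linspace(0.0, 1.0, 4 * 7).reshape(4, 7)
        q = quantize(ramp, 4)
        assert np.array_equal(np.bincount(q.levels.ravel())[1:], [7, 7, 7, 7])

    def test_extremes_map_to_extreme_levels(self):
        rng = np.random.default_rng(0)
        img = rng.random((10, 10))
        q = quantize(img, 16)
        assert q.levels[np.unravel_index(img.argmin(), img.shape)] == 1
        assert q.levels[np.unravel_index(img.argmax(), img.shape)] == 16


class TestMatrixExamples:
    def test_glcm_uniform_image(self):
        q = QuantizedImage(np.ones((2, 2), dtype=int), 1)
        P = glcm(q, (1, 0))
        assert P[0, 0] == 1.0

    def test_glcm_asymmetric_column_pattern(self):
        q = QuantizedImage(np.array([[1, 2], [1, 2]]), 2)
        P = glcm(q, (1, 0), symmetric=False)
        assert P[0, 1] == 1.0 and P.sum() == 1.0

    def test_glcm_offset_too_large(self):
        q = QuantizedImage(np.ones((2, 2), dtype=int), 1)
        with pytest.raises(InvalidInputError):
            glcm(q, (5, 0))

    def test_glrlm_single_run(self):
        q = QuantizedImage(np.array([[1, 1, 1, 1]]), 1)
        P = glrlm(q, 0)
        assert P[0, 3] == 1.0 and P.sum() == 1.0

    def test_glrlm_two_runs(self):
        q = QuantizedImage(np.array([[1, 1, 2, 2]]), 2)
        P = glrlm(q, 0)
        assert P[0, 1] == 1.0 and P[1, 1] == 1.0 and P.sum() == 2.0

    def test_glszm_constant_image(self):
        q = QuantizedImage(np.full((3, 3), 2, dtype=int), 2)
        P = glszm(q)
        assert P[1, 8] == 1.0 and P.sum() == 1.0

    def test_glszm_checkerboard_diagonal_connectivity(self):
        q = QuantizedImage(np.array([[1, 2], [2, 1]]), 2)
        P = glszm(q)
        assert P[0, 1] == 1.0 and P[1, 1] == 1.0

    def test_gldm_constant_3x3(self):
        q = QuantizedImage(np.ones((3, 3), dtype=int), 1)
        P = gldm(q, delta=0, distance=1)
        assert P[0, 3] == 4 and P[0, 5] == 4 and P[0, 8] == 1

    def test_gldm_saturated_delta_equals_constant_case(self):
        rng = np.random.default_rng(3)
        q = QuantizedImage(rng.integers(1, 5, size=(6, 7)), 4)
        const = QuantizedImage(np.ones((6, 7), dtype=int), 4)
        left = gldm(q, delta=3, distance=1)  # delta >= ng - 1
        right = gldm(const, delta=0, distance=1)
        assert np.array_equal(left.sum(axis=0), right.sum(axis=0))


class TestOracleEquivalence:
    """Matrix builders vs independent brute-force enumeration."""

    def test_all_binary_3x3_images(self):
        for q in all_binary_3x3():
            lv = q.levels
            for deg, off in DIRECTIONS.items():
                assert np.allclose(glcm(q, off, symmetric=True),
                                   oracles.glcm_brute(lv, 2, off, True))
                got_r = glrlm(q, deg)
                exp_r = oracles.glrlm_brute(lv, 2, off)
                assert np.allclose(got_r[:, :exp_r.shape[1]], exp_r)
            got_z = glszm(q)
            exp_z = oracles.glszm_brute(lv, 2)
            assert np.allclose(got_z[:, :exp_z.shape[1]], exp_z)
            assert np.allclose(gldm(q, 0, 1), oracles.gldm_brute(lv, 2, 0, 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_16x16_images(self, seed):
        rng = np.random.default_rng(seed)
        q = QuantizedImage(rng.integers(1, 5, size=(16, 16)), 4)
        for deg, off in DIRECTIONS.items():
            assert np.allclose(glcm(q, off), oracles.glcm_brute(q.levels, 4, off))
            got = glrlm(q, deg)
            exp = oracles.glrlm_brute(q.levels, 4, off)
            assert np.allclose(got[:, :exp.shape[1]], exp)
        exp_z = oracles.glszm_brute(q.levels, 4)
        assert np.allclose(glszm(q)[:, :exp_z.shape[1]], exp_z)
        assert np.allclose(gldm(q, 1, 1), oracles.gldm_brute(q.levels, 4, 1, 1))


class TestPartitionInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_counts_partition_pixels(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = QuantizedImage(rng.integers(1, 9, size=(12, 15)), 8)
        n = q.levels.size
        P = glcm(q, (1, 0))
        assert abs(P.sum() - 1.0) < 1e-12
        for deg in DIRECTIONS:
            R = glrlm(q, deg)
            lengths = np.arange(1, R.shape[1] + 1)
            assert np.isclose((R * lengths).sum(), n)
        Z = glszm(q)
        sizes = np.arange(1, Z.shape[1] + 1)
        assert np.isclose((Z * sizes).sum(), n)
        D = gldm(q, 0, 1)
        assert np.isclose(D.sum(), n)


class TestFeaturePanel:
    def test_exactly_70_features_in_stable_order(self):
        rng = np.random.default_rng(0)
        f = extract_texture_features(rng.random((16, 16)), ng=8)
        assert len(f) == 70
        assert list(f.keys()) == FEATURE_NAMES[:24] + FEATURE_NAMES[24:]
        assert len(FEATURE_NAMES) == 70
        groups = [n.split("_")[0] for n in FEATURE_NAMES]
        assert (groups.count("glcm"), groups.count("glrlm"),
                groups.count("glszm"), groups.count("gldm")) == (24, 16, 16, 14)

    def test_constant_image_zero_joint_entropy(self):
        f = extract_texture_features(np.ones((8, 8)))
        assert f["glcm_joint_entropy"] == 0.0

    def test_all_features_finite_on_random_images(self, random_quantized_images):
        for q in random_quantized_images[:30]:
            f = texture_features(compute_all_matrices(q))
            v = feature_vector(f)
            assert np.all(np.isfinite(v))

    def test_direction_averaged_features_rotation_invariant(self):
        """Averaging GLCM/GLRLM features over the four directions makes them
        invariant to a 90-degree rotation of the image."""
        rng = np.random.default_rng(5)
        img = rng.random((20, 20))
        f0 = extract_texture_features(img, ng=8)
        f90 = extract_texture_features(np.rot90(img), ng=8)
        for name in FEATURE_NAMES[:40]:  # glcm + glrlm
            assert np.isclose(f0[name], f90[name], rtol=1e-9), name

    def test_degenerate_matrices_yield_finite_features(self):
        f = texture_features(compute_all_matrices(
            QuantizedImage(np.ones((4, 4), dtype=int), 32)))
        assert np.all(np.isfinite(feature_vector(f)))
        assert f["glcm_correlation"] == 0.0  # zero-variance convention

    def test_invalid_ng_rejected(self):
        with pytest.raises(InvalidConfigError):
            quantize(np.ones((3, 3)), 1)


def test_glcm_matches_skimage_crosscheck():
    """Independent library cross-check on asymmetric unnormalized counts."""
    from skimage.feature import graycomatrix

    rng = np.random.default_rng(8)
    lv = rng.integers(1, 5, size=(10, 10))
    q = QuantizedImage(lv, 4)
    ours = glcm(q, (1, 0), symmetric=False, normalize=False)
    sk = graycomatrix(lv - 1, [1], [0], levels=4)[:, :, 0, 0]
    assert np.array_equal(ours, sk)
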