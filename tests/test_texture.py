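"""Co-occurrence matrices and Haralick statistics.

The GLCM implementation is checked exactly against an exhaustive
brute-force pair-counting oracle (all configured 2D and 3D displacements)
and against skimage's reference implementation where conventions overlap.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from conftest import brute_force_glcm
from skimage.feature import graycomatrix, graycoprops

from dualifc.registry import HARALICK_NAMES
from dualifc.texture import (
    ANGLE_VECTORS_2D,
    BACKGROUND,
    DIRECTIONS_3D,
    EmptyGLCMError,
    TextureConfig,
    average_texture,
    glcm,
    haralick,
    quantize,
    zscore_columns,
)


class TestGLCMOracle:
    def test_2d_matches_brute_force_on_random_masked_images(self, rng):
        """Vectorized GLCM == exhaustive pair counting, all 16 2D configs."""
        config = TextureConfig(n_levels=8)
        for _ in range(50):
            img = rng.integers(0, 8, (8, 8))
            mask = rng.random((8, 8)) > 0.2
            mask[4, 4] = True  # keep at least one foreground pixel
            levels = np.where(mask, img, BACKGROUND)
            for disp in config.displacements_2d():
                try:
                    ours = glcm(levels, disp, 8)
                except EmptyGLCMError:
                    continue
                expected = brute_force_glcm(levels, disp, 8)
                np.testing.assert_array_equal(ours, expected)

    def test_3d_matches_brute_force_on_random_volumes(self, rng):
        """Vectorized GLCM == exhaustive pair counting, all 52 3D configs."""
        config = TextureConfig(n_levels=4)
        assert len(config.displacements_3d()) == 52
        for _ in range(20):
            vol = rng.integers(0, 4, (6, 6, 6))
            mask = rng.random((6, 6, 6)) > 0.15
            mask[3, 3, 3] = True
            levels = np.where(mask, vol, BACKGROUND)
            for disp in config.displacements_3d():
                try:
                    ours = glcm(levels, disp, 4)
                except EmptyGLCMError:
                    continue
                expected = brute_force_glcm(levels, disp, 4)
                np.testing.assert_array_equal(ours, expected)

    def test_matches_skimage_reference(self, rng):
        """Unmasked 2D GLCMs equal skimage's graycomatrix.

        skimage's 45/135 degree displacements are mirrored w.r.t. ours;
        the four-angle set is identical, so angles map pairwise. Diagonal
        angles are compared at d=1 only: skimage rounds diagonal offsets to
        Euclidean distance, whereas ours step d pixels along the direction.
        """
        angle_map = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        img = rng.integers(0, 16, (12, 12)).astype(np.uint8)
        levels = img.astype(np.int64)
        for ang, vec in ANGLE_VECTORS_2D.items():
            for d in (1, 2, 3, 4) if ang in (0, 90) else (1,):
                sk = graycomatrix(
                    img, [d], [angle_map[ang]], levels=16, symmetric=True, normed=True
                )[:, :, 0, 0]
                ours = glcm(levels, (d * vec[0], d * vec[1]), 16)
                np.testing.assert_allclose(ours, sk, atol=1e-12)


class TestGLCMProperties:
    def test_normalized_and_symmetric(self, rng):
        levels = rng.integers(0, 8, (10, 10))
        P = glcm(levels, (0, 1), 8)
        assert np.isclose(P.sum(), 1.0)
        np.testing.assert_allclose(P, P.T)

    def test_pair_example(self):
        """[[0,1],[0,1]] at displacement (0,1): P(0,1) = P(1,0) = 0.5."""
        levels = np.array([[0, 1], [0, 1]])
        P = glcm(levels, (0, 1), 2)
        np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_image_is_single_entry(self):
        P = glcm(np.zeros((4, 4), dtype=int), (0, 1), 4)
        assert P[0, 0] == 1.0

    def test_empty_pairs_raise(self):
        levels = np.full((4, 4), BACKGROUND)
        levels[0, 0] = 1
        with pytest.raises(EmptyGLCMError):
            glcm(levels, (0, 1), 4)

    def test_directions_3d_cover_half_neighborhood(self):
        assert len(DIRECTIONS_3D) == 13
        as_set = set(DIRECTIONS_3D)
        for v in as_set:
            assert tuple(-c for c in v) not in as_set


class TestHaralick:
    def test_constant_image_closed_forms(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        h = haralick(P)
        assert h["energy"] == 1.0
        assert h["entropy"] == 0.0
        assert h["homogeneity"] == 1.0
        assert h["max_probability"] == 1.0
        assert h["contrast"] == 0.0
        assert h["correlation"] == 1.0  # degenerate convention

    def test_checkerboard_closed_forms(self):
        """2x2 checkerboard at d=1, 0 deg: energy/homogeneity/maxp 0.5, entropy 1 bit."""
        levels = np.array([[0, 1], [0, 1]])
        h = haralick(glcm(levels, (0, 1), 2))
        assert h["energy"] == pytest.approx(0.5)
        assert h["entropy"] == pytest.approx(1.0)
        assert h["homogeneity"] == pytest.approx(0.5)
        assert h["max_probability"] == pytest.approx(0.5)

    def test_returns_all_13_statistics(self, rng):
        levels = rng.integers(0, 8, (10, 10))
        h = haralick(glcm(levels, (0, 1), 8))
        assert tuple(h) == HARALICK_NAMES

    def test_agrees_with_skimage_props(self, rng):
        """contrast/correlation/ASM match graycoprops to 1e-6."""
        img = rng.integers(0, 32, (20, 20)).astype(np.uint8)
        sk = graycomatrix(img, [1], [0.0], levels=32, symmetric=True, normed=True)
        ours = haralick(sk[:, :, 0, 0])
        assert ours["contrast"] == pytest.approx(graycoprops(sk, "contrast")[0, 0], abs=1e-6)
        assert ours["correlation"] == pytest.approx(graycoprops(sk, "correlation")[0, 0], abs=1e-6)
        assert ours["energy"] == pytest.approx(graycoprops(sk, "ASM")[0, 0], abs=1e-6)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_on_random_glcms(self, seed):
        """energy in (0,1], entropy in [0, 2 log2 L]."""
        r = np.random.default_rng(seed)
        L = 8
        levels = r.integers(0, L, (9, 9))
        h = haralick(glcm(levels, (1, 1), L))
        assert 0 < h["energy"] <= 1
        assert 0 <= h["entropy"] <= 2 * np.log2(L)
        assert 0 < h["homogeneity"] <= 1
        assert 0 < h["max_probability"] <= 1


class TestQuantize:
    def test_constant_region_is_level_zero(self):
        img = np.full((5, 5), 3.7)
        levels = quantize(img, np.ones((5, 5), bool), 8)
        assert set(np.unique(levels)) == {0}

    def test_linear_ramp_fills_bins_evenly(self):
        vals = np.linspace(0, 1, 64).reshape(8, 8)
        levels = quantize(vals, np.ones((8, 8), bool), 4)
        counts = np.bincount(levels.ravel(), minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_background_gets_sentinel(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        mask = img > 7
        levels = quantize(img, mask, 4)
        assert (levels[~mask] == BACKGROUND).all()
        assert (levels[mask] >= 0).all()

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.ones((3, 3)), np.ones((3, 3), bool), 1)


class TestAverageTexture:
    def test_isotropic_constant_image(self):
        img = np.ones((12, 12))
        out = average_texture(img, np.ones((12, 12), bool), ndim=2)
        assert out["energy"] == pytest.approx(1.0)
        assert out["entropy"] == pytest.approx(0.0)

    def test_2d_average_invariant_under_90_degree_rotation(self, rng):
        """The 4-angle set is closed under 90-degree rotation."""
        img = rng.random((16, 16))
        mask = np.ones((16, 16), bool)
        a = average_texture(img, mask, ndim=2)
        b = average_texture(np.rot90(img), np.rot90(mask), ndim=2)
        for name in HARALICK_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_3d_uses_52_glcms(self):
        config = TextureConfig()
        assert len(config.displacements_3d()) == 13 * 4


class TestZScore:
    def test_column_123(self):
        """(r - mean)/sigma with population sigma: [1,2,3] -> +-1.2247."""
        out, mean, sigma = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.224745, 0.0, 1.224745], atol=1e-6)
        assert mean[0] == 2.0
        assert sigma[0] == pytest.approx(0.816497, abs=1e-6)

    def test_zero_mean_unit_sigma(self, rng):
        out, _, _ = zscore_columns(rng.random((50, 7)))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1, atol=1e-9)

    def test_constant_column_maps_to_zero_with_warning(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning):
            out, _, _ = zscore_columns(x)
        assert (out[:, 0] == 0).all()
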