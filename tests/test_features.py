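"""Color, GLCM, Gabor and DT-CWT feature extraction from ROI patches."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from skinspeckle import (
    ColorFeatures,
    DTCWTFeatures,
    GaborFeatures,
    GLCMFeatures,
    color_features,
    contrast_con,
    dtcwt_features,
    extract_features,
    gabor_features,
    glcm_features,
    gray_convert,
)
from skinspeckle.features import FAMILY_LENGTHS

from ._oracles import glcm_stats_bruteforce


@pytest.mark.parametrize(
    "extractor, family",
    [
        (color_features, "color"),
        (glcm_features, "glcm"),
        (gabor_features, "gabor"),
        (dtcwt_features, "dtcwt"),
    ],
)
def test_feature_length_contract(extractor, family, patch_pair):
    """Fixed family lengths 6/8/108/12 with matching names, finite values."""
    for patch in patch_pair:
        fv = extractor(patch)
        assert len(fv) == FAMILY_LENGTHS[family]
        assert len(fv.names) == len(fv.values)
        assert np.all(np.isfinite(fv.values))


def test_features_are_deterministic(patch_pair):
    ss, _ = patch_pair
    for extractor in (color_features, glcm_features, gabor_features, dtcwt_features):
        a = extractor(ss).values
        b = extractor(ss).values
        np.testing.assert_array_equal(a, b)


class TestColorFeatures:
    def test_constant_patch_means_and_zero_sd(self):
        patch = np.zeros((65, 65, 3), dtype=np.uint8)
        patch[:, :, 0], patch[:, :, 1], patch[:, :, 2] = 100, 50, 25
        fv = color_features(patch)
        np.testing.assert_allclose(fv.values, [100, 50, 25, 0, 0, 0])

    def test_checkerboard_two_point_distribution(self):
        """0/255 checkerboard in one channel: mean 127.5, population SD 127.5."""
        patch = np.zeros((64, 64, 3), dtype=np.uint8)
        checker = np.indices((64, 64)).sum(axis=0) % 2
        patch[:, :, 1] = checker * 255
        fv = color_features(patch)
        named = dict(zip(fv.names, fv.values))
        assert named["mean_G"] == pytest.approx(127.5)
        assert named["sd_G"] == pytest.approx(127.5)


class TestGLCMFeatures:
    def test_constant_patch_degenerate_matrix(self, constant_patch):
        named = dict(zip(*[glcm_features(constant_patch).names, glcm_features(constant_patch).values]))
        assert named["asm_mean"] == pytest.approx(1.0)
        assert named["ent_mean"] == pytest.approx(0.0)
        assert named["ine_mean"] == pytest.approx(0.0)
        assert named["cor_mean"] == 0.0  # zero-variance convention
        assert all(named[k] == pytest.approx(0.0) for k in ("asm_sd", "ent_sd", "ine_sd", "cor_sd"))

    def test_toy_image_matches_pair_counting_oracle(self):
        """4x4 two-level image: stats equal explicit pair enumeration."""
        toy = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [0, 1, 1, 0], [1, 1, 0, 0]], dtype=np.uint8
        )
        patch = np.repeat((toy * 255)[:, :, None], 3, axis=2).astype(np.uint8)
        extractor = GLCMFeatures(levels=2)
        values = extractor.fit([patch]).transform([patch])[0]
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees
        per_dir = np.array([glcm_stats_bruteforce(toy, 2, off) for off in offsets])
        expected = np.empty(8)
        expected[0::2] = per_dir.mean(axis=0)
        expected[1::2] = per_dir.std(axis=0)
        np.testing.assert_allclose(values, expected, rtol=1e-12, atol=1e-12)

    def test_matches_skimage_graycoprops_on_random_patch(self, rng):
        """Independent route: skimage property code on the same matrices."""
        patch = rng.integers(0, 256, (65, 65, 3), dtype=np.uint8).astype(np.uint8)
        named = dict(zip(*[glcm_features(patch).names, glcm_features(patch).values]))
        gray = gray_convert(patch)
        q = np.clip(np.floor(gray * 32 / 256), 0, 31).astype(np.uint8)
        mats = graycomatrix(
            q, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4], levels=32,
            symmetric=True, normed=True,
        )
        assert named["asm_mean"] == pytest.approx(graycoprops(mats, "ASM")[0].mean(), rel=1e-10)
        assert named["ine_mean"] == pytest.approx(graycoprops(mats, "contrast")[0].mean(), rel=1e-10)
        assert named["cor_mean"] == pytest.approx(graycoprops(mats, "correlation")[0].mean(), rel=1e-10)


class TestGaborFeatures:
    def test_constant_patch_uniform_dc_response(self, constant_patch):
        """Translation invariance: all 9 blocks identical on a constant input."""
        values = gabor_features(constant_patch).values.reshape(12, 9)
        for filter_blocks in values:
            np.testing.assert_allclose(filter_blocks, filter_blocks[0], atol=1e-10)

    def test_rotating_the_patch_permutes_orientations(self):
        """90-degree rotation maps the 0-degree response onto the 90-degree one."""
        x = np.arange(66)
        grating = (127.5 + 127.5 * np.sin(2 * np.pi * x / 11.0)).astype(np.uint8)
        patch = np.repeat(np.repeat(grating[None, :, None], 66, axis=0), 3, axis=2)
        rotated = np.rot90(patch, axes=(0, 1)).copy()
        f_orig = gabor_features(patch).values.reshape(3, 4, 9)
        f_rot = gabor_features(rotated).values.reshape(3, 4, 9)
        for scale in range(3):
            np.testing.assert_allclose(
                np.sort(f_rot[scale, 0]), np.sort(f_orig[scale, 2]), rtol=1e-6
            )

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            gabor_features(np.zeros((8, 8, 3), dtype=np.uint8))


class TestDTCWTFeatures:
    def test_constant_patch_all_zero(self, constant_patch):
        """Highpass subbands vanish on constants."""
        np.testing.assert_allclose(dtcwt_features(constant_patch).values, 0.0, atol=1e-12)

    def test_white_noise_strictly_positive_and_finite(self, rng):
        patch = rng.integers(0, 256, (65, 65, 3), dtype=np.uint8).astype(np.uint8)
        values = dtcwt_features(patch).values
        assert np.all(values > 0)
        assert np.all(np.isfinite(values))

    def test_diagonal_grating_prefers_matching_diagonal_subband(self):
        """+45 and -45 gratings excite opposite diagonal subband groups."""
        idx = np.indices((64, 64)).astype(float)
        plus = (127.5 + 127.5 * np.sin(2 * np.pi * (idx[0] + idx[1]) / 8)).astype(np.uint8)
        minus = (127.5 + 127.5 * np.sin(2 * np.pi * (idx[0] - idx[1]) / 8)).astype(np.uint8)
        fp = dtcwt_features(np.repeat(plus[:, :, None], 3, axis=2)).values.reshape(6, 2).sum(axis=1)
        fm = dtcwt_features(np.repeat(minus[:, :, None], 3, axis=2)).values.reshape(6, 2).sum(axis=1)
        # subband order: +15, +45, +75, -75, -45, -15
        assert fp[1] / fm[1] > 2 or fm[1] / fp[1] > 2
        assert (fp[1] > fp[4]) != (fm[1] > fm[4])

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            dtcwt_features(np.zeros((12, 12, 3), dtype=np.uint8))


class TestContrastCon:
    def test_identical_patches_zero(self, constant_patch):
        assert contrast_con(constant_patch, constant_patch) == 0.0

    def test_constructed_gray_difference(self):
        ss = np.full((65, 65, 3), 130, dtype=np.uint8)
        is_ = np.full((65, 65, 3), 100, dtype=np.uint8)
        assert contrast_con(ss, is_) == pytest.approx(30.0)

    def test_antisymmetry(self, patch_pair):
        ss, is_ = patch_pair
        assert contrast_con(ss, is_) == pytest.approx(-contrast_con(is_, ss), rel=1e-12)


def test_combined_families_concatenate(patch_pair):
    ss, _ = patch_pair
    fv = extract_features(ss, ("color", "glcm"))
    assert fv.family == "combined"
    assert len(fv) == FAMILY_LENGTHS["color"] + FAMILY_LENGTHS["glcm"]
    with pytest.raises(ValueError):
        extract_features(ss, ("color", "fractal"))
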