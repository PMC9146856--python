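"""GLCM, contrast, calibration and R/G scorer tests, with two independent
oracles: a brute-force pair enumeration for small images, and
skimage.feature.graycomatrix on full rectangular masks."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import grey_frame, level_value
from cequal.frame import Frame, full_fov
from cequal.frame_scoring import (
    GlcmParams,
    calibrate_from_contrasts,
    classify_bubbles,
    classify_cleanliness,
    compute_glcm,
    glcm_contrast,
    quantize_grey,
    rg_ratio,
    score_frame,
)
from cequal.synthetic import FrameSpec, render_frame

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_brute_force(levels, mask, n_levels, orientations, distance, symmetric):
    """Independent pair-enumeration oracle (plain Python loops)."""
    counts = np.zeros((n_levels, n_levels))
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for angle in orientations:
                dr, dc = _OFFSETS[angle]
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    counts[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


class TestComputeGlcm:
    def test_constant_image_single_diagonal_cell(self, glcm_params):
        frame = grey_frame(np.full((16, 16), 100))
        m = compute_glcm(frame, glcm_params)
        k = quantize_grey(frame.rgb, glcm_params.n_levels)[0, 0]
        assert m.p[k, k] == 1.0
        assert m.p.sum() == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        # grey columns [0, 255; 0, 255]: two horizontal pairs, plus transpose
        frame = grey_frame(np.array([[0, 255], [0, 255]]))
        params = GlcmParams(n_levels=2, distance=1, orientations=(0,), symmetric=True)
        m = compute_glcm(frame, params)
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)
        assert m.p[0, 0] == m.p[1, 1] == 0.0

    def test_normalisation_and_symmetry_on_random_frames(self, glcm_params):
        rng = np.random.default_rng(0)
        for _ in range(20):
            frame = Frame.from_array(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))
            m = compute_glcm(frame, glcm_params)
            assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(m.p, m.p.T)
            assert (m.p >= 0).all()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        h=st.integers(2, 8),
        w=st.integers(2, 8),
        n_levels=st.sampled_from([2, 4, 8]),
        distance=st.integers(1, 2),
        symmetric=st.booleans(),
    )
    def test_matches_brute_force_oracle_on_small_images(
        self, seed, h, w, n_levels, distance, symmetric
    ):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, n_levels, (h, w))
        values = np.vectorize(lambda k: level_value(k, n_levels))(levels)
        mask = rng.uniform(size=(h, w)) < 0.8
        frame = Frame(
            rgb=np.stack([values] * 3, axis=-1).astype(np.uint8), fov=mask
        )
        params = GlcmParams(
            n_levels=n_levels,
            distance=distance,
            orientations=(0, 45, 90, 135),
            symmetric=symmetric,
        )
        try:
            ours = compute_glcm(frame, params).p
        except ValueError:
            return  # degenerate mask: fewer than 2 interior pairs
        expected = glcm_brute_force(
            levels, mask, n_levels, (0, 45, 90, 135), distance, symmetric
        )
        np.testing.assert_allclose(ours, expected, atol=1e-12)

    def test_matches_skimage_on_full_mask(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(7)
        n_levels = 16
        levels = rng.integers(0, n_levels, (24, 24))
        values = np.vectorize(lambda k: level_value(k, n_levels))(levels)
        frame = Frame(
            rgb=np.stack([values] * 3, axis=-1).astype(np.uint8),
            fov=full_fov(24, 24),
        )
        ours = compute_glcm(frame, GlcmParams(n_levels=n_levels)).p
        ref = graycomatrix(
            levels.astype(np.uint8),
            distances=[1],
            angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=n_levels,
            symmetric=True,
        )[:, :, 0, :].sum(axis=-1).astype(float)
        np.testing.assert_allclose(ours, ref / ref.sum(), atol=1e-12)

    def test_degenerate_mask_raises(self, glcm_params):
        frame = Frame(
            rgb=np.zeros((8, 8, 3), dtype=np.uint8), fov=np.zeros((8, 8), bool)
        )
        with pytest.raises(ValueError, match="degenerate field of view"):
            compute_glcm(frame, glcm_params)


class TestContrast:
    def test_diagonal_matrix_has_zero_contrast(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        assert glcm_contrast(p) == 0.0

    def test_off_diagonal_hand_value(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        assert glcm_contrast(p) == pytest.approx(1.0)

    def test_checkerboard_extreme_levels(self):
        n_levels = 32
        board = np.indices((4, 4)).sum(axis=0) % 2
        frame = grey_frame(np.where(board, 255, 0))
        params = GlcmParams(n_levels=n_levels, orientations=(0, 90))
        m = compute_glcm(frame, params)
        assert glcm_contrast(m) == pytest.approx((n_levels - 1) ** 2)

    def test_checkerboard_contrast_monotone_in_level_separation(self):
        n_levels = 32
        board = np.indices((8, 8)).sum(axis=0) % 2
        params = GlcmParams(n_levels=n_levels, orientations=(0, 90))
        previous = -1.0
        for sep in range(1, n_levels):
            values = np.where(board, level_value(sep, n_levels), level_value(0, n_levels))
            c = glcm_contrast(compute_glcm(grey_frame(values), params))
            assert c > previous
            previous = c

    def test_whole_bin_offset_invariance(self, glcm_params):
        rng = np.random.default_rng(3)
        bin_width = 256 // glcm_params.n_levels
        # mid-bin values, so the shifted image lands mid-bin too
        values = (
            rng.integers(0, glcm_params.n_levels - 2, (32, 32)) * bin_width
            + bin_width // 2
        ).astype(np.uint8)
        base = glcm_contrast(compute_glcm(grey_frame(values), glcm_params))
        shifted = glcm_contrast(
            compute_glcm(grey_frame(values + bin_width), glcm_params)
        )
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_unnormalised_matrix_rejected(self):
        with pytest.raises(ValueError, match="not normalised"):
            glcm_contrast(np.ones((4, 4)))


class TestRgRatio:
    def _uniform(self, r, g, b=50):
        rgb = np.zeros((32, 32, 3), dtype=np.uint8)
        rgb[..., 0], rgb[..., 1], rgb[..., 2] = r, g, b
        return Frame.from_array(rgb, full_fov(32, 32))

    def test_boundary_ratio_is_exact_and_inadequate(self):
        frame = self._uniform(160, 100)
        assert rg_ratio(frame) == pytest.approx(1.6, abs=0)
        assert classify_cleanliness(frame) == "inadequate"  # strict > 1.6

    @pytest.mark.parametrize(
        "r,g,expected_ratio,expected_class",
        [(200, 100, 2.0, "adequate"), (100, 200, 0.5, "inadequate")],
    )
    def test_uniform_ratios(self, r, g, expected_ratio, expected_class):
        frame = self._uniform(r, g)
        assert rg_ratio(frame) == pytest.approx(expected_ratio)
        assert classify_cleanliness(frame) == expected_class

    def test_all_black_fov_is_undefined(self):
        frame = self._uniform(0, 0, 0)
        with pytest.raises(ValueError, match="undefined ratio"):
            rg_ratio(frame)


class TestCalibration:
    def test_perfect_separation(self):
        res = calibrate_from_contrasts([1, 2, 10, 11], [False, False, True, True])
        assert res.sensitivity == res.specificity == 1.0
        assert 2 < res.tau < 10

    def test_identical_distributions_have_no_youden(self):
        contrasts = [1, 2, 3, 4, 1, 2, 3, 4]
        labels = [False] * 4 + [True] * 4
        res = calibrate_from_contrasts(contrasts, labels)
        assert res.youden == pytest.approx(0.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            calibrate_from_contrasts([1.0, 2.0], [True, True])

    def test_synthetic_calibration_separates_classes(self, calibration):
        # 500 frames, coverage ~ U[0, 0.3]: scorer must separate the 10% criterion
        assert calibration.sensitivity >= 0.95
        assert calibration.specificity >= 0.95


class TestClassification:
    def test_planted_extremes_classified_correctly(self, calibration):
        high = render_frame(FrameSpec(true_bubble_coverage=0.30, seed=21))
        none = render_frame(FrameSpec(true_bubble_coverage=0.0, seed=22))
        assert classify_bubbles(high, tau=calibration.tau) == "abundant"
        assert classify_bubbles(none, tau=calibration.tau) == "scarce"

    def test_boundary_coverage_ground_truth_is_abundant(self):
        # the criterion is ">= 10% of the image surface": 0.10 itself counts
        from cequal.synthetic import ABUNDANT_COVERAGE

        assert FrameSpec(true_bubble_coverage=0.10).true_bubble_coverage >= ABUNDANT_COVERAGE

    def test_score_frame_fields_consistent(self, calibration):
        frame = render_frame(FrameSpec(true_bubble_coverage=0.2, rg_balance=2.0, seed=30))
        s = score_frame(frame, tau=calibration.tau)
        assert s.contrast >= 0
        assert s.bubble_class == ("abundant" if s.contrast >= calibration.tau else "scarce")
        assert s.cleanliness_class == ("adequate" if s.rg_ratio > 1.6 else "inadequate")

    def test_held_out_balanced_accuracy(self, calibration):
        from cequal.pipeline import calibration_set

        specs, labels = calibration_set(999_331, n=1000)
        pred = np.array(
            [
                glcm_contrast(compute_glcm(render_frame(s))) >= calibration.tau
                for s in specs
            ]
        )
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        assert (sens + spec) / 2 >= 0.95
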