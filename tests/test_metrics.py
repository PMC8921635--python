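"""Similarity and quality metrics: identities, closed forms, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contourpro import (
    ContourImage,
    RandomConvExtractor,
    deep_feature_similarity,
    fid,
    hamming_distance,
    psnr,
    qscore,
    qscore_ratio,
    scan_windows,
    sharpness,
    ssim,
)
from contourpro.errors import ShapeMismatchError
from contourpro.metrics import PSNR_CAP, QSCORE_EQUAL
from scipy import ndimage


def _blur(img, sigma=2.0):
    return ContourImage(
        np.clip(ndimage.gaussian_filter(img.pixels, (sigma, sigma, 0)), 0, 1)
        .astype(np.float32))


def _sharpen(img, amount=1.5):
    soft = ndimage.gaussian_filter(img.pixels, (1.0, 1.0, 0))
    return ContourImage(np.clip(img.pixels + amount * (img.pixels - soft), 0, 1)
                        .astype(np.float32))


class TestSharpness:
    def test_constant_image_zero(self, const_image):
        assert sharpness(const_image) == 0.0

    def test_blur_reduces_sharpness(self, peak_image):
        assert sharpness(_blur(peak_image)) < sharpness(peak_image)

    def test_checkerboard_sharper_than_gradient(self):
        idx = np.indices((32, 32)).sum(axis=0)
        checker = ContourImage(((idx % 2).astype(np.float32))[:, :, None])
        grad = ContourImage(np.tile(np.linspace(0, 1, 32, dtype=np.float32), (32, 1))
                            [:, :, None])
        assert sharpness(checker) > sharpness(grad)


class TestQScore:
    def test_identical_batches_score_the_reference_value(self, peak_image):
        batch = [peak_image] * 4
        assert qscore(batch, batch) == pytest.approx(QSCORE_EQUAL, abs=1e-9)

    def test_blurred_batch_below_reference(self, peak_image):
        assert qscore([_blur(peak_image)], [peak_image]) < QSCORE_EQUAL

    def test_sharpened_batch_above_reference(self, peak_image):
        assert qscore([_sharpen(peak_image)], [peak_image]) > QSCORE_EQUAL

    def test_directional(self, peak_image):
        b = _blur(peak_image)
        assert qscore([b], [peak_image]) != qscore([peak_image], [b])

    def test_zero_source_sharpness_errors(self, const_image, peak_image):
        with pytest.raises(ZeroDivisionError):
            qscore([peak_image], [const_image])

    def test_monotone_in_synth_sharpness(self, peak_image):
        vals = [qscore([_blur(peak_image, s)], [peak_image]) for s in (3.0, 1.5, 0.5)]
        assert vals[0] < vals[1] < vals[2]


class TestQScoreRatio:
    def test_identical_images_zero(self, peak_image):
        assert qscore_ratio(peak_image, peak_image) == pytest.approx(0.0, abs=1e-9)

    def test_constant_other_is_one(self, peak_image, const_image):
        assert qscore_ratio(peak_image, const_image) == pytest.approx(1.0)

    def test_sharper_other_negative(self, peak_image):
        assert qscore_ratio(peak_image, _sharpen(peak_image)) < 0.0

    def test_zero_reference_errors(self, const_image, peak_image):
        with pytest.raises(ZeroDivisionError):
            qscore_ratio(const_image, peak_image)


class TestPSNR:
    def test_identical_capped(self, peak_image):
        assert psnr(peak_image, peak_image) == PSNR_CAP

    def test_closed_form_20db(self):
        a = ContourImage(np.zeros((16, 16, 1), np.float32))
        b = ContourImage(np.full((16, 16, 1), 0.1, np.float32))
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-6)

    def test_opposite_extremes_zero_db(self):
        a = ContourImage(np.zeros((16, 16, 1), np.float32))
        b = ContourImage(np.ones((16, 16, 1), np.float32))
        assert psnr(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_shape_mismatch(self, peak_image, const_image):
        with pytest.raises(ShapeMismatchError):
            psnr(peak_image, const_image)


class TestSSIM:
    def test_identity(self, peak_image):
        assert ssim(peak_image, peak_image) == pytest.approx(1.0)

    def test_symmetry(self, peak_image):
        other = _blur(peak_image)
        assert ssim(peak_image, other) == pytest.approx(ssim(other, peak_image))

    def test_inverted_structured_image_negative(self, peak_image):
        inv = ContourImage(1.0 - peak_image.pixels)
        assert ssim(peak_image, inv) < 0.0

    def test_too_small_rejected(self):
        tiny = ContourImage(np.zeros((8, 8, 1), np.float32))
        with pytest.raises(ValueError):
            ssim(tiny, tiny)


class TestHamming:
    def test_identity_zero(self, peak_image):
        assert hamming_distance(peak_image, peak_image) == 0.0

    def test_inversion_flips_all_bits(self, peak_image):
        inv = ContourImage(1.0 - peak_image.pixels)
        assert hamming_distance(peak_image, inv) == pytest.approx(1.0)

    def test_bounded(self, peak_image, const_image):
        rng = np.random.default_rng(0)
        other = ContourImage(rng.random(peak_image.shape).astype(np.float32))
        assert 0.0 <= hamming_distance(peak_image, other) <= 1.0


class TestFID:
    def test_identity_within_tolerance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 6))
        assert fid(x, x) <= 1e-6

    def test_1d_closed_form_on_sample_moments(self):
        """FID with 1-D features equals (mu diff)^2 + (sd_a - sd_b)^2."""
        a = np.array([[-1.0], [1.0]])          # mean 0, var 2
        b = np.array([[2.0], [4.0], [3.0]])    # mean 3, var 1
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        expected = 9.0 + va + vb - 2 * np.sqrt(va * vb)
        assert fid(a, b) == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_matches_closed_form(self):
        """Large samples from shifted Gaussians approach the population value."""
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, size=(20000, 1))
        b = rng.normal(1.0, 1.0, size=(20000, 1))
        assert fid(a, b) == pytest.approx(1.0, abs=0.08)

    def test_nonnegative_and_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(30, 4)), rng.normal(1.0, 2.0, size=(25, 4))
        assert fid(a, b) >= 0.0
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-6)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            fid(np.zeros((5, 3)), np.zeros((5, 4)))


class TestDeepFeatureSimilarity:
    def test_identity_is_one(self, peak_image):
        win = peak_image.pixels[:, :32]
        assert deep_feature_similarity(win, win) == pytest.approx(1.0)

    def test_zero_feature_norm_gives_zero(self):
        z = np.zeros((32, 16, 3), np.float32)
        assert deep_feature_similarity(z, z) == 0.0

    def test_small_perturbation_scores_higher_than_noise(self, peak_image):
        rng = np.random.default_rng(0)
        win = peak_image.pixels[:, :48]
        near = np.clip(win + rng.normal(0, 0.02, win.shape), 0, 1).astype(np.float32)
        noise = rng.random(win.shape).astype(np.float32)
        assert deep_feature_similarity(win, near) > deep_feature_similarity(win, noise)

    def test_extractor_deterministic(self, peak_image):
        ext = RandomConvExtractor(seed=1)
        f1, f2 = ext(peak_image), ext(peak_image)
        assert np.array_equal(f1, f2)


class TestScanWindows:
    def test_window_count_arithmetic(self, study_fixture):
        a = study_fixture.dataset_a.groups["A"][0]
        scores = scan_windows(a, a, window_width=32, stride=32)
        assert len(scores) == (256 - 32) // 32 + 1 == 8

    def test_identical_inputs_score_identity(self, peak_image):
        scores = scan_windows(peak_image, peak_image, window_width=24, stride=24)
        assert all(s.score == pytest.approx(1.0) for s in scores)

    def test_window_wider_than_image_rejected(self, peak_image):
        with pytest.raises(ValueError):
            scan_windows(peak_image, peak_image, window_width=4096)

    def test_coverage_and_bounds(self, peak_image):
        scores = scan_windows(peak_image, peak_image, window_width=20, stride=10)
        assert scores[0].x_start == 0
        assert all(s.x_end <= peak_image.width for s in scores)
        covered = set()
        for s in scores:
            covered.update(range(s.x_start, s.x_end))
        assert covered == set(range(scores[-1].x_end))

    @pytest.mark.parametrize("metric", ["ssim", "psnr", "hamming"])
    def test_alternative_metrics_run(self, peak_image, metric):
        other = _blur(peak_image)
        scores = scan_windows(peak_image, other, window_width=24, stride=24,
                              metric=metric)
        assert len(scores) == 4
        assert all(np.isfinite(s.score) for s in scores)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.data())
def test_auroc_property_matches_pair_counting(data):
    """Rank-based AUROC equals brute-force pair counting with tie half-credit."""
    from contourpro import auroc

    n = data.draw(st.integers(4, 60))
    labels = data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)))
    scores = data.draw(st.lists(
        st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n))
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    brute = np.mean([[1.0 if p > q else 0.5 if p == q else 0.0 for q in neg]
                     for p in pos])
    assert auroc(scores, labels) == pytest.approx(float(brute), abs=1e-9)
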