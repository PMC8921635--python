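"""Image-quality and similarity metrics.

Covers the full metric toolbox of the pipeline: Laplacian-variance
sharpness and the qScore / qScore-ratio derived from it, PSNR, SSIM,
average-hash Hamming distance, the Fréchet distance between feature-set
Gaussians (FID), deep-feature window similarity, and the sliding-window
scan that compares two group AFRCs along the first retention-time axis.

On qScore scalarization: "sigmoid of the Laplacian" applied to an image
yields an image, not a number, so the scalar used throughout is the
standard variance-of-Laplacian blur statistic.  qScore maps the log-ratio
of synthesized-to-source mean sharpness through a sigmoid offset so that
equal sharpness scores exactly 0.18 (the calibrated reference value);
values below 0.18 mean the synthesized batch is blurrier than its source,
above 0.18 sharper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import convolve
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .errors import ShapeMismatchError
from .image import ContourImage

__all__ = [
    "sharpness",
    "qscore",
    "qscore_ratio",
    "psnr",
    "ssim",
    "average_hash",
    "hamming_distance",
    "fid",
    "FeatureExtractor",
    "RandomConvExtractor",
    "deep_feature_similarity",
    "WindowScore",
    "scan_windows",
    "PSNR_CAP",
    "QSCORE_EQUAL",
]

PSNR_CAP = 100.0
QSCORE_EQUAL = 0.18
# Sigmoid offset calibrated so equal mean sharpness gives exactly 0.18.
_QSCORE_OFFSET = float(np.log(0.82 / 0.18))

_LAPLACIAN_3X3 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def _as_image(img: ContourImage | np.ndarray) -> ContourImage:
    return img if isinstance(img, ContourImage) else ContourImage(np.asarray(img))


def sharpness(img: ContourImage | np.ndarray) -> float:
    """Variance of the 3×3 Laplacian of the luma plane (0 for constants)."""
    lum = _as_image(img).luma().astype(np.float64)
    lap = convolve(lum, _LAPLACIAN_3X3, mode="reflect")
    return float(lap.var())


def _mean_sharpness(batch: Sequence[ContourImage | np.ndarray]) -> float:
    if not batch:
        raise ValueError("image batch must be non-empty")
    return float(np.mean([sharpness(im) for im in batch]))


def qscore(
    synth: Sequence[ContourImage | np.ndarray],
    source: Sequence[ContourImage | np.ndarray],
) -> float:
    """Sharpness of a synthesized batch relative to its source batch, in (0, 1).

    qscore = sigmoid(ln(S_synth / S_source) - ln(0.82/0.18)); equal mean
    sharpness gives exactly 0.18.  Directional: swapping the arguments
    changes the value.
    """
    s_synth = _mean_sharpness(synth)
    s_source = _mean_sharpness(source)
    if s_source <= 0.0:
        raise ZeroDivisionError("source batch has zero sharpness; qScore undefined")
    if s_synth <= 0.0:
        return 0.0
    x = np.log(s_synth / s_source) - _QSCORE_OFFSET
    return float(1.0 / (1.0 + np.exp(-x)))


def qscore_ratio(high_res: ContourImage | np.ndarray, other: ContourImage | np.ndarray) -> float:
    """Relative sharpness deficit of ``other`` versus the high-res reference.

    (S_hr - S_other) / S_hr: 0 for equal sharpness, 1 when ``other`` is
    featureless, negative when ``other`` is the sharper image.
    """
    s_hr = sharpness(high_res)
    if s_hr <= 0.0:
        raise ZeroDivisionError("high-resolution image has zero sharpness")
    return float((s_hr - sharpness(other)) / s_hr)


def psnr(a: ContourImage | np.ndarray, b: ContourImage | np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on the [0, 1] scale, capped at 100."""
    pa, pb = _as_image(a).pixels, _as_image(b).pixels
    if pa.shape != pb.shape:
        raise ShapeMismatchError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    mse = float(np.mean((pa.astype(np.float64) - pb.astype(np.float64)) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return min(PSNR_CAP, float(10.0 * np.log10(1.0 / mse)))


def ssim(a: ContourImage | np.ndarray, b: ContourImage | np.ndarray) -> float:
    """Mean structural similarity (11×11 Gaussian window, σ=1.5, L=1)."""
    ia, ib = _as_image(a), _as_image(b)
    if ia.shape != ib.shape:
        raise ShapeMismatchError(f"shape mismatch: {ia.shape} vs {ib.shape}")
    if min(ia.height, ia.width) < 11:
        raise ValueError("SSIM requires images of at least 11×11")
    return float(
        structural_similarity(
            ia.pixels,
            ib.pixels,
            channel_axis=2,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def average_hash(img: ContourImage | np.ndarray, hash_size: int = 8) -> np.ndarray:
    """Mean-threshold perceptual hash of the luma plane (hash_size² bits)."""
    lum = _as_image(img).luma()
    small = resize(lum, (hash_size, hash_size), order=1, anti_aliasing=True,
                   preserve_range=True)
    return (small > small.mean()).ravel()


def hamming_distance(a: ContourImage | np.ndarray, b: ContourImage | np.ndarray) -> float:
    """Normalized Hamming distance between 64-bit average hashes, in [0, 1]."""
    ha, hb = average_hash(a), average_hash(b)
    return float(np.mean(ha != hb))


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, clipping negatives."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Fréchet distance between Gaussian fits of two feature sets.

    ||μa−μb||² + Tr(Σa + Σb − 2(ΣaΣb)^{1/2}); the cross term is computed
    as Tr((√Σa Σb √Σa)^{1/2}) so only symmetric eigendecompositions are
    needed, with negative eigenvalues clipped at zero.  Always ≥ 0 up to
    numerical tolerance.
    """
    fa = np.asarray(features_a, dtype=np.float64)
    fb = np.asarray(features_b, dtype=np.float64)
    if fa.ndim != 2 or fb.ndim != 2 or fa.shape[1] != fb.shape[1]:
        raise ShapeMismatchError(
            f"feature sets must be 2-D with common dimension, got {fa.shape} vs {fb.shape}"
        )
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("each feature set needs at least 2 vectors")
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    cov_a = np.cov(fa, rowvar=False)
    cov_b = np.cov(fb, rowvar=False)
    cov_a = np.atleast_2d(cov_a)
    cov_b = np.atleast_2d(cov_b)
    sqrt_a = _psd_sqrt(cov_a)
    cross = _psd_sqrt(sqrt_a @ cov_b @ sqrt_a)
    val = float(mu_a @ mu_a - 2 * mu_a @ mu_b + mu_b @ mu_b
                + np.trace(cov_a) + np.trace(cov_b) - 2.0 * np.trace(cross))
    return max(val, 0.0)


@dataclass
class FeatureExtractor:
    """Pluggable window → fixed-length feature-vector transform."""

    name: str
    transform: Callable[[np.ndarray], np.ndarray]
    deterministic: bool = True

    def __call__(self, window: ContourImage | np.ndarray) -> np.ndarray:
        arr = np.asarray(window.pixels if isinstance(window, ContourImage) else window,
                         dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        return np.asarray(self.transform(arr), dtype=np.float64).ravel()


class RandomConvExtractor(FeatureExtractor):
    """Fixed-seed random convolutional embedding.

    Windows are resized to a small square, filtered by a bank of random
    3×3 convolutions (fixed by ``seed``), rectified and average-pooled on
    a coarse grid.  Random convolutional features are a standard cheap
    image embedding; the extractor is deterministic, so similarity scores
    are reproducible, and it is pluggable so a pretrained CNN can be
    substituted when its weights are available.
    """

    def __init__(self, seed: int = 0, n_filters: int = 24, patch: int = 32, grid: int = 4):
        rng = np.random.default_rng(seed)
        filters = rng.normal(0.0, 1.0, size=(n_filters, 3, 3, 3)).astype(np.float32)
        filters -= filters.mean(axis=(1, 2, 3), keepdims=True)

        def transform(arr: np.ndarray) -> np.ndarray:
            if arr.shape[2] == 1:
                arr = np.repeat(arr, 3, axis=2)
            small = resize(arr, (patch, patch, 3), order=1, anti_aliasing=True,
                           preserve_range=True).astype(np.float32)
            feats = np.empty((n_filters, grid, grid), dtype=np.float32)
            responses = np.stack(
                [sum(convolve(small[:, :, c], filters[f, :, :, c], mode="reflect")
                     for c in range(3)) for f in range(n_filters)]
            )
            responses = np.maximum(responses, 0.0)
            step = patch // grid
            for gy in range(grid):
                for gx in range(grid):
                    feats[:, gy, gx] = responses[
                        :, gy * step:(gy + 1) * step, gx * step:(gx + 1) * step
                    ].mean(axis=(1, 2))
            return feats.ravel()

        super().__init__(name=f"randconv(seed={seed})", transform=transform, deterministic=True)


def default_extractor() -> RandomConvExtractor:
    return RandomConvExtractor(seed=0)


def deep_feature_similarity(
    win_a: ContourImage | np.ndarray,
    win_b: ContourImage | np.ndarray,
    extractor: FeatureExtractor | None = None,
) -> float:
    """Cosine similarity of extractor features; 0 when either norm is zero."""
    extractor = extractor or default_extractor()
    fa, fb = extractor(win_a), extractor(win_b)
    if fa.shape != fb.shape:
        raise ShapeMismatchError("feature vectors differ in length")
    na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(fa @ fb / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class WindowScore:
    """Similarity score of one full-height strip [x_start, x_end)."""

    x_start: int
    x_end: int
    score: float
    metric_name: str

    def __post_init__(self):
        if not (0 <= self.x_start < self.x_end):
            raise ValueError("require 0 <= x_start < x_end")


def scan_windows(
    afrc_a: ContourImage,
    afrc_b: ContourImage,
    window_width: int | None = None,
    stride: int | None = None,
    metric: str | Callable[[np.ndarray, np.ndarray], float] = "deep",
    extractor: FeatureExtractor | None = None,
) -> list[WindowScore]:
    """Score full-height strips of two AFRCs along the first retention axis.

    Windows start at x = 0, stride, 2·stride, … giving
    floor((W − window_width)/stride) + 1 windows.  Defaults: width W/16,
    stride = width (a non-overlapping tiling).  Higher scores mean more
    similar; the ROI selector looks for the least similar windows.
    """
    if afrc_a.shape != afrc_b.shape:
        raise ShapeMismatchError(f"AFRC shapes differ: {afrc_a.shape} vs {afrc_b.shape}")
    w = afrc_a.width
    if window_width is None:
        window_width = max(w // 16, 1)
    if stride is None:
        stride = window_width
    if window_width > w:
        raise ValueError(f"window width {window_width} exceeds image width {w}")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    if callable(metric):
        score_fn = metric
        metric_name = getattr(metric, "__name__", "custom")
    elif metric in ("deep", "vgg", "cosine"):
        extractor = extractor or default_extractor()

        def score_fn(a, b):
            return deep_feature_similarity(a, b, extractor)

        metric_name = extractor.name
    elif metric == "ssim":
        score_fn, metric_name = ssim, "ssim"
    elif metric == "psnr":
        score_fn, metric_name = psnr, "psnr"
    elif metric == "hamming":
        # similarity orientation: higher = more similar
        def score_fn(a, b):
            return 1.0 - hamming_distance(a, b)

        metric_name = "1-hamming"
    elif metric == "fid":
        ext = extractor or default_extractor()

        def score_fn(a, b):
            # negative distance so that higher = more similar, like the rest
            cols_a = np.stack([ext(a[:, j::4]) for j in range(4)])
            cols_b = np.stack([ext(b[:, j::4]) for j in range(4)])
            return -fid(cols_a, cols_b)

        metric_name = "neg-fid"
    else:
        raise ValueError(f"unknown metric {metric!r}")

    scores = []
    for x in range(0, w - window_width + 1, stride):
        wa = afrc_a.pixels[:, x:x + window_width]
        wb = afrc_b.pixels[:, x:x + window_width]
        scores.append(
            WindowScore(x_start=x, x_end=x + window_width,
                        score=float(score_fn(wa, wb)), metric_name=metric_name)
        )
    return scores
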