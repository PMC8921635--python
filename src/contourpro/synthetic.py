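"""Synthetic GC×GC–TOFMS contour-image generator.

Real contour exports are colormapped renderings of a peak field: each
metabolite appears as a roughly Gaussian blob whose (x, y) position encodes
its two retention times and whose color encodes ion intensity.  Runs differ
by small unpredictable retention-time shifts, detector noise, and a
column-bleed streak of late-eluting stationary-phase signal along the
bottom of the plot.  This module emulates exactly those image-level
statistics with controllable group differences, providing both test
fixtures with a known ground truth (planted marker windows) and the
simulated high-quality contour-like dataset used to train the
super-resolution network.

It does not attempt physical chromatographic simulation (mass spectra,
modulation phase); only what the downstream image pipeline can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .image import ContourImage, ContourDataset

__all__ = [
    "PeakSpec",
    "GroupSpec",
    "StudyFixture",
    "contour_colormap",
    "render_intensity",
    "render_contour",
    "generate_group_dataset",
    "generate_two_group_study",
    "generate_sr_training_pairs",
]


@dataclass(frozen=True)
class PeakSpec:
    """One anisotropic Gaussian peak in fractional image coordinates."""

    x_center: float
    y_center: float
    amplitude: float
    sigma_x: float = 0.02
    sigma_y: float = 0.02

    def __post_init__(self):
        if not (0.0 <= self.x_center <= 1.0 and 0.0 <= self.y_center <= 1.0):
            raise ValueError("peak centers must lie in [0, 1]")
        if not (0.0 < self.sigma_x <= 0.5 and 0.0 < self.sigma_y <= 0.5):
            raise ValueError("peak sigmas must lie in (0, 0.5]")
        if self.amplitude < 0.0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class GroupSpec:
    """Peak inventory of one study group.

    ``base_peaks`` are shared across groups (the common metabolome);
    ``marker_peaks`` are unique to this group (e.g. the sugar-alcohol
    signature of a disease group).  ``bleed_level`` 0.3 mimics a low-bleed
    run, 0.8 a high-bleed run.
    """

    label: str
    base_peaks: list[PeakSpec] = field(default_factory=list)
    marker_peaks: list[PeakSpec] = field(default_factory=list)
    bleed_level: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.bleed_level <= 1.0):
            raise ValueError("bleed_level must lie in [0, 1]")

    @property
    def peaks(self) -> list[PeakSpec]:
        return list(self.base_peaks) + list(self.marker_peaks)


@dataclass
class StudyFixture:
    """Two-group study with known marker locations (the ROI ground truth)."""

    dataset_a: ContourDataset
    dataset_b: ContourDataset
    planted_windows: list[tuple[int, int]]

    def __post_init__(self):
        spans = sorted(self.planted_windows)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("planted windows must be pairwise disjoint")


_LUT_ANCHORS = [
    (0.00, (0.05, 0.05, 0.45)),  # deep blue background
    (0.25, (0.00, 0.35, 0.95)),
    (0.50, (0.00, 0.80, 0.20)),  # green
    (0.75, (0.95, 0.90, 0.05)),  # yellow
    (1.00, (0.90, 0.05, 0.05)),  # red
]


def contour_colormap() -> np.ndarray:
    """Fixed 256-entry blue→green→yellow→red lookup table, shape (256, 3)."""
    pos = np.array([p for p, _ in _LUT_ANCHORS])
    cols = np.array([c for _, c in _LUT_ANCHORS])
    x = np.linspace(0.0, 1.0, 256)
    lut = np.stack([np.interp(x, pos, cols[:, i]) for i in range(3)], axis=1)
    return lut.astype(np.float32)


_LUT = contour_colormap()


def render_intensity(
    group: GroupSpec,
    size: tuple[int, int],
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render the scalar intensity field (H×W in [0, 1]) before colormapping.

    Each peak center is perturbed by a uniform shift of up to
    ``jitter`` × (image extent) on both axes, modelling run-to-run
    retention-time drift.  The bleed band occupies the bottom H/8 rows with
    a Gaussian falloff upward.
    """
    h, w = size
    rng = rng or np.random.default_rng(0)
    yy = np.arange(h, dtype=np.float32)[:, None]
    xx = np.arange(w, dtype=np.float32)[None, :]
    field_ = np.zeros((h, w), dtype=np.float32)
    for peak in group.peaks:
        dx = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
        dy = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
        cx = (peak.x_center + dx) * (w - 1)
        cy = (peak.y_center + dy) * (h - 1)
        sx = max(peak.sigma_x * w, 1e-3)
        sy = max(peak.sigma_y * h, 1e-3)
        field_ += peak.amplitude * np.exp(
            -((xx - cx) ** 2) / (2 * sx**2) - ((yy - cy) ** 2) / (2 * sy**2)
        )
    if group.bleed_level > 0:
        band_h = max(h // 8, 1)
        y0 = h - band_h
        falloff = np.exp(-0.5 * ((y0 - yy) / (band_h / 2.0)) ** 2)
        falloff[int(y0):] = 1.0
        field_ += group.bleed_level * falloff * np.ones_like(xx)
    return np.clip(field_, 0.0, 1.0)


def render_contour(
    group: GroupSpec,
    size: tuple[int, int] = (256, 256),
    jitter: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ContourImage:
    """Render one colormapped contour image; deterministic given ``seed``."""
    h, w = size
    if h < 64 or w < 64:
        raise ValueError(f"size must be at least 64×64, got {size}")
    if not (0.0 <= jitter <= 0.05):
        raise ValueError("jitter must lie in [0, 0.05]")
    if not (0.0 <= noise_sd <= 0.2):
        raise ValueError("noise_sd must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    field_ = render_intensity(group, size, jitter=jitter, rng=rng)
    idx = np.clip(np.round(field_ * 255.0), 0, 255).astype(np.intp)
    rgb = _LUT[idx]
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape).astype(np.float32)
    return ContourImage(np.clip(rgb, 0.0, 1.0).astype(np.float32))


def generate_group_dataset(
    group: GroupSpec,
    n: int,
    size: tuple[int, int] = (256, 256),
    jitter: float = 0.01,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> ContourDataset:
    """Render ``n`` replicate contours of one group (per-image seed ``seed+i``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    images = [
        render_contour(group, size=size, jitter=jitter, noise_sd=noise_sd, seed=seed + i)
        for i in range(n)
    ]
    return ContourDataset({group.label: images})


def _random_base_peaks(rng: np.random.Generator, n_peaks: int = 14) -> list[PeakSpec]:
    """Shared metabolome: scattered peaks away from the bleed band."""
    peaks = []
    for _ in range(n_peaks):
        peaks.append(
            PeakSpec(
                x_center=float(rng.uniform(0.05, 0.95)),
                y_center=float(rng.uniform(0.08, 0.75)),
                amplitude=float(rng.uniform(0.35, 0.9)),
                sigma_x=float(rng.uniform(0.012, 0.03)),
                sigma_y=float(rng.uniform(0.012, 0.03)),
            )
        )
    return peaks


def generate_two_group_study(
    n_per_group: int = 15,
    k_markers: int = 3,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    marker_amplitude: float = 0.8,
    window_width: int | None = None,
    jitter: float = 0.01,
    noise_sd: float = 0.02,
    bleed_level: float = 0.3,
) -> StudyFixture:
    """Build a two-group study with ``k_markers`` planted marker windows.

    Both groups share the same base peak field; group B additionally
    carries ``k_markers`` marker peaks placed at the centers of disjoint
    full-height windows of width ``window_width`` (default W/16, the
    default scan tiling), so the x-extent of each marker defines a planted
    window the ROI scanner should recover.  ``marker_amplitude = 0`` is the
    negative control: the groups are then statistically identical.
    """
    h, w = size
    if window_width is None:
        window_width = w // 16
    if k_markers < 1:
        raise ValueError("k_markers must be >= 1")
    if k_markers * window_width > w // 2:
        raise ValueError(
            f"{k_markers} markers of width {window_width}px overcrowd a {w}px image"
        )
    rng = np.random.default_rng(seed)
    base = _random_base_peaks(rng)
    n_tiles = w // window_width
    # evenly spaced tiles, avoiding the image edges
    tile_ids = np.linspace(1, n_tiles - 2, k_markers).round().astype(int)
    if len(set(tile_ids.tolist())) < k_markers:
        raise ValueError("markers cannot be placed in disjoint windows")
    planted, markers = [], []
    for t in tile_ids:
        x0, x1 = int(t) * window_width, (int(t) + 1) * window_width
        planted.append((x0, x1))
        markers.append(
            PeakSpec(
                x_center=(x0 + x1) / 2.0 / w,
                y_center=float(rng.uniform(0.2, 0.6)),
                amplitude=marker_amplitude,
                sigma_x=window_width / (8.0 * w),
                sigma_y=float(rng.uniform(0.02, 0.04)),
            )
        )
    group_a = GroupSpec(label="A", base_peaks=base, bleed_level=bleed_level)
    group_b = GroupSpec(
        label="B",
        base_peaks=base,
        marker_peaks=[m for m in markers if m.amplitude > 0],
        bleed_level=bleed_level,
    )
    ds_a = generate_group_dataset(
        group_a, n_per_group, size=size, jitter=jitter, noise_sd=noise_sd, seed=seed + 1000
    )
    ds_b = generate_group_dataset(
        group_b, n_per_group, size=size, jitter=jitter, noise_sd=noise_sd, seed=seed + 2000
    )
    return StudyFixture(dataset_a=ds_a, dataset_b=ds_b, planted_windows=planted)


def generate_sr_training_pairs(
    n: int,
    size: tuple[int, int] = (128, 128),
    scale: int = 2,
    seed: int = 0,
) -> list[tuple[ContourImage, ContourImage]]:
    """Simulated (high-res, low-res) contour pairs for super-resolution training.

    Each high-resolution image is a fresh random peak field; the
    low-resolution partner is its bicubic downsample by ``scale``.
    """
    if scale not in (2, 4):
        raise ValueError("scale must be 2 or 4")
    h, w = size
    if h % scale or w % scale:
        raise ValueError(f"size {size} not divisible by scale {scale}")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        peak_rng = np.random.default_rng(seed + 7919 * (i + 1))
        group = GroupSpec(
            label="sr",
            base_peaks=_random_base_peaks(peak_rng, n_peaks=int(rng.integers(8, 18))),
            bleed_level=float(rng.uniform(0.0, 0.4)),
        )
        hr = render_contour(group, size=size, jitter=0.0, noise_sd=0.0, seed=seed + i)
        lo = resize(
            hr.pixels,
            (h // scale, w // scale, hr.channels),
            order=3,  # bicubic
            mode="reflect",
            anti_aliasing=True,
            preserve_range=True,
        )
        pairs.append((hr, ContourImage(np.clip(lo, 0.0, 1.0).astype(np.float32))))
    return pairs
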