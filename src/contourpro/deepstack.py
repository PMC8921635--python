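"""ROI selection and deepstacking.

Given the window-similarity profile of two group AFRCs, the k windows
with the lowest similarity scores are the regions of interest: the places
where the groups differ most.  "Deepstacking" crops those full-height
strips from every source contour and concatenates them side by side in
ascending score order, producing a contrast-enhanced dataset in which the
discriminating regions dominate the frame.  The selection is serialized
so the identical geometry can be re-applied at inference time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ShapeMismatchError
from .image import ContourImage, ContourDataset
from .metrics import WindowScore

__all__ = [
    "DeepstackSpec",
    "select_rois",
    "flag_low_outliers",
    "apply_deepstack",
    "build_deepstacked_dataset",
    "manual_roi",
    "save_spec",
    "load_spec",
]

DEFAULT_K = 5


@dataclass
class DeepstackSpec:
    """Ordered ROI selection: windows in ascending similarity-score order."""

    windows: list[tuple[int, int]]
    scores: list[float]
    metric_name: str
    source_resolution: tuple[int, int]
    # manual rectangular ROI keeps its y-extent; automatic strips are full height
    y_extent: tuple[int, int] | None = field(default=None)

    def __post_init__(self):
        if len(self.windows) < 1:
            raise ValueError("spec must contain at least one window")
        if len(self.windows) != len(self.scores):
            raise ValueError("windows and scores must have equal length")
        if any(s1 < s0 for s0, s1 in zip(self.scores, self.scores[1:])):
            raise ValueError("windows must be in ascending score order")
        spans = sorted(self.windows)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("windows must be pairwise non-overlapping")
        self.windows = [(int(a), int(b)) for a, b in self.windows]
        self.source_resolution = (int(self.source_resolution[0]), int(self.source_resolution[1]))


def select_rois(scores: list[WindowScore], k: int = DEFAULT_K,
                source_resolution: tuple[int, int] | None = None) -> DeepstackSpec:
    """Pick the k least-similar windows, ascending by score.

    Ties break toward the smaller ``x_start``.  Overlapping candidates
    (possible when stride < width) are greedily suppressed: a window is
    skipped if it overlaps an already-selected one.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scanned windows")
    ordered = sorted(scores, key=lambda s: (s.score, s.x_start))
    chosen: list[WindowScore] = []
    for cand in ordered:
        if any(cand.x_start < c.x_end and c.x_start < cand.x_end for c in chosen):
            continue
        chosen.append(cand)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError(f"only {len(chosen)} non-overlapping windows available for k={k}")
    if source_resolution is None:
        # height unknown from scores alone; 0 disables the resolution check
        source_resolution = (0, max(s.x_end for s in scores))
    return DeepstackSpec(
        windows=[(s.x_start, s.x_end) for s in chosen],
        scores=[s.score for s in chosen],
        metric_name=chosen[0].metric_name,
        source_resolution=source_resolution,
    )


def tie_threshold(
    images_a: list[ContourImage],
    images_b: list[ContourImage],
    window_width: int | None = None,
    stride: int | None = None,
    metric="deep",
    extractor=None,
    alpha: float | None = None,
    safety: float = 1.5,
) -> float:
    """Similarity level below which a window contrast is real, not noise.

    Split-half null calibration: each group's images are split in half,
    an AFRC is built per half, and the two halves of the *same* group are
    scanned against each other.  Any dissimilarity seen there is pure
    replicate noise (retention-time jitter, detector noise), so the tie
    threshold is the worst within-group similarity, widened by a safety
    factor on the dissimilarity scale.  Windows of the between-group scan
    scoring *below* this threshold carry genuine group contrast.
    """
    from .afrc import build_afrc, DEFAULT_ALPHA
    from .metrics import scan_windows

    alpha = DEFAULT_ALPHA if alpha is None else alpha
    null_scores: list[float] = []
    for images in (images_a, images_b):
        if len(images) < 4:
            raise ValueError("need at least 4 images per group for split-half calibration")
        half = len(images) // 2
        a1 = build_afrc(images[:half], alpha=alpha)
        a2 = build_afrc(images[half:], alpha=alpha)
        null_scores.extend(
            s.score for s in scan_windows(a1, a2, window_width=window_width,
                                          stride=stride, metric=metric,
                                          extractor=extractor)
        )
    worst_dissimilarity = max(1.0 - min(null_scores), 0.0)
    return 1.0 - safety * worst_dissimilarity


def significant_rois(scores: list[WindowScore], threshold: float) -> list[WindowScore]:
    """Windows scoring below the tie threshold (genuine group contrast)."""
    return [s for s in scores if s.score < threshold]


def apply_deepstack(img: ContourImage, spec: DeepstackSpec) -> ContourImage:
    """Crop and horizontally concatenate the spec's strips from one image."""
    if spec.source_resolution[0] and (img.height, img.width) != spec.source_resolution:
        raise ShapeMismatchError(
            f"image resolution {(img.height, img.width)} != spec {spec.source_resolution}"
        )
    y0, y1 = spec.y_extent if spec.y_extent is not None else (0, img.height)
    strips = [img.pixels[y0:y1, x0:x1] for x0, x1 in spec.windows]
    return ContourImage(np.concatenate(strips, axis=1), source_path=img.source_path)


def build_deepstacked_dataset(dataset: ContourDataset, spec: DeepstackSpec) -> ContourDataset:
    """Deepstack every image of every group, preserving structure and counts."""
    out: dict[str, list[ContourImage]] = {}
    for label, imgs in dataset.groups.items():
        out[label] = []
        for img in imgs:
            try:
                out[label].append(apply_deepstack(img, spec))
            except ShapeMismatchError as exc:
                raise ShapeMismatchError(
                    f"group {label!r}, image {img.source_path or '<in-memory>'}: {exc}"
                ) from exc
    return ContourDataset(out)


def manual_roi(img_region: tuple[int, int, int, int],
               source_resolution: tuple[int, int] | None = None) -> DeepstackSpec:
    """Single manually chosen rectangular ROI (x0, y0, x1, y1)."""
    x0, y0, x1, y1 = (int(v) for v in img_region)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty ROI rectangle {img_region}")
    if x0 < 0 or y0 < 0:
        raise ValueError("ROI must lie within image bounds")
    res = source_resolution or (0, 0)
    if source_resolution is not None and (y1 > res[0] or x1 > res[1]):
        raise ValueError(f"ROI {img_region} exceeds resolution {source_resolution}")
    return DeepstackSpec(
        windows=[(x0, x1)],
        scores=[0.0],
        metric_name="manual",
        source_resolution=res,
        y_extent=(y0, y1),
    )


def save_spec(spec: DeepstackSpec, path: str | Path) -> None:
    payload = {
        "windows": [list(w) for w in spec.windows],
        "scores": spec.scores,
        "metric": spec.metric_name,
        "resolution": list(spec.source_resolution),
        "y_extent": list(spec.y_extent) if spec.y_extent is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_spec(path: str | Path) -> DeepstackSpec:
    payload = json.loads(Path(path).read_text())
    return DeepstackSpec(
        windows=[tuple(w) for w in payload["windows"]],
        scores=[float(s) for s in payload["scores"]],
        metric_name=payload["metric"],
        source_resolution=tuple(payload["resolution"]),
        y_extent=tuple(payload["y_extent"]) if payload.get("y_extent") else None,
    )
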