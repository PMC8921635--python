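"""Core raster containers: :class:`ContourImage` and :class:`ContourDataset`.

A contour image is the colormapped rendering of a GC×GC–TOFMS chromatogram:
the x axis (columns) maps to the first-dimension retention time, the y axis
(rows) to the second-dimension retention time, and color encodes aggregate
ion intensity.  Internally every image is a row-major ``float32`` array in
``[0, 1]`` with origin at the top-left; 8-bit quantization happens only at
file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeMismatchError

__all__ = ["ContourImage", "ContourDataset"]

MIN_DIM = 8


@dataclass
class ContourImage:
    """An H×W×C raster with float values in [0, 1].

    ``pixels`` always has an explicit channel axis, even for grayscale
    (C=1).  The chromatographic axis mapping (RT1 ↔ x, RT2 ↔ y) is a
    storage convention only; no computation depends on orientation except
    the window scan, which slides along x.
    """

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D pixel array, got ndim={arr.ndim}")
        if arr.shape[2] not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {arr.shape[2]}")
        if arr.shape[0] < MIN_DIM or arr.shape[1] < MIN_DIM:
            raise ValueError(f"image must be at least {MIN_DIM}×{MIN_DIM}, got {arr.shape[:2]}")
        arr = arr.astype(np.float32, copy=False)
        if arr.size and (float(arr.min()) < 0.0 or float(arr.max()) > 1.0):
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def luma(self) -> np.ndarray:
        """Return the BT.601 luma plane (H×W); identity for grayscale."""
        if self.channels == 1:
            return self.pixels[:, :, 0]
        r, g, b = self.pixels[:, :, 0], self.pixels[:, :, 1], self.pixels[:, :, 2]
        return 0.299 * r + 0.587 * g + 0.114 * b

    def copy(self) -> "ContourImage":
        return ContourImage(self.pixels.copy(), source_path=self.source_path)


@dataclass
class ContourDataset:
    """Group-labeled collection of same-shaped contour images."""

    groups: dict[str, list[ContourImage]] = field(default_factory=dict)

    def __post_init__(self):
        shapes = {img.shape for imgs in self.groups.values() for img in imgs}
        if len(shapes) > 1:
            raise ShapeMismatchError(f"all dataset images must share one shape, got {shapes}")
        for label, imgs in self.groups.items():
            if not imgs:
                raise ValueError(f"group {label!r} is empty")

    @property
    def resolution(self) -> tuple[int, int]:
        img = next(iter(self.groups.values()))[0]
        return (img.height, img.width)

    @property
    def channels(self) -> int:
        return next(iter(self.groups.values()))[0].channels

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups)

    def n_images(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def items(self):
        """Yield ``(label, image)`` pairs in group, then file, order."""
        for label, imgs in self.groups.items():
            for img in imgs:
                yield label, img

    def map_images(self, fn) -> "ContourDataset":
        """Apply ``fn`` to every image, preserving the group structure."""
        return ContourDataset(
            {label: [fn(img) for img in imgs] for label, imgs in self.groups.items()}
        )
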