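"""Aggregate feature representative contour (AFRC) construction.

One AFRC summarizes a whole study group as a single image by running the
group's contour images through an exponentially weighted accumulator:

    afrc(x, y) <- (1 - alpha) * afrc(x, y) + alpha * frame(x, y)

applied only where the incoming frame carries content.  The update is the
running-average model familiar from background estimation (OpenCV's
``accumulateWeighted``): frequent features are reinforced every cycle
while a feature present in a single outlier image decays geometrically,
so the AFRC is an unbiased group representative that suppresses outliers
without any signal/noise discrimination.

The "video at a fixed FPS" used by the original workflow is a frame
streaming detail with no mathematical effect; here frames are applied
directly in cyclic order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError
from .image import ContourImage

__all__ = ["AFRCAccumulator", "afrc_update", "content_mask", "build_afrc"]

DEFAULT_ALPHA = 0.05
DEFAULT_CYCLES = 3

# Content threshold: a pixel participates in the update when it deviates
# from the frame's background level by more than 2 8-bit steps in any
# channel.  Contour exports have a non-zero (colormapped) background, so
# "content exists" is judged against the modal pixel value, not zero.
CONTENT_TOL = 2.0 / 255.0


@dataclass
class AFRCAccumulator:
    """State of the cyclic weighted accumulation."""

    afrc: np.ndarray  # H×W×C float32
    alpha: float = DEFAULT_ALPHA
    frames_seen: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        self.afrc = np.asarray(self.afrc, dtype=np.float32)


def afrc_update(
    acc: AFRCAccumulator,
    frame: ContourImage,
    content_mask: np.ndarray | None = None,
) -> AFRCAccumulator:
    """Apply one weighted-accumulation step in place and return ``acc``.

    Where ``content_mask`` is True the accumulator moves toward the frame
    by a factor ``alpha`` (per channel); elsewhere it is untouched.  A
    ``None`` mask updates everywhere.
    """
    if frame.pixels.shape != acc.afrc.shape:
        raise ShapeMismatchError(
            f"frame shape {frame.pixels.shape} != accumulator shape {acc.afrc.shape}"
        )
    a = acc.alpha
    if content_mask is None:
        acc.afrc = (1.0 - a) * acc.afrc + a * frame.pixels
    else:
        mask = np.asarray(content_mask, dtype=bool)
        if mask.shape != acc.afrc.shape[:2]:
            raise ShapeMismatchError(
                f"mask shape {mask.shape} != image plane {acc.afrc.shape[:2]}"
            )
        updated = (1.0 - a) * acc.afrc + a * frame.pixels
        acc.afrc = np.where(mask[:, :, None], updated, acc.afrc)
    acc.frames_seen += 1
    return acc


def content_mask(frame: ContourImage, tol: float = CONTENT_TOL) -> np.ndarray:
    """Pixels that differ from the frame's modal (background) value.

    The background level is estimated per channel as the modal 8-bit
    value; a pixel has content when any channel deviates from it by more
    than ``tol``.
    """
    quant = np.clip(np.round(frame.pixels * 255.0), 0, 255).astype(np.intp)
    bg = np.empty(frame.channels, dtype=np.float32)
    for c in range(frame.channels):
        counts = np.bincount(quant[:, :, c].ravel(), minlength=256)
        bg[c] = counts.argmax() / 255.0
    dev = np.abs(frame.pixels - bg[None, None, :])
    return (dev > tol).any(axis=2)


def build_afrc(
    group_images: list[ContourImage],
    alpha: float = DEFAULT_ALPHA,
    cycles: int = DEFAULT_CYCLES,
    masked: bool = True,
) -> ContourImage:
    """Build the group AFRC by cyclic weighted accumulation.

    The accumulator is initialized to the first image and the group is
    replayed in order ``cycles`` times.  The result is order-dependent (the
    recurrence is not permutation invariant) and lies pixelwise within the
    [min, max] envelope of the inputs.
    """
    if not group_images:
        raise ValueError("group_images must be non-empty")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    shapes = {img.pixels.shape for img in group_images}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"group images must share one shape, got {shapes}")
    acc = AFRCAccumulator(afrc=group_images[0].pixels.copy(), alpha=alpha)
    for _ in range(cycles):
        for frame in group_images:
            mask = content_mask(frame) if masked else None
            afrc_update(acc, frame, mask)
    return ContourImage(np.clip(acc.afrc, 0.0, 1.0))
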