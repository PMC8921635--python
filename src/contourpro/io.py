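"""Raster and dataset I/O.

PNG is the canonical interchange format; JPEG and TIFF are accepted.  Any
RGB raster is treated as a valid contour export — vendor software does not
standardize the export resolution or palette — so images are rescaled to a
common working resolution on load.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .errors import EmptyDatasetError, ImageFormatError
from .image import ContourImage, ContourDataset

__all__ = ["load_contour_image", "save_contour_image", "load_dataset"]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def load_contour_image(path: str | Path) -> ContourImage:
    """Load a PNG/JPEG/TIFF raster, scaled to float [0, 1].

    Grayscale files keep C=1, color files keep C=3; an alpha channel is
    dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoder backends raise variously
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray+alpha
        arr = arr[:, :, :1]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float32) / scale
    else:
        arr = np.clip(arr.astype(np.float32), 0.0, 1.0)
    return ContourImage(arr, source_path=str(path))


def save_contour_image(img: ContourImage, path: str | Path) -> None:
    """Write an image as an 8-bit raster (format from the file suffix)."""
    path = Path(path)
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    iio.imwrite(path, arr)


def _resize_to(img: ContourImage, resolution: tuple[int, int]) -> ContourImage:
    if (img.height, img.width) == tuple(resolution):
        return img
    out = resize(
        img.pixels,
        (resolution[0], resolution[1], img.channels),
        order=1,  # bilinear
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )
    return ContourImage(np.clip(out, 0.0, 1.0).astype(np.float32), source_path=img.source_path)


def load_dataset(
    root: str | Path,
    resolution: tuple[int, int] | None = None,
    channels: int | None = None,
) -> ContourDataset:
    """Load a group-per-subdirectory image tree into a dataset.

    Group labels are the subdirectory names; within a group, images are
    sorted by filename so loading is deterministic.  All images are resized
    (bilinear) to ``resolution``; when ``resolution`` is None the shape of
    the first image encountered is used.  Unreadable files are skipped with
    a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise EmptyDatasetError(f"dataset root is not a directory: {root}")
    groups: dict[str, list[ContourImage]] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        images = []
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            try:
                img = load_contour_image(f)
            except (ImageFormatError, OSError) as exc:
                warnings.warn(f"skipping unreadable image {f}: {exc}", stacklevel=2)
                continue
            if channels == 3 and img.channels == 1:
                img = ContourImage(np.repeat(img.pixels, 3, axis=2), source_path=img.source_path)
            if resolution is None:
                resolution = (img.height, img.width)
            images.append(_resize_to(img, resolution))
        if images:
            groups[sub.name] = images
    if not groups:
        raise EmptyDatasetError(f"no readable images found under {root}")
    return ContourDataset(groups)
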