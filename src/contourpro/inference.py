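"""Inference on unknown contour images: thresholded prediction,
watermarked result images, and CSV/JSON reports.

A sample is assigned its most probable class only when the confidence
(the maximum class probability) reaches the confidence threshold, 0.85
by default, boundary inclusive; otherwise it is reported as
``unclassified`` but retained in the report.  The preprocessing applied
at inference (full frame vs. a specific deepstack geometry) must match
what the classifier was trained on; a mismatch is an error, not a
silent fallback.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .classifier import ClassifierModel, predict_proba
from .deepstack import DeepstackSpec, apply_deepstack
from .errors import PreprocessingMismatchError
from .image import ContourImage

__all__ = [
    "InferenceRecord",
    "DEFAULT_THRESHOLD",
    "infer",
    "watermark",
    "write_report",
    "read_report",
    "spec_id",
]

DEFAULT_THRESHOLD = 0.85
UNCLASSIFIED = "unclassified"

CSV_HEADER = ["image_path", "predicted_class", "confidence", "passed_threshold",
              "preprocessing"]


@dataclass
class InferenceRecord:
    image_path: str
    predicted_class: str
    confidence: float
    passed_threshold: bool
    preprocessing: str

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if self.passed_threshold == (self.predicted_class == UNCLASSIFIED):
            raise ValueError(
                "predicted_class must be 'unclassified' exactly when the threshold fails"
            )


def spec_id(spec: DeepstackSpec) -> str:
    """Stable short identifier of a deepstack geometry."""
    payload = json.dumps([list(w) for w in spec.windows]).encode()
    return hashlib.md5(payload).hexdigest()[:8]


def infer(
    model: ClassifierModel,
    images: list[ContourImage],
    threshold: float = DEFAULT_THRESHOLD,
    spec: DeepstackSpec | None = None,
) -> list[InferenceRecord]:
    """Classify unknown images at a confidence threshold (inclusive ≥)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    trained_deepstacked = model.preprocessing.startswith("deepstacked")
    if trained_deepstacked and spec is None:
        raise PreprocessingMismatchError(
            f"model was trained on {model.preprocessing!r}; a matching deepstack "
            "spec is required at inference"
        )
    if not trained_deepstacked and spec is not None:
        raise PreprocessingMismatchError(
            "model was trained on full-frame images; do not supply a deepstack spec"
        )
    if trained_deepstacked:
        expected = f"deepstacked({spec_id(spec)})"
        if model.preprocessing != expected:
            raise PreprocessingMismatchError(
                f"deepstack spec mismatch: model trained with {model.preprocessing!r}, "
                f"supplied spec is {expected!r}"
            )
        proc_images = [apply_deepstack(img, spec) for img in images]
        preprocessing = expected
    else:
        proc_images = images
        preprocessing = "full"
    probs = predict_proba(model, proc_images)
    records = []
    for img, p in zip(images, probs):
        conf = float(p.max())
        # inclusive boundary, at single-precision resolution
        passed = conf >= threshold - 1e-6
        records.append(
            InferenceRecord(
                image_path=img.source_path or "<in-memory>",
                predicted_class=model.class_labels[int(p.argmax())] if passed else UNCLASSIFIED,
                confidence=conf,
                passed_threshold=passed,
                preprocessing=preprocessing,
            )
        )
    return records


def watermark(img: ContourImage, record: InferenceRecord) -> ContourImage:
    """Render the verdict (class + confidence, 2 decimals) into a corner.

    Only the overlay box is touched; the source image object is left
    unchanged.
    """
    text = f"{record.predicted_class} {record.confidence:.2f}"
    px = (np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
    if px.shape[2] == 1:
        px = np.repeat(px, 3, axis=2)
    pil = Image.fromarray(px)
    draw = ImageDraw.Draw(pil)
    pad = 2
    bbox = draw.textbbox((pad, pad), text)
    draw.rectangle((0, 0, bbox[2] + pad, bbox[3] + pad), fill=(0, 0, 0))
    draw.text((pad, pad), text, fill=(255, 255, 255))
    out = np.asarray(pil).astype(np.float32) / 255.0
    return ContourImage(out, source_path=img.source_path)


def write_report(records: list[InferenceRecord], fmt: str, path: str | Path) -> None:
    """Write one row/object per record; CSV header is fixed and documented."""
    if not records:
        raise ValueError("records must be non-empty")
    path = Path(path)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for r in records:
                writer.writerow([r.image_path, r.predicted_class,
                                 f"{r.confidence:.6f}", str(r.passed_threshold).lower(),
                                 r.preprocessing])
    elif fmt == "json":
        path.write_text(json.dumps([asdict(r) for r in records], indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r} (use 'csv' or 'json')")


def read_report(path: str | Path) -> list[InferenceRecord]:
    """Read back a JSON report into records (inverse of ``write_report``)."""
    payload = json.loads(Path(path).read_text())
    return [InferenceRecord(**obj) for obj in payload]
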