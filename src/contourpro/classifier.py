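"""Contour-image classification.

Trains a configurable CNN on group-labeled contour datasets with a
stratified 85:15 train/validation split, optional random augmentation
(shear, skew, distortion) of training batches, and per-epoch tracking of
loss, accuracy and AUROC.  The default ``small_cnn`` backbone is a
four-block convolutional network that needs no pretrained weights; the
named transfer-learning backbones accept a local weights file and refuse
to download anything.

Also provides the conventional baseline feature pipeline: a flattened
L1-normalized 3-D HSV color histogram, suitable for feeding classical
scikit-learn classifiers for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata
from skimage.color import rgb2hsv
from skimage.transform import resize

from . import nn
from .errors import TrainingDivergenceError
from .image import ContourImage, ContourDataset

__all__ = [
    "BACKBONES",
    "ClassifierModel",
    "TrainingHistory",
    "split_dataset",
    "build_classifier",
    "train_classifier",
    "predict_proba",
    "evaluate",
    "auroc",
    "hsv_histogram_features",
    "save_classifier",
    "load_classifier",
]

BACKBONES = ("small_cnn", "vgg16", "vgg19", "inception_v3", "resnet50", "densenet")
MIN_INPUT, MAX_INPUT = 128, 512
DEFAULT_BATCH = 8


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    auroc: list[float] = field(default_factory=list)

    def append(self, tl: float, vl: float, ta: float, va: float, au: float) -> None:
        for name, v in (("train_acc", ta), ("val_acc", va), ("auroc", au)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        self.train_loss.append(float(tl))
        self.val_loss.append(float(vl))
        self.train_acc.append(float(ta))
        self.val_acc.append(float(va))
        self.auroc.append(float(au))

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class ClassifierModel:
    backbone: str
    input_size: int
    n_classes: int
    class_labels: list[str]
    net: nn.Sequential
    preprocessing: str = "full"  # or "deepstacked(<spec-id>)"
    seed: int = 0


def split_dataset(dataset: ContourDataset, train_fraction: float = 0.85,
                  seed: int = 0) -> tuple[ContourDataset, ContourDataset]:
    """Per-group stratified shuffle split (default 85:15); disjoint, exhaustive."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_groups: dict[str, list[ContourImage]] = {}
    val_groups: dict[str, list[ContourImage]] = {}
    for label, imgs in dataset.groups.items():
        n = len(imgs)
        if n < 2:
            raise ValueError(f"group {label!r} has {n} image(s); need at least 2 to split")
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        order = rng.permutation(n)
        train_groups[label] = [imgs[i] for i in order[:n_train]]
        val_groups[label] = [imgs[i] for i in order[n_train:]]
    return ContourDataset(train_groups), ContourDataset(val_groups)


def _conv_block(cin: int, cout: int, rng) -> list[nn.Layer]:
    return [nn.Conv2d(cin, cout, 3, stride=2, rng=rng), nn.LeakyReLU(0.1)]


def _build_small_cnn(input_size: int, n_classes: int, rng) -> nn.Sequential:
    # four stride-2 blocks: input_size -> input_size/16, then GAP + linear head
    chans = [3, 12, 24, 48, 48]
    layers: list[nn.Layer] = []
    for i in range(4):
        layers += _conv_block(chans[i], chans[i + 1], rng)
    layers += [nn.GlobalAvgPool(), nn.Dense(chans[-1], n_classes, rng=rng)]
    return nn.Sequential(*layers)


def _build_vgg_stack(cfg: list, n_classes: int, rng) -> nn.Sequential:
    # "M" (the maxpool slot) is realized as stride 2 on the following conv
    layers: list[nn.Layer] = []
    cin = 3
    stride = 1
    for item in cfg:
        if item == "M":
            stride = 2
            continue
        layers += [nn.Conv2d(cin, item, 3, stride=stride, rng=rng), nn.ReLU()]
        cin = item
        stride = 1
    layers += [nn.GlobalAvgPool(), nn.Dense(cin, n_classes, rng=rng)]
    return nn.Sequential(*layers)


_VGG16_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M",
              512, 512, 512, "M"]
_VGG19_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


def _build_compact_deep(n_classes: int, rng, widths=(16, 32, 64, 128, 128)) -> nn.Sequential:
    """Compact deep-stack variant used for the inception/resnet/densenet slots."""
    layers: list[nn.Layer] = []
    cin = 3
    for wdt in widths:
        layers += _conv_block(cin, wdt, rng)
        cin = wdt
    layers += [nn.GlobalAvgPool(), nn.Dense(cin, n_classes, rng=rng)]
    return nn.Sequential(*layers)


def build_classifier(backbone: str, input_size: int, n_classes: int,
                     pretrained: bool = False, seed: int = 0,
                     class_labels: list[str] | None = None,
                     weights_path: str | Path | None = None) -> ClassifierModel:
    """Build a classifier; pretrained weights must exist locally (no download)."""
    if backbone not in BACKBONES:
        raise ValueError(f"unsupported backbone {backbone!r}; choose from {BACKBONES}")
    if not (MIN_INPUT <= input_size <= MAX_INPUT):
        raise ValueError(
            f"input_size must lie in [{MIN_INPUT}, {MAX_INPUT}], got {input_size}"
        )
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    if backbone == "small_cnn":
        net = _build_small_cnn(input_size, n_classes, rng)
    elif backbone == "vgg16":
        net = _build_vgg_stack(_VGG16_CFG, n_classes, rng)
    elif backbone == "vgg19":
        net = _build_vgg_stack(_VGG19_CFG, n_classes, rng)
    else:
        net = _build_compact_deep(n_classes, rng)
    if pretrained:
        if weights_path is None or not Path(weights_path).exists():
            raise FileNotFoundError(
                f"pretrained weights for {backbone!r} not found locally "
                f"(looked for {weights_path}); weights are never downloaded"
            )
        with np.load(weights_path) as z:
            net.load_state_arrays([z[k] for k in z.files])
    labels = class_labels or [f"class{i}" for i in range(n_classes)]
    if len(labels) != n_classes:
        raise ValueError("class_labels length must equal n_classes")
    return ClassifierModel(backbone=backbone, input_size=input_size,
                           n_classes=n_classes, class_labels=list(labels),
                           net=net, seed=seed)


def _prepare(images: list[ContourImage], input_size: int) -> np.ndarray:
    out = np.empty((len(images), 3, input_size, input_size), dtype=np.float32)
    for i, img in enumerate(images):
        px = img.pixels
        if px.shape[2] == 1:
            px = np.repeat(px, 3, axis=2)
        if px.shape[0] != input_size or px.shape[1] != input_size:
            px = resize(px, (input_size, input_size, 3), order=1,
                        anti_aliasing=px.shape[0] > input_size,
                        preserve_range=True).astype(np.float32)
        out[i] = np.moveaxis(np.clip(px, 0.0, 1.0), 2, 0)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _dataset_arrays(dataset: ContourDataset, class_labels: list[str],
                    input_size: int) -> tuple[np.ndarray, np.ndarray]:
    images, labels = [], []
    index = {lab: i for i, lab in enumerate(class_labels)}
    for lab, img in dataset.items():
        if lab not in index:
            raise ValueError(f"dataset group {lab!r} unknown to the model {class_labels}")
        images.append(img)
        labels.append(index[lab])
    return _prepare(images, input_size), np.array(labels, dtype=np.intp)


def _random_affine(px: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random shear/skew/distort of one CHW training example."""
    shear = rng.uniform(-0.12, 0.12)
    skew = rng.uniform(-0.12, 0.12)
    zoom = rng.uniform(0.92, 1.08)
    mat = np.array([[zoom, shear], [skew, zoom]])
    c, h, w = px.shape
    center = np.array([h / 2.0, w / 2.0])
    offset = center - mat @ center
    out = np.empty_like(px)
    for ch in range(c):
        out[ch] = ndimage.affine_transform(px[ch], mat, offset=offset, order=1,
                                           mode="nearest")
    return out


def train_classifier(
    model: ClassifierModel,
    train: ContourDataset,
    val: ContourDataset,
    epochs: int,
    augment: bool = False,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = DEFAULT_BATCH,
) -> tuple[ClassifierModel, TrainingHistory]:
    """Cross-entropy training; augmentation applies to training batches only."""
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    x_train, y_train = _dataset_arrays(train, model.class_labels, model.input_size)
    x_val, y_val = _dataset_arrays(val, model.class_labels, model.input_size)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    opt = nn.Adam(model.net.params(), lr=lr, beta1=0.9)
    rng = np.random.default_rng(seed)
    history = TrainingHistory()
    n = len(y_train)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = x_train[idx]
            if augment:
                xb = np.stack([_random_affine(im, rng) for im in xb])
            yb = y_train[idx]
            logits = model.net.forward(xb)
            probs = _softmax(logits)
            loss = -float(np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12)))
            if not np.isfinite(loss):
                raise TrainingDivergenceError("classifier loss is not finite")
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            opt.zero_grad()
            model.net.backward(dlogits.astype(np.float32))
            opt.step()
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == yb).sum())
        val_probs = _forward_chunks(model, x_val)
        val_loss = -float(np.mean(np.log(val_probs[np.arange(len(y_val)), y_val] + 1e-12)))
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        au = _history_auroc(val_probs, y_val, model.n_classes)
        history.append(float(np.mean(losses)), val_loss, correct / n, val_acc, au)
    return model, history


def _forward_chunks(model: ClassifierModel, x: np.ndarray, chunk: int = 16) -> np.ndarray:
    outs = [
        _softmax(model.net.forward(x[i:i + chunk], train=False))
        for i in range(0, len(x), chunk)
    ]
    return np.concatenate(outs, axis=0)


def _history_auroc(probs: np.ndarray, y: np.ndarray, n_classes: int) -> float:
    if n_classes == 2:
        if len(np.unique(y)) < 2:
            return 0.5
        return auroc(probs[:, 1].tolist(), y.tolist())
    vals = []
    for k in range(n_classes):
        yk = (y == k).astype(int)
        if len(np.unique(yk)) < 2:
            continue
        vals.append(auroc(probs[:, k].tolist(), yk.tolist()))
    return float(np.mean(vals)) if vals else 0.5


def predict_proba(model: ClassifierModel, images: list[ContourImage]) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) in input order."""
    return _forward_chunks(model, _prepare(images, model.input_size))


def auroc(scores: list[float], labels: list[int]) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Ties receive half credit, equivalent to trapezoidal integration of
    the ROC curve.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = rankdata(s)  # average ranks on ties -> 1/2 credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def hsv_histogram_features(img: ContourImage, bins: tuple[int, int, int] = (8, 8, 8)) -> np.ndarray:
    """Flattened L1-normalized 3-D HSV histogram (default length 512).

    The conventional baseline feature: the joint distribution of hue,
    saturation and value over all pixels, independent of pixel position.
    """
    if img.channels != 3:
        raise ValueError("HSV histogram requires a 3-channel image")
    hsv = rgb2hsv(img.pixels)
    hist, _ = np.histogramdd(hsv.reshape(-1, 3), bins=bins,
                             range=((0, 1), (0, 1), (0, 1)))
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist.ravel(order="C")


def evaluate(model: ClassifierModel, dataset: ContourDataset
             ) -> tuple[float, dict[tuple[str, str], int], float | None]:
    """Accuracy, per-class confusion counts, and AUROC (2-class only)."""
    x, y = _dataset_arrays(dataset, model.class_labels, model.input_size)
    probs = _forward_chunks(model, x)
    preds = probs.argmax(axis=1)
    accuracy = float((preds == y).mean())
    confusion: dict[tuple[str, str], int] = {}
    for yi, pi in zip(y, preds):
        key = (model.class_labels[yi], model.class_labels[pi])
        confusion[key] = confusion.get(key, 0) + 1
    au = None
    if model.n_classes == 2 and len(np.unique(y)) == 2:
        au = auroc(probs[:, 1].tolist(), y.tolist())
    return accuracy, confusion, au


def save_classifier(model: ClassifierModel, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "classifier.npz", *model.net.state_arrays())
    meta = {
        "backbone": model.backbone,
        "input_size": model.input_size,
        "n_classes": model.n_classes,
        "class_labels": model.class_labels,
        "preprocessing": model.preprocessing,
        "seed": model.seed,
    }
    (out_dir / "classifier.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_classifier(model_dir: str | Path) -> ClassifierModel:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "classifier.json").read_text())
    model = build_classifier(meta["backbone"], meta["input_size"], meta["n_classes"],
                             seed=meta["seed"], class_labels=meta["class_labels"])
    with np.load(model_dir / "classifier.npz") as z:
        model.net.load_state_arrays([z[k] for k in z.files])
    model.preprocessing = meta["preprocessing"]
    return model
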