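"""Cascading-residual super-resolution for contour images.

The network follows the cascading-residual recipe: a feature stem, a
chain of residual blocks whose outputs are all concatenated and fused by
1×1 convolutions after every block (the cascading connections), and a
nearest-neighbour-upsample + convolution head.  The head predicts a
residual added to a bicubic upsample of the input, and the final
convolution starts at zero, so an untrained model reproduces bicubic
interpolation exactly and training only has to learn the
high-frequency correction on top of it.  Training minimizes the
L1 loss (mean absolute difference between the prediction and the true
high-resolution image) and tracks the qScore ratio of the reconstruction
against its reference, which trends toward zero as the model learns to
restore sharpness.

Training data is simulated: :func:`contourpro.synthetic.generate_sr_training_pairs`
renders high-quality contour-like images and pairs them with bicubic
downsamples, mirroring how a contour-specific super-resolution model is
trained when real high-resolution exports are scarce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import TrainingDivergenceError
from .image import ContourImage
from .gan import images_to_batch
from .metrics import qscore_ratio

__all__ = ["CARN", "build_carn", "train_carn", "enhance", "save_carn", "load_carn"]


def _cubic_weights(scale: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-phase 4-tap cubic-convolution (a = −0.5) weights and base offsets."""
    a = -0.5
    phases = (np.arange(scale) + 0.5) / scale - 0.5
    base = np.floor(phases).astype(int)
    t = phases - base
    d = np.stack([t + 1.0, t, 1.0 - t, 2.0 - t])  # distances of the 4 taps

    def k(x):
        x = np.abs(x)
        return np.where(
            x <= 1.0, (a + 2) * x**3 - (a + 3) * x**2 + 1.0,
            np.where(x < 2.0, a * x**3 - 5 * a * x**2 + 8 * a * x - 4 * a, 0.0),
        )

    return k(d).astype(np.float32), base


def bicubic_upsample(x: np.ndarray, scale: int) -> np.ndarray:
    """Separable cubic-convolution upsampling of an NCHW batch (edge clamp)."""
    weights, base = _cubic_weights(scale)

    def up_axis(arr: np.ndarray) -> np.ndarray:
        # upsample the last axis
        n = arr.shape[-1]
        out = np.zeros(arr.shape[:-1] + (n * scale,), dtype=np.float32)
        for phase in range(scale):
            taps = np.arange(n) + base[phase] - 1
            acc = np.zeros(arr.shape[:-1] + (n,), dtype=np.float32)
            for tap in range(4):
                idx = np.clip(taps + tap, 0, n - 1)
                acc += weights[tap, phase] * arr[..., idx]
            out[..., phase::scale] = acc
        return out

    y = up_axis(np.moveaxis(x, 2, -1))   # rows
    y = up_axis(np.moveaxis(y, -1, 2))   # cols (W is back at the last axis)
    return y


@dataclass
class _Block:
    conv1: nn.Conv2d
    relu1: nn.ReLU
    conv2: nn.Conv2d
    relu2: nn.ReLU
    cascade: nn.Conv2d
    cascade_relu: nn.ReLU


class CARN:
    """Cascading residual network; ``scale`` ∈ {2, 4}."""

    def __init__(self, scale: int = 2, n_blocks: int = 3, n_channels: int = 64,
                 seed: int = 0):
        if scale not in (2, 4):
            raise ValueError(f"scale must be 2 or 4, got {scale}")
        if n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        rng = np.random.default_rng(seed)
        c = n_channels
        self.scale, self.n_blocks, self.n_channels = scale, n_blocks, c
        self.seed = seed
        self.conv_in = nn.Conv2d(3, c, 3, rng=rng)
        self.relu_in = nn.ReLU()
        self.blocks: list[_Block] = []
        for b in range(n_blocks):
            self.blocks.append(_Block(
                conv1=nn.Conv2d(c, c, 3, rng=rng), relu1=nn.ReLU(),
                conv2=nn.Conv2d(c, c, 3, rng=rng), relu2=nn.ReLU(),
                cascade=nn.Conv2d((b + 2) * c, c, 1, rng=rng), cascade_relu=nn.ReLU(),
            ))
        self.up_stages: list[tuple[nn.Upsample2x, nn.Conv2d, nn.ReLU]] = []
        for _ in range(int(np.log2(scale))):
            self.up_stages.append((nn.Upsample2x(), nn.Conv2d(c, c, 3, rng=rng), nn.ReLU()))
        self.conv_out = nn.Conv2d(c, 3, 3, rng=rng)
        self.conv_out.w.value[...] = 0.0  # start as pure bicubic interpolation

    def params(self) -> list[nn.Param]:
        out = self.conv_in.params()
        for blk in self.blocks:
            out += blk.conv1.params() + blk.conv2.params() + blk.cascade.params()
        for _, conv, _ in self.up_stages:
            out += conv.params()
        out += self.conv_out.params()
        return out

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: N×3×h×w → N×3×(h·scale)×(w·scale), unclipped."""
        f0 = self.relu_in.forward(self.conv_in.forward(x))
        feats = [f0]
        cur = f0
        for blk in self.blocks:
            mid = blk.conv2.forward(blk.relu1.forward(blk.conv1.forward(cur)))
            r = blk.relu2.forward(mid + cur)
            feats.append(r)
            cur = blk.cascade_relu.forward(blk.cascade.forward(np.concatenate(feats, axis=1)))
        u = cur
        for ups, conv, relu in self.up_stages:
            u = relu.forward(conv.forward(ups.forward(u)))
        residual = self.conv_out.forward(u)
        skip = bicubic_upsample(x, self.scale)
        self._c = self.n_channels
        return residual + skip

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate dL/dy into parameter gradients (input grad discarded)."""
        d = self.conv_out.backward(dy)
        for ups, conv, relu in reversed(self.up_stages):
            d = ups.backward(conv.backward(relu.backward(d)))
        c = self._c
        n_blocks = len(self.blocks)
        dfeats = [None] * (n_blocks + 1)  # grads w.r.t. f0 and each r_b
        dcur = d
        for b in range(n_blocks - 1, -1, -1):
            blk = self.blocks[b]
            dconcat = blk.cascade.backward(blk.cascade_relu.backward(dcur))
            for i in range(b + 2):
                part = dconcat[:, i * c:(i + 1) * c]
                dfeats[i] = part if dfeats[i] is None else dfeats[i] + part
            dr = dfeats[b + 1]
            da = blk.relu2.backward(dr)
            dthrough = blk.conv1.backward(blk.relu1.backward(blk.conv2.backward(da)))
            dcur = dthrough + da
        df0 = dcur if dfeats[0] is None else dcur + dfeats[0]
        self.conv_in.backward(self.relu_in.backward(df0))


def build_carn(scale: int = 2, n_blocks: int = 3, n_channels: int = 64,
               seed: int = 0) -> CARN:
    """Deterministically initialized cascading residual network."""
    return CARN(scale=scale, n_blocks=n_blocks, n_channels=n_channels, seed=seed)


def train_carn(
    model: CARN,
    pairs: list[tuple[ContourImage, ContourImage]],
    epochs: int,
    seed: int = 0,
    batch_size: int = 4,
    lr: float = 1e-3,
    monitor_pairs: int = 6,
) -> tuple[CARN, dict[str, list[float]]]:
    """L1 training on (high-res, low-res) pairs.

    History records, per epoch, the mean training L1 loss and the mean
    qScore ratio of reconstructions against their high-resolution
    references on a fixed monitoring subset.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    hr_batch = images_to_batch([hr for hr, _ in pairs])
    lr_batch = images_to_batch([lo for _, lo in pairs])
    if hr_batch.shape[2] != lr_batch.shape[2] * model.scale:
        raise ValueError("pair resolutions inconsistent with model scale")
    opt = nn.Adam(model.params(), lr=lr, beta1=0.9)
    rng = np.random.default_rng(seed)
    history: dict[str, list[float]] = {"l1_loss": [], "qscore_ratio": []}
    n = len(pairs)
    mon = min(monitor_pairs, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            pred = model.forward(lr_batch[idx])
            diff = pred - hr_batch[idx]
            l1 = float(np.abs(diff).mean())
            if not np.isfinite(l1):
                raise TrainingDivergenceError("L1 loss is not finite")
            opt.zero_grad()
            model.backward(np.sign(diff).astype(np.float32) / diff.size)
            opt.step()
            losses.append(l1)
        ratios = []
        for i in range(mon):
            rec = enhance(model, pairs[i][1])
            ratios.append(qscore_ratio(pairs[i][0], rec))
        history["l1_loss"].append(float(np.mean(losses)))
        history["qscore_ratio"].append(float(np.mean(ratios)))
    return model, history


def enhance(model: CARN, img: ContourImage) -> ContourImage:
    """Upscale one contour image by the model's scale factor."""
    px = img.pixels
    if px.shape[2] == 1:
        px = np.repeat(px, 3, axis=2)
    batch = np.moveaxis(px, 2, 0)[None].astype(np.float32)
    out = model.forward(batch, train=False)[0]
    return ContourImage(np.clip(np.moveaxis(out, 0, 2), 0.0, 1.0),
                        source_path=img.source_path)


def save_carn(model: CARN, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "carn.npz", *[p.value for p in model.params()])
    meta = {"scale": model.scale, "n_blocks": model.n_blocks,
            "n_channels": model.n_channels, "seed": model.seed}
    (out_dir / "carn.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_carn(model_dir: str | Path) -> CARN:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "carn.json").read_text())
    model = CARN(scale=meta["scale"], n_blocks=meta["n_blocks"],
                 n_channels=meta["n_channels"], seed=meta["seed"])
    with np.load(model_dir / "carn.npz") as z:
        arrays = [z[k] for k in z.files]
    params = model.params()
    if len(arrays) != len(params):
        raise ValueError("weight count mismatch")
    for p, a in zip(params, arrays):
        p.value = np.asarray(a, dtype=np.float32)
    return model
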