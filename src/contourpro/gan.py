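"""Adversarial contour synthesizer.

A DCGAN-style convolutional generator/discriminator pair is trained on
(deepstacked or full-frame) contour datasets.  Two objectives are
available:

``logistic``
    the classic non-saturating min–max game: the discriminator (named the
    *trainer* T here, since under the QP objective it is a critic rather
    than a classifier) ascends
    E_x[log σ(T(x))] + E_{x=G(z)}[log(1 − σ(T(x)))]
    while the generator descends −log σ(T(G(z))).

``qp`` (default)
    the quadratic-potential objective, which replaces the logistic
    divergence with a pairwise potential: the critic minimizes
    E[T(f) − T(r)] + E[(T(r) − T(f))² / (2·λ·d(r, f))], where d is the
    mean absolute pixel distance between a real/fake pair, and the
    generator minimizes E[T(r) − T(f)].  The quadratic term is a built-in
    Lipschitz penalty, which keeps gradients finite without weight
    clipping and is what makes the architecture stable enough to scale to
    512×512 contours.

Training is monitored with FID and qScore of a synthesized batch versus a
real batch at fixed checkpoint intervals, and the latent vector can be
proportionally scaled (intensity manipulation) at synthesis time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .errors import TrainingDivergenceError
from .image import ContourImage, ContourDataset
from .io import save_contour_image
from .metrics import FeatureExtractor, default_extractor, fid as fid_metric, qscore

__all__ = [
    "GANState",
    "GANTrainingHistory",
    "init_gan",
    "gan_train_step",
    "train_gan",
    "synthesize",
    "synthesize_dataset",
    "augment",
    "save_gan",
    "load_gan",
    "images_to_batch",
    "batch_to_images",
]

SUPPORTED_RESOLUTIONS = (64, 128, 256, 512)
DEFAULT_Z_DIM = 128
DEFAULT_LAMBDA_QP = 10.0
DEFAULT_LR = 2e-4


def images_to_batch(images: list[ContourImage]) -> np.ndarray:
    """Stack images into an N×3×H×W float32 batch (grayscale replicated)."""
    arrs = []
    for img in images:
        px = img.pixels
        if px.shape[2] == 1:
            px = np.repeat(px, 3, axis=2)
        arrs.append(np.moveaxis(px, 2, 0))
    return np.stack(arrs).astype(np.float32)


def batch_to_images(batch: np.ndarray) -> list[ContourImage]:
    return [ContourImage(np.clip(np.moveaxis(b, 0, 2), 0.0, 1.0)) for b in batch]


@dataclass
class GANTrainingHistory:
    """Per-checkpoint monitoring series recorded during training."""

    iterations: list[int] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    fid: list[float] = field(default_factory=list)
    qscore: list[float] = field(default_factory=list)

    def append(self, iteration: int, g_loss: float, d_loss: float,
               fid_val: float, qscore_val: float) -> None:
        if self.iterations and iteration <= self.iterations[-1]:
            raise ValueError("checkpoint iterations must be strictly increasing")
        self.iterations.append(int(iteration))
        self.g_loss.append(float(g_loss))
        self.d_loss.append(float(d_loss))
        self.fid.append(float(fid_val))
        self.qscore.append(float(qscore_val))

    def __len__(self) -> int:
        return len(self.iterations)


@dataclass
class GANState:
    generator: nn.Sequential
    discriminator: nn.Sequential
    z_dim: int
    resolution: int
    loss_mode: str = "qp"
    lambda_qp: float = DEFAULT_LAMBDA_QP
    rng_seed: int = 0
    iteration: int = 0
    opt_g: nn.Adam | None = None
    opt_d: nn.Adam | None = None
    rng: np.random.Generator | None = None


def _build_generator(resolution: int, z_dim: int, rng: np.random.Generator) -> nn.Sequential:
    n_stages = int(np.log2(resolution // 4))
    c0 = 128
    chans = [max(c0 >> s, 8) for s in range(n_stages + 1)]
    layers: list[nn.Layer] = [
        nn.Dense(z_dim, chans[0] * 4 * 4, rng=rng),
        nn.Reshape((chans[0], 4, 4)),
        nn.ReLU(),
    ]
    for s in range(n_stages):
        layers += [nn.Upsample2x(), nn.Conv2d(chans[s], chans[s + 1], 3, rng=rng), nn.ReLU()]
    layers += [nn.Conv2d(chans[-1], 3, 3, rng=rng), nn.Sigmoid()]
    return nn.Sequential(*layers)


def _build_discriminator(resolution: int, rng: np.random.Generator) -> nn.Sequential:
    n_stages = int(np.log2(resolution // 4))
    chans = [3] + [min(8 << s, 128) for s in range(n_stages)]
    layers: list[nn.Layer] = []
    for s in range(n_stages):
        layers += [nn.Conv2d(chans[s], chans[s + 1], 3, stride=2, rng=rng), nn.LeakyReLU(0.2)]
    layers += [nn.Flatten(), nn.Dense(chans[-1] * 4 * 4, 1, rng=rng)]
    return nn.Sequential(*layers)


def init_gan(resolution: int, z_dim: int = DEFAULT_Z_DIM, seed: int = 0,
             loss_mode: str = "qp", lambda_qp: float = DEFAULT_LAMBDA_QP,
             lr: float = DEFAULT_LR) -> GANState:
    """Deterministically initialize a generator/discriminator pair."""
    if resolution not in SUPPORTED_RESOLUTIONS:
        raise ValueError(
            f"resolution must be a square power of two in {SUPPORTED_RESOLUTIONS}, got {resolution}"
        )
    if z_dim < 8:
        raise ValueError("z_dim must be >= 8")
    if loss_mode not in ("qp", "logistic"):
        raise ValueError(f"loss_mode must be 'qp' or 'logistic', got {loss_mode!r}")
    rng = np.random.default_rng(seed)
    gen = _build_generator(resolution, z_dim, rng)
    disc = _build_discriminator(resolution, rng)
    state = GANState(
        generator=gen, discriminator=disc, z_dim=z_dim, resolution=resolution,
        loss_mode=loss_mode, lambda_qp=lambda_qp, rng_seed=seed,
        opt_g=nn.Adam(gen.params(), lr=lr, beta1=0.5),
        opt_d=nn.Adam(disc.params(), lr=lr, beta1=0.5),
        rng=np.random.default_rng(seed + 1),
    )
    return state


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def gan_train_step(state: GANState, real_batch: np.ndarray,
                   z_batch: np.ndarray) -> tuple[GANState, float, float]:
    """One alternating discriminator/generator update; returns losses."""
    m = real_batch.shape[0]
    if m < 2:
        raise ValueError("batch size must be >= 2")
    if real_batch.shape[2] != state.resolution or real_batch.shape[3] != state.resolution:
        raise ValueError(
            f"real batch spatial size {real_batch.shape[2:]} != resolution {state.resolution}"
        )
    g, d = state.generator, state.discriminator
    eps = 1e-8

    fake = g.forward(z_batch.astype(np.float32))

    # --- discriminator / trainer update -------------------------------
    x = np.concatenate([real_batch.astype(np.float32), fake], axis=0)
    logits = d.forward(x)[:, 0]
    t_r, t_f = logits[:m], logits[m:]
    if state.loss_mode == "logistic":
        s_r, s_f = _sigmoid(t_r), _sigmoid(t_f)
        d_loss = -float(np.mean(np.log(s_r + eps)) + np.mean(np.log(1.0 - s_f + eps)))
        dt_r = -(1.0 - s_r) / m
        dt_f = s_f / m
    else:  # qp
        dist = np.abs(real_batch - fake).mean(axis=(1, 2, 3)) + eps
        delta = t_r - t_f
        penalty = delta**2 / (2.0 * state.lambda_qp * dist)
        d_loss = float(np.mean(t_f - t_r) + np.mean(penalty))
        dpen = delta / (state.lambda_qp * dist)
        dt_r = (-1.0 + dpen) / m
        dt_f = (1.0 - dpen) / m
    if not np.isfinite(d_loss):
        raise TrainingDivergenceError("discriminator loss is not finite", state.iteration)
    state.opt_d.zero_grad()
    dlogits = np.concatenate([dt_r, dt_f])[:, None].astype(np.float32)
    d.backward(dlogits)
    state.opt_d.step()

    # --- generator update ---------------------------------------------
    if state.loss_mode == "logistic":
        t_f2 = d.forward(fake)[:, 0]
        s_f2 = _sigmoid(t_f2)
        g_loss = -float(np.mean(np.log(s_f2 + eps)))
        dt_f2 = -(1.0 - s_f2) / m
    else:
        t_r2 = d.forward(real_batch.astype(np.float32))[:, 0]
        t_f2 = d.forward(fake)[:, 0]
        g_loss = float(np.mean(t_r2) - np.mean(t_f2))
        dt_f2 = np.full(m, -1.0 / m)
    if not np.isfinite(g_loss):
        raise TrainingDivergenceError("generator loss is not finite", state.iteration)
    state.opt_g.zero_grad()
    state.opt_d.zero_grad()  # discard critic grads from this pass
    dfake = d.backward(dt_f2[:, None].astype(np.float32))
    g.backward(dfake)
    state.opt_g.step()

    state.iteration += 1
    return state, g_loss, d_loss


def synthesize(state: GANState, n: int, z_scale: float = 1.0,
               seed: int = 0, chunk: int = 16) -> list[ContourImage]:
    """Draw z ~ N(0, I), scale it, and decode contour images.

    ``z_scale`` proportionally manipulates the latent vector, the
    intensity-variation control; 0 collapses every draw to G(0).
    """
    if not (0.0 <= z_scale <= 2.0):
        raise ValueError("z_scale must lie in [0, 2]")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[ContourImage] = []
    remaining = n
    while remaining > 0:
        b = min(chunk, remaining)
        z = z_scale * rng.standard_normal((b, state.z_dim)).astype(np.float32)
        out.extend(batch_to_images(state.generator.forward(z, train=False)))
        remaining -= b
    return out


def synthesize_dataset(state: GANState, source_count: int, multiplier: int = 10,
                       seed: int = 0, z_scale: float = 1.0,
                       label: str = "synthetic") -> ContourDataset:
    """Expand a source set ``multiplier``-fold (default 10×) synthetically."""
    if source_count < 1:
        raise ValueError("source_count must be >= 1")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    images = synthesize(state, n=multiplier * source_count, z_scale=z_scale, seed=seed)
    return ContourDataset({label: images})


def train_gan(
    state: GANState,
    dataset: ContourDataset,
    iterations: int,
    fid_every: int = 10,
    fid_batch: int = 8,
    extractor: FeatureExtractor | None = None,
    batch_size: int = 8,
    preview_dir: str | Path | None = None,
    preview_cols: int = 4,
) -> tuple[GANState, GANTrainingHistory]:
    """Train on a dataset, recording FID/qScore checkpoints.

    Every ``fid_every`` iterations a batch of ``fid_batch`` images is
    synthesized and compared to a real batch: FID between extractor
    features, qScore for relative sharpness.  A preview grid image is
    written to ``preview_dir`` at each checkpoint when given.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    images = [img for _, img in dataset.items()]
    if not images:
        raise ValueError("dataset is empty")
    extractor = extractor or default_extractor()
    all_real = images_to_batch(images)
    history = GANTrainingHistory()
    rng = state.rng or np.random.default_rng(state.rng_seed + 1)
    for it in range(iterations):
        idx = rng.choice(len(images), size=min(batch_size, len(images)), replace=False)
        real = all_real[idx]
        z = rng.standard_normal((real.shape[0], state.z_dim)).astype(np.float32)
        state, g_loss, d_loss = gan_train_step(state, real, z)
        if (it + 1) % fid_every == 0 or it + 1 == iterations:
            if history.iterations and state.iteration <= history.iterations[-1]:
                continue
            synth = synthesize(state, n=min(fid_batch, len(images)),
                               seed=state.rng_seed + 9000 + it)
            ridx = rng.choice(len(images), size=min(fid_batch, len(images)), replace=False)
            real_imgs = [images[i] for i in ridx]
            feats_s = np.stack([extractor(im) for im in synth])
            feats_r = np.stack([extractor(im) for im in real_imgs])
            fid_val = fid_metric(feats_s, feats_r)
            q_val = qscore(synth, real_imgs)
            history.append(state.iteration, g_loss, d_loss, fid_val, q_val)
            if preview_dir is not None:
                _write_preview(synth, Path(preview_dir), state.iteration, preview_cols)
    return state, history


def _write_preview(images: list[ContourImage], out_dir: Path,
                   iteration: int, cols: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(images)
    cols = max(1, min(cols, n))
    rows = (n + cols - 1) // cols
    h, w, c = images[0].shape
    grid = np.zeros((rows * h, cols * w, c), dtype=np.float32)
    for i, img in enumerate(images):
        r, col = divmod(i, cols)
        grid[r * h:(r + 1) * h, col * w:(col + 1) * w] = img.pixels
    save_contour_image(ContourImage(grid), out_dir / f"preview_{iteration:06d}.png")


# ---------------------------------------------------------------------------
# augmentation filter bank
# ---------------------------------------------------------------------------

def _op_sharpen(px, rng, amount=1.0, sigma=1.0):
    blurred = ndimage.gaussian_filter(px, sigma=(sigma, sigma, 0))
    return px + amount * (px - blurred)


def _op_blur(px, rng, sigma=1.0):
    return ndimage.gaussian_filter(px, sigma=(sigma, sigma, 0))


def _op_noise(px, rng, sd=0.02):
    return px + rng.normal(0.0, sd, size=px.shape)


def _op_denoise(px, rng, size=3):
    return ndimage.median_filter(px, size=(size, size, 1))


def _op_erode(px, rng, size=3):
    return ndimage.grey_erosion(px, size=(size, size, 1))


def _op_dilate(px, rng, size=3):
    return ndimage.grey_dilation(px, size=(size, size, 1))


def _op_distort(px, rng, amplitude=2.0, period=32.0):
    h, w, c = px.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    shift_x = amplitude * np.sin(2 * np.pi * yy / period)
    shift_y = amplitude * np.sin(2 * np.pi * xx / period)
    out = np.empty_like(px)
    for ch in range(c):
        out[:, :, ch] = ndimage.map_coordinates(
            px[:, :, ch], [yy + shift_y, xx + shift_x], order=1, mode="reflect"
        )
    return out


def _op_brightness(px, rng, delta=0.0):
    return px + delta


def _op_contrast(px, rng, factor=1.0):
    return (px - 0.5) * factor + 0.5


def _op_edge_enhance(px, rng, amount=0.5):
    lap = np.stack(
        [ndimage.laplace(px[:, :, ch], mode="reflect") for ch in range(px.shape[2])], axis=2
    )
    return px - amount * lap


_AUGMENT_OPS = {
    "sharpen": _op_sharpen,
    "blur": _op_blur,
    "noise": _op_noise,
    "denoise": _op_denoise,
    "erode": _op_erode,
    "dilate": _op_dilate,
    "distort": _op_distort,
    "brightness": _op_brightness,
    "contrast": _op_contrast,
    "edge_enhance": _op_edge_enhance,
}


def augment(img: ContourImage, ops: list[str],
            params: dict[str, dict] | None = None, seed: int = 0) -> ContourImage:
    """Apply named filters in order; output clipped to [0, 1].

    The operations do not commute (e.g. blur∘sharpen ≠ sharpen∘blur), so
    the list order is honored exactly.  Stochastic ops (noise) draw from a
    generator seeded with ``seed``.
    """
    if not ops:
        raise ValueError("ops must be a non-empty list")
    params = params or {}
    rng = np.random.default_rng(seed)
    px = img.pixels.astype(np.float64)
    for name in ops:
        if name not in _AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {name!r}")
        px = _AUGMENT_OPS[name](px, rng, **params.get(name, {}))
        px = np.clip(px, 0.0, 1.0)
    return ContourImage(px.astype(np.float32), source_path=img.source_path)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_gan(state: GANState, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "generator.npz", *state.generator.state_arrays())
    np.savez(out_dir / "discriminator.npz", *state.discriminator.state_arrays())
    meta = {
        "z_dim": state.z_dim,
        "resolution": state.resolution,
        "loss_mode": state.loss_mode,
        "lambda_qp": state.lambda_qp,
        "rng_seed": state.rng_seed,
        "iteration": state.iteration,
    }
    (out_dir / "gan.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_gan(model_dir: str | Path) -> GANState:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "gan.json").read_text())
    state = init_gan(meta["resolution"], z_dim=meta["z_dim"], seed=meta["rng_seed"],
                     loss_mode=meta["loss_mode"], lambda_qp=meta["lambda_qp"])
    with np.load(model_dir / "generator.npz") as gz:
        state.generator.load_state_arrays([gz[k] for k in gz.files])
    with np.load(model_dir / "discriminator.npz") as dz:
        state.discriminator.load_state_arrays([dz[k] for k in dz.files])
    state.iteration = meta["iteration"]
    return state
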