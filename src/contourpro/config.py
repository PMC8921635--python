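"""Plain-text run configuration, model summaries and run logging.

Every stage of the pipeline can be driven from a flat ``key = value``
configuration file so that a run can be restored, edited or re-executed.
Trained models are accompanied by a plain-text summary (model type, input
dimension, trained iterations, source dataset location, loss function) so a
weights file is never opaque.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError

__all__ = [
    "RunConfig",
    "parse_config",
    "serialize_config",
    "ModelSummary",
    "write_model_summary",
    "read_model_summary",
    "RunLogger",
]

# Keys whose values must parse as numbers; a non-numeric value is a
# configuration error rather than a silently-kept string.
NUMERIC_KEYS = {
    "alpha", "cycles", "roi_count", "k", "window", "window_width", "stride",
    "seed", "iterations", "epochs", "batch_size", "fid_every", "fid_batch",
    "z_dim", "z_scale", "multiplier", "scale", "n_blocks", "n_channels",
    "threshold", "train_fraction", "input_size", "n", "markers", "size",
    "jitter", "noise_sd", "learning_rate", "lambda_qp",
}


class RunConfig(dict):
    """Flat typed key→value map; round-trips through plain text."""


def _parse_value(key: str, raw: str, line_no: int):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        val: object = low == "true"
    else:
        try:
            val = int(raw)
        except ValueError:
            try:
                val = float(raw)
            except ValueError:
                val = raw
    if key in NUMERIC_KEYS:
        is_number = isinstance(val, (int, float)) and not isinstance(val, bool)
        if not is_number:
            raise ConfigError(f"key {key!r} requires a numeric value, got {raw!r}", line_no)
    return val


def parse_config(text: str) -> RunConfig:
    """Parse ``key = value`` lines (``#`` comments and blanks allowed)."""
    cfg = RunConfig()
    for line_no, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"expected 'key = value', got {stripped!r}", line_no)
        key, _, raw = stripped.partition("=")
        key = key.strip()
        if not key:
            raise ConfigError("empty key", line_no)
        cfg[key] = _parse_value(key, raw, line_no)
    return cfg


def _format_value(val) -> str:
    if isinstance(val, bool):
        return "true" if val else "false"
    return str(val)


def serialize_config(cfg: RunConfig) -> str:
    """Serialize to the canonical one-key-per-line form (insertion order)."""
    return "\n".join(f"{k} = {_format_value(v)}" for k, v in cfg.items()) + "\n"


@dataclass
class ModelSummary:
    """Human-readable description stored alongside trained weights."""

    model_type: str
    input_dim: tuple[int, int, int]
    trained_iterations: int
    dataset_location: str
    loss_function: str

    def __post_init__(self):
        for name in ("model_type", "dataset_location", "loss_function"):
            if not getattr(self, name):
                raise ValueError(f"ModelSummary field {name!r} must be set")
        self.input_dim = tuple(int(v) for v in self.input_dim)
        if len(self.input_dim) != 3:
            raise ValueError("input_dim must be (H, W, C)")
        self.trained_iterations = int(self.trained_iterations)


def write_model_summary(meta: ModelSummary, path: str | Path) -> None:
    h, w, c = meta.input_dim
    lines = [
        f"model_type = {meta.model_type}",
        f"input_dim = {h}x{w}x{c}",
        f"trained_iterations = {meta.trained_iterations}",
        f"dataset_location = {meta.dataset_location}",
        f"loss_function = {meta.loss_function}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_summary(path: str | Path) -> ModelSummary:
    cfg = parse_config(Path(path).read_text())
    missing = {"model_type", "input_dim", "trained_iterations",
               "dataset_location", "loss_function"} - set(cfg)
    if missing:
        raise ConfigError(f"model summary missing fields: {sorted(missing)}")
    dims = tuple(int(v) for v in str(cfg["input_dim"]).split("x"))
    return ModelSummary(
        model_type=str(cfg["model_type"]),
        input_dim=dims,  # type: ignore[arg-type]
        trained_iterations=int(cfg["trained_iterations"]),
        dataset_location=str(cfg["dataset_location"]),
        loss_function=str(cfg["loss_function"]),
    )


class RunLogger:
    """Timestamped append-only text log; ``path=None`` disables output."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None

    def log(self, message: str) -> None:
        if self.path is None:
            return
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        with open(self.path, "a") as fh:
            fh.write(f"[{stamp}] {message}\n")
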