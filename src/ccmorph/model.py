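"""Segmentation model family and training loss.

Two encoder families (compact double-conv and 18/34-layer residual) are
combined with either a full-resolution skip decoder (U-Net style) or a
feature-pyramid decoder, mirroring the architecture pairs used for
histology (34-layer residual + U-Net decoder + batch norm) and micro-CT
(18-layer residual + pyramid decoder + instance norm + spatial dropout).
A ``small`` preset (three down-blocks, 16 base channels) exists for
CPU-scale work.

The loss is the sum of mean binary cross-entropy and (1 - soft Jaccard),
weighted 1:1 by default: cross-entropy gives stable convergence while the
Jaccard term counteracts the class imbalance between the thin CC band and
the surrounding tissue.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn

_EPS_CLAMP = 1e-7

ENCODER_PRESETS = {
    "small": None,
    "18-layer-residual": (2, 2, 2, 2),
    "34-layer-residual": (3, 4, 6, 3),
}


@dataclass(frozen=True)
class ModelConfig:
    encoder_depth: str = "small"
    decoder_style: str = "full_resolution_skip"  # or "pyramid"
    normalization: str = "batch"  # or "instance"
    spatial_dropout_rate: float = 0.2
    base_channels: int = 16
    pretrained_init: bool = False
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_depth not in ENCODER_PRESETS:
            raise ValueError(f"encoder_depth must be one of {sorted(ENCODER_PRESETS)}")
        if self.decoder_style not in ("full_resolution_skip", "pyramid"):
            raise ValueError("decoder_style must be 'full_resolution_skip' or 'pyramid'")
        if self.normalization not in ("batch", "instance"):
            raise ValueError("normalization must be 'batch' or 'instance'")
        if not 0 <= self.spatial_dropout_rate < 1:
            raise ValueError("spatial_dropout_rate must be in [0, 1)")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")


#: Architecture presets matching the published modality choices.
HISTOLOGY_MODEL = ModelConfig(
    encoder_depth="34-layer-residual",
    decoder_style="full_resolution_skip",
    normalization="batch",
    spatial_dropout_rate=0.0,
    base_channels=64,
)
MICROCT_MODEL = ModelConfig(
    encoder_depth="18-layer-residual",
    decoder_style="pyramid",
    normalization="instance",
    spatial_dropout_rate=0.2,
    base_channels=64,
)


@dataclass(frozen=True)
class LossConfig:
    bce_weight: float = 1.0
    jaccard_weight: float = 1.0
    smoothing_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.bce_weight < 0 or self.jaccard_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.bce_weight + self.jaccard_weight <= 0:
            raise ValueError("at least one loss weight must be positive")
        if self.smoothing_eps <= 0:
            raise ValueError("smoothing_eps must be positive")


def build_model(cfg: ModelConfig) -> nn.SegNet:
    """Build a segmentation network from its configuration.

    The returned handle exposes ``predict(tile) -> probability tile`` and
    trainable parameters; output shape equals input shape for tiles whose
    sides are multiples of the encoder's downsampling factor (8 for the
    small preset, 16 for the residual presets). Weights are randomly
    initialized from ``cfg.seed``; ``pretrained_init`` is accepted for
    interface compatibility but no pretrained weights ship with this
    package, so it falls back to random initialization.
    """
    rng = np.random.default_rng(cfg.seed)
    preset = ENCODER_PRESETS[cfg.encoder_depth]
    if preset is None:
        encoder = nn.SmallEncoder(cfg.in_channels, cfg.base_channels, cfg.normalization, rng)
    else:
        encoder = nn.ResNetEncoder(cfg.in_channels, cfg.base_channels, preset, cfg.normalization, rng)
    if cfg.decoder_style == "full_resolution_skip":
        decoder = nn.UNetDecoder(encoder.channels, cfg.normalization, cfg.spatial_dropout_rate, rng)
    else:
        decoder = nn.FPNDecoder(encoder.channels, cfg.normalization, cfg.spatial_dropout_rate, rng)
    net = nn.SegNet(encoder, decoder)
    net.config = cfg
    return net


# ---------------------------------------------------------------------------
# losses


def _check_pair(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"pred/target shapes differ: {pred.shape} vs {target.shape}")
    if not np.all(np.isfinite(pred)):
        raise ValueError("pred contains non-finite values")
    return pred, target


def soft_jaccard(pred: np.ndarray, target, eps: float = _EPS_CLAMP) -> float:
    """Soft Jaccard index (Σ p·t + ε) / (Σp + Σt − Σ p·t + ε) in [0, 1].

    Equals the hard intersection-over-union on binary inputs (up to ε), and
    1.0 when both prediction and target are empty.
    """
    tvals = target.values if hasattr(target, "values") else target
    pred, tvals = _check_pair(pred, tvals)
    inter = float((pred * tvals).sum())
    union = float(pred.sum() + tvals.sum() - inter)
    return (inter + eps) / (union + eps)


def combined_loss(pred: np.ndarray, target, lc: LossConfig = LossConfig()) -> float:
    """bce_weight·BCE + jaccard_weight·(1 − soft Jaccard), both from probabilities."""
    loss, _ = combined_loss_and_grad(pred, target, lc)
    return loss


def combined_loss_and_grad(pred: np.ndarray, target, lc: LossConfig = LossConfig()):
    """Loss value and its gradient with respect to the predicted probabilities.

    BCE is the mean per-pixel binary cross-entropy with probabilities
    clamped to [1e-7, 1−1e-7] for numerical safety.
    """
    tvals = target.values if hasattr(target, "values") else target
    pred, t = _check_pair(pred, np.asarray(tvals))
    p = np.clip(pred, _EPS_CLAMP, 1.0 - _EPS_CLAMP)
    n = p.size

    bce = float(-(t * np.log(p) + (1 - t) * np.log1p(-p)).mean())
    g_bce = (-(t / p) + (1 - t) / (1 - p)) / n
    # clamped pixels have zero gradient through the clamp
    g_bce = np.where((pred > _EPS_CLAMP) & (pred < 1 - _EPS_CLAMP), g_bce, 0.0)

    eps = lc.smoothing_eps
    inter = float((p * t).sum())
    num = inter + eps
    den = float(p.sum() + t.sum() - inter) + eps
    jac = num / den
    g_jac = (t * den - num * (1 - t)) / den**2

    loss = lc.bce_weight * bce + lc.jaccard_weight * (1.0 - jac)
    grad = lc.bce_weight * g_bce + lc.jaccard_weight * (-g_jac)
    return loss, grad


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: nn.SegNet, path: str | Path) -> Path:
    """Save weights to ``path`` (npz payload) plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **model.state_arrays())
    cfg = getattr(model, "config", None)
    if cfg is not None:
        path.with_suffix(".json").write_text(json.dumps(asdict(cfg), indent=2))
    return path


def load_checkpoint(path: str | Path, cfg: ModelConfig | None = None) -> nn.SegNet:
    """Rebuild a model from a checkpoint and its JSON sidecar."""
    path = Path(path)
    if cfg is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"no ModelConfig sidecar at {sidecar}")
        cfg = ModelConfig(**json.loads(sidecar.read_text()))
    model = build_model(cfg)
    with np.load(path) as data:
        model.load_state_arrays(dict(data))
    return model
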