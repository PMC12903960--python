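"""The three-channel ddG regressor and its training loss.

Architecture (per forward pass):

1. each of three per-residue embedding channels (L x D_c) is projected by
   two affine layers with a ReLU between them to L x 256;
2. a fixed sinusoidal positional encoding is added;
3. a dedicated two-layer transformer encoder (4-head self-attention,
   feedforward, dropout, residual connections, layer normalization)
   contextualizes each channel independently;
4. the mutation-site (center) row is extracted from each channel output
   and the three vectors are concatenated into one 768-d vector;
5. an MLP head (256 -> 128 -> 1) regresses the ddG in kcal/mol.

Training minimizes the pseudo-Huber loss
``L_delta(a) = delta^2 (sqrt(1 + ((y_true - y_pred)/delta)^2) - 1)``,
quadratic near zero error and asymptotically linear for large errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import CompatibilityError, ConfigurationError, ShapeError
from .nn import Linear, Module, Parameter, Tensor, TransformerEncoderLayer


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the regressor; defaults mirror the reference
    three-channel setup (ESM-2 / ESM-1v / ProtTrans widths, 181-residue
    windows, 256-d projection, 2 encoder layers with 4 heads)."""

    window_length: int = 181
    channel_dims: tuple[int, ...] = (1280, 1280, 1024)
    projected_dim: int = 256
    encoder_layers: int = 2
    attention_heads: int = 4
    feedforward_dim: int = 512
    dropout: float = 0.1
    head_hidden: tuple[int, ...] = (256, 128)
    output_dim: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length < 1:
            raise ConfigurationError("window_length must be odd and positive")
        if len(self.channel_dims) != 3:
            raise ConfigurationError("exactly three channels are expected")
        if self.projected_dim % self.attention_heads:
            raise ConfigurationError(
                "projected_dim must be divisible by attention_heads"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")

    @property
    def fused_dim(self) -> int:
        return 3 * self.projected_dim

    @property
    def center_offset(self) -> int:
        return (self.window_length - 1) // 2


@dataclass(frozen=True)
class LossConfig:
    """Pseudo-Huber transition scale delta (kcal/mol)."""

    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ConfigurationError(f"delta must be positive, got {self.delta}")


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal position table (length x dim), values in [-1, 1]."""
    if dim % 2:
        raise ConfigurationError(f"positional encoding dim must be even, got {dim}")
    pos = np.arange(length, dtype=np.float64)[:, None]
    j = np.arange(dim)[None, :]
    angle = pos / (10000.0 ** (2 * (j // 2) / dim))
    return np.where(j % 2 == 0, np.sin(angle), np.cos(angle))


def pseudo_huber_loss(
    y_true: np.ndarray | float, y_pred: np.ndarray | float,
    loss: LossConfig = LossConfig(),
) -> float:
    """Mean pseudo-Huber loss over prediction pairs (scalar inputs allowed)."""
    d = loss.delta
    a = (np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)) / d
    return float(np.mean(d * d * (np.sqrt(1.0 + a * a) - 1.0)))


def _pseudo_huber_tensor(pred: Tensor, target: np.ndarray, delta: float) -> Tensor:
    a = (pred - Tensor(target)) * (1.0 / delta)
    inner = (a.square() + 1.0).sqrt() + (-1.0)
    return inner.mean() * (delta * delta)


class DdgRegressor(Module):
    """Three-channel transformer regressor for mutation-induced ddG."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.projected_dim
        self.proj1 = [
            Linear(dc, d, rng, f"proj1.{i}")
            for i, dc in enumerate(config.channel_dims)
        ]
        self.proj2 = [Linear(d, d, rng, f"proj2.{i}") for i in range(3)]
        self.encoders = [
            [
                TransformerEncoderLayer(
                    d, config.attention_heads, config.feedforward_dim,
                    config.dropout, rng, f"enc.{i}.{l}",
                )
                for l in range(config.encoder_layers)
            ]
            for i in range(3)
        ]
        dims = (config.fused_dim,) + tuple(config.head_hidden) + (config.output_dim,)
        self.head = [
            Linear(a, b, rng, f"head.{j}")
            for j, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
        ]
        self._pe = positional_encoding(config.window_length, d)

    def parameters(self) -> list[Parameter]:
        out = []
        for lin in self.proj1 + self.proj2 + self.head:
            out.extend(lin.parameters())
        for channel in self.encoders:
            for layer in channel:
                out.extend(layer.parameters())
        return out

    def forward(
        self,
        channel_inputs: list[np.ndarray],
        train_rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Run a batch; returns (predictions (B,), fused vectors (B, 768)).

        ``channel_inputs[i]`` has shape (B, L, channel_dims[i]).  Pass a
        generator to enable dropout (training); None runs in eval mode.
        """
        cfg = self.config
        if len(channel_inputs) != 3:
            raise ShapeError(f"expected 3 channels, got {len(channel_inputs)}")
        site_vectors = []
        for i, raw in enumerate(channel_inputs):
            x = np.asarray(raw, dtype=np.float64)
            if x.ndim == 2:
                x = x[None]
            if x.shape[1:] != (cfg.window_length, cfg.channel_dims[i]):
                raise ShapeError(
                    f"channel {i}: shape {x.shape[1:]} does not match "
                    f"({cfg.window_length}, {cfg.channel_dims[i]})"
                )
            if not np.all(np.isfinite(x)):
                raise ShapeError(f"channel {i}: non-finite input values")
            t = Tensor(x)
            t = self.proj2[i](self.proj1[i](t).relu())
            t = t + Tensor(self._pe)
            for layer in self.encoders[i]:
                t = layer(t, train_rng)
            site_vectors.append(t.select_row(cfg.center_offset))
        fused = nn.concat_last(site_vectors)  # (B, 3 * projected_dim)
        h = fused
        for j, lin in enumerate(self.head):
            h = lin(h)
            if j < len(self.head) - 1:
                h = h.relu()
        return h.reshape(h.shape[0]), fused

    def predict(self, channel_inputs: list[np.ndarray]) -> np.ndarray:
        """Deterministic eval-mode predictions as a plain array."""
        preds, _ = self.forward(channel_inputs, train_rng=None)
        return preds.data.copy()

    def loss(
        self,
        channel_inputs: list[np.ndarray],
        targets: np.ndarray,
        loss_config: LossConfig = LossConfig(),
        train_rng: np.random.Generator | None = None,
    ) -> Tensor:
        preds, _ = self.forward(channel_inputs, train_rng)
        return _pseudo_huber_tensor(preds, np.asarray(targets, float),
                                    loss_config.delta)


# ---------------------------------------------------------------------------
# checkpoints

_CKPT_VERSION = 1


def save_checkpoint(
    model: DdgRegressor,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Save weights + config + training metadata to one .npz file."""
    header = {
        "version": _CKPT_VERSION,
        "config": asdict(model.config),
        "metadata": metadata or {},
    }
    state = model.state_dict()
    np.savez_compressed(
        Path(path), __header__=np.array(json.dumps(header)), **state
    )


def load_checkpoint(
    path: str | Path, expect_config: ModelConfig | None = None
) -> tuple[DdgRegressor, dict]:
    """Rebuild a model from a checkpoint; returns (model, metadata).

    If ``expect_config`` is given it must match the stored config exactly.
    """
    with np.load(Path(path), allow_pickle=False) as z:
        header = json.loads(str(z["__header__"]))
        state = {k: z[k] for k in z.files if k != "__header__"}
    cfg_dict = dict(header["config"])
    for key in ("channel_dims", "head_hidden"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    if expect_config is not None and expect_config != config:
        raise CompatibilityError(
            f"checkpoint config {config} does not match expected {expect_config}"
        )
    model = DdgRegressor(config)
    model.load_state_dict(state)
    return model, header["metadata"]
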