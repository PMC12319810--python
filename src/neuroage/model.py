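"""The brain-age regression network.

The architecture is a hierarchical 3D convolutional encoder built from
MedNeXt-style residual blocks, followed by a global-average-pool
regression head. Each block mirrors the transformer-inspired
depthwise/expand/compress pattern:

* a depthwise k^3 convolution captures spatial structure per channel,
* a pointwise expansion (x ``expansion_ratio`` channels) with a GELU
  nonlinearity enriches the representation,
* a pointwise compression maps back to the block width,

with a residual connection around the triplet and an instance-style
per-channel normalization after the depthwise step (chosen for stability
at small batch sizes). Stages are separated by stride-2 convolutions that
halve each spatial dimension and double the channel width. The head
applies 3D global average pooling, a hidden fully connected layer with
ReLU and dropout 0.2, and a final fully connected layer with ReLU — so
the predicted age is a single nonnegative scalar.

The network is implemented on the package's own numpy layer kernels
(:mod:`neuroage._nn`); in eval mode a forward pass is bit-deterministic.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigError, ShapeError

__all__ = [
    "ModelConfig",
    "MedNeXtBlock",
    "BrainAgeModel",
    "build_model",
    "predict_single",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    n_stages: int = 4
    blocks_per_stage: tuple[int, ...] | None = None
    base_channels: int = 8
    kernel_size: int = 3
    expansion_ratio: int = 2
    downsample_factor: int = 2
    fc_hidden: int = 64
    dropout_p: float = 0.2
    input_dims: tuple[int, int, int] = (160, 192, 160)
    output_bias_init: float = 50.0  # mid-lifespan prior for the age output

    def __post_init__(self):
        if self.n_stages < 1 or self.base_channels < 1 or self.fc_hidden < 1:
            raise ConfigError("stage/channel/hidden counts must be positive")
        if self.kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError("dropout_p must be in [0, 1)")
        blocks = self.resolved_blocks
        if len(blocks) != self.n_stages or any(b < 1 for b in blocks):
            raise ConfigError("blocks_per_stage must give >= 1 block per stage")
        total_down = self.downsample_factor ** (self.n_stages - 1)
        if any(d % total_down for d in self.input_dims):
            raise ConfigError(
                f"input_dims {self.input_dims} not divisible by the "
                f"cumulative downsampling factor {total_down}"
            )

    @property
    def resolved_blocks(self) -> tuple[int, ...]:
        if self.blocks_per_stage is None:
            return (1,) * self.n_stages
        return tuple(self.blocks_per_stage)

    @property
    def stage_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**s for s in range(self.n_stages))


class MedNeXtBlock(_nn.Layer):
    """Residual depthwise -> expand(GELU) -> compress unit."""

    def __init__(self, channels, kernel_size, ratio, rng):
        self.dw = _nn.DepthwiseConv3d(channels, kernel_size, rng)
        self.norm = _nn.ChannelNorm(channels)
        self.expand = _nn.PointwiseConv(channels, channels * ratio, rng)
        self.act = _nn.GELU()
        self.compress = _nn.PointwiseConv(channels * ratio, channels, rng)

    def params(self):
        for sub in (self.dw, self.norm, self.expand, self.act, self.compress):
            yield from sub.params()

    def named_subs(self):
        return [
            ("dw", self.dw), ("norm", self.norm), ("expand", self.expand),
            ("compress", self.compress),
        ]

    def forward(self, x, *, train=False, rng=None):
        h = self.dw.forward(x, train=train, rng=rng)
        h = self.norm.forward(h, train=train, rng=rng)
        h = self.expand.forward(h, train=train, rng=rng)
        h = self.act.forward(h, train=train, rng=rng)
        h = self.compress.forward(h, train=train, rng=rng)
        return x + h

    def backward(self, gy):
        gh = self.compress.backward(gy)
        gh = self.act.backward(gh)
        gh = self.expand.backward(gh)
        gh = self.norm.backward(gh)
        gh = self.dw.backward(gh)
        return gy + gh


class BrainAgeModel:
    """Volume -> nonnegative scalar age, with explicit train/eval modes."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.stem = _nn.PointwiseConv(1, config.base_channels, rng)
        self.stages: list[list[MedNeXtBlock]] = []
        self.downsamples: list[_nn.Downsample] = []
        channels = config.stage_channels
        for s, n_blocks in enumerate(config.resolved_blocks):
            self.stages.append(
                [
                    MedNeXtBlock(
                        channels[s], config.kernel_size,
                        config.expansion_ratio, rng,
                    )
                    for _ in range(n_blocks)
                ]
            )
            if s < config.n_stages - 1:
                self.downsamples.append(
                    _nn.Downsample(channels[s], channels[s + 1], rng)
                )
        self.pool = _nn.GlobalAvgPool()
        self.fc1 = _nn.Dense(channels[-1], config.fc_hidden, rng)
        self.relu1 = _nn.ReLU()
        self.dropout = _nn.Dropout(config.dropout_p)
        self.fc2 = _nn.Dense(
            config.fc_hidden, 1, rng, bias_init=config.output_bias_init
        )
        self.relu2 = _nn.ReLU()

    # ------------------------------------------------------------------ #

    def _ordered_layers(self):
        layers: list[tuple[str, _nn.Layer]] = [("stem", self.stem)]
        for s, blocks in enumerate(self.stages):
            for b, block in enumerate(blocks):
                layers.append((f"stage{s}.block{b}", block))
            if s < len(self.downsamples):
                layers.append((f"down{s}", self.downsamples[s]))
        layers += [
            ("pool", self.pool), ("fc1", self.fc1), ("relu1", self.relu1),
            ("dropout", self.dropout), ("fc2", self.fc2), ("relu2", self.relu2),
        ]
        return layers

    def params(self):
        for _, layer in self._ordered_layers():
            yield from layer.params()

    def named_params(self):
        out = []
        for lname, layer in self._ordered_layers():
            if isinstance(layer, MedNeXtBlock):
                for sname, sub in layer.named_subs():
                    for attr in ("w", "b", "gamma", "beta"):
                        if hasattr(sub, attr):
                            out.append((f"{lname}.{sname}.{attr}", getattr(sub, attr)))
            else:
                for attr in ("w", "b"):
                    if hasattr(layer, attr):
                        out.append((f"{lname}.{attr}", getattr(layer, attr)))
        return out

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # ------------------------------------------------------------------ #

    def forward(self, x: np.ndarray, *, train=False, rng=None) -> np.ndarray:
        """Batched forward pass: (B, D, H, W) -> (B,) predicted ages."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != tuple(self.config.input_dims):
            raise ShapeError(
                f"input dims {x.shape[1:]} != configured "
                f"{self.config.input_dims}"
            )
        h = x[:, None]  # add the single input channel
        for _, layer in self._ordered_layers():
            h = layer.forward(h, train=train, rng=rng)
        return h[:, 0]

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients for dLoss/dOutput ``gy`` (B,)."""
        g = np.ascontiguousarray(gy, dtype=np.float32)[:, None]
        for _, layer in reversed(self._ordered_layers()):
            g = layer.backward(g)

    def predict(self, volume: np.ndarray) -> float:
        """Deterministic single-volume inference (eval mode)."""
        return float(self.forward(volume, train=False)[0])

    def get_state(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_params()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_params():
            p.value[...] = state[name]


def build_model(config: ModelConfig, seed: int = 0) -> BrainAgeModel:
    """Construct and randomly initialize a model from its configuration."""
    return BrainAgeModel(config, seed=seed)


def predict_single(model: BrainAgeModel, volume: np.ndarray) -> float:
    """Predict the raw (pre-bias-correction) age of one volume."""
    return model.predict(volume)


def save_checkpoint(model: BrainAgeModel, path, provenance: dict | None = None):
    """Serialize weights + config (+ provenance) to an .npz file.

    Weights round-trip bit-exactly.
    """
    meta = {
        "config": asdict(model.config),
        "provenance": provenance or {},
    }
    arrays = {f"param::{n}": p.value for n, p in model.named_params()}
    np.savez(
        Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **arrays,
    )


def load_checkpoint(path) -> tuple[BrainAgeModel, dict]:
    """Rebuild a model from a checkpoint; returns (model, provenance)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = dict(meta["config"])
        for key in ("blocks_per_stage", "input_dims"):
            if cfg_dict.get(key) is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        model = BrainAgeModel(config, seed=0)
        state = {
            key[len("param::"):]: data[key]
            for key in data.files
            if key.startswith("param::")
        }
    model.set_state(state)
    return model, meta["provenance"]
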