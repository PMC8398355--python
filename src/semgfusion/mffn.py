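"""Multiple-feature-fusion network: a DenseNet-style feature extractor.

The network is a stem convolution (7x7/2) + max pool, followed by two
dense blocks (6 and 12 composite layers) separated by transition layers.
Each composite layer is BN-ReLU-Conv(1x1)-BN-ReLU-Conv(3x3) and receives
the concatenation of the block input and every previous layer's output,
so an L-layer block realizes L(L+1)/2 direct connections.  Transition
layers (BN-ReLU-Conv 1x1-AvgPool 2x2) halve the spatial size and
compress channels by a factor theta.  Features are read out after the
second transition layer: a 14x14x256 map, flattened to 50,176 values,
for the default 224x224x3 input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .representation import RGBImage

__all__ = [
    "ShapeError",
    "MFFNConfig",
    "ShapePlan",
    "FeatureMap",
    "DenseBlock",
    "Transition",
    "FeatureExtractor",
    "build_mffn",
    "shape_plan",
    "dense_block_forward",
    "transition_forward",
    "extract_features",
    "channel_mean_profile",
]


class ShapeError(ValueError):
    """A stage's spatial size is incompatible with its stride chain."""


@dataclass(frozen=True)
class MFFNConfig:
    input_size: int = 224
    input_planes: int = 3
    stem_filters: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_padding: int = 3
    pool_kernel: int = 3
    pool_stride: int = 2
    pool_padding: int = 1
    block_sizes: tuple[int, ...] = (6, 12)
    growth_rate: int = 32
    bottleneck_factor: int = 4
    compression: float = 0.5
    transition_pool: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be positive")
        if not (0 < self.compression <= 1):
            raise ValueError("compression must be in (0, 1]")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be >= 1")


@dataclass(frozen=True)
class ShapePlan:
    """Symbolic per-stage output shapes (height, width, channels)."""

    stages: tuple[tuple[str, int, int, int], ...]

    def stage(self, name: str) -> tuple[int, int, int]:
        for n, h, w, c in self.stages:
            if n == name:
                return (h, w, c)
        raise KeyError(name)

    @property
    def flatten_length(self) -> int:
        h, w, c = self.stages[-1][1:]
        return h * w * c


def _conv_out(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def shape_plan(config: MFFNConfig) -> ShapePlan:
    """Propagate shapes through the layer plan without allocating a model."""
    h = w = config.input_size
    stages = [("input", h, w, config.input_planes)]
    h = _conv_out(h, config.stem_kernel, config.stem_stride, config.stem_padding)
    w = _conv_out(w, config.stem_kernel, config.stem_stride, config.stem_padding)
    c = config.stem_filters
    stages.append(("convolution", h, w, c))
    h = _conv_out(h, config.pool_kernel, config.pool_stride, config.pool_padding)
    w = _conv_out(w, config.pool_kernel, config.pool_stride, config.pool_padding)
    stages.append(("pooling", h, w, c))
    for i, L in enumerate(config.block_sizes, start=1):
        c = c + L * config.growth_rate
        stages.append((f"dense_block_{i}", h, w, c))
        if h % config.transition_pool or w % config.transition_pool:
            raise ShapeError(
                f"transition {i} needs spatial dims divisible by "
                f"{config.transition_pool}, got {h}x{w}"
            )
        c = int(np.floor(config.compression * c))
        h //= config.transition_pool
        w //= config.transition_pool
        stages.append((f"transition_{i}", h, w, c))
    return ShapePlan(stages=tuple(stages))


class _DenseLayer(nn.Layer):
    """BN-ReLU-Conv(1x1, 4k)-BN-ReLU-Conv(3x3, k) composite."""

    def __init__(self, c_in: int, growth: int, bottleneck_factor: int,
                 rng: np.random.Generator):
        width = bottleneck_factor * growth
        self.c_in = c_in
        self.net = nn.Sequential(
            nn.BatchNorm2d(c_in),
            nn.ReLU(),
            nn.Conv2d(c_in, width, 1, rng=rng),
            nn.BatchNorm2d(width),
            nn.ReLU(),
            nn.Conv2d(width, growth, 3, padding=1, rng=rng),
        )

    def params(self):
        return self.net.params()

    def train(self):
        self.net.train()

    def eval(self):
        self.net.eval()

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, dy):
        return self.net.backward(dy)


class DenseBlock(nn.Layer):
    """L composite layers with full dense connectivity."""

    def __init__(self, c_in: int, n_layers: int, growth: int,
                 bottleneck_factor: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.growth = c_in, growth
        self.layers = [
            _DenseLayer(c_in + j * growth, growth, bottleneck_factor, rng)
            for j in range(n_layers)
        ]

    @property
    def wiring(self) -> list[list[int]]:
        """Feature indices consumed by each layer (0 = block input)."""
        return [list(range(j + 1)) for j in range(len(self.layers))]

    @property
    def n_connections(self) -> int:
        return sum(len(w) for w in self.wiring)

    @property
    def c_out(self) -> int:
        return self.c_in + len(self.layers) * self.growth

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def train(self):
        for l in self.layers:
            l.train()

    def eval(self):
        for l in self.layers:
            l.eval()

    def forward(self, x):
        feats = [x]
        for layer in self.layers:
            feats.append(layer.forward(np.concatenate(feats, axis=1)))
        self._channels = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, dy):
        # split grad of the final concatenation into per-feature grads
        bounds = np.cumsum([0] + self._channels)
        grads = [dy[:, bounds[i] : bounds[i + 1]].copy() for i in range(len(self._channels))]
        for j in reversed(range(len(self.layers))):
            dinp = self.layers[j].backward(grads[j + 1])
            in_channels = self._channels[: j + 1]
            ib = np.cumsum([0] + in_channels)
            for i in range(j + 1):
                grads[i] += dinp[:, ib[i] : ib[i + 1]]
        return grads[0]


class Transition(nn.Layer):
    """BN-ReLU-Conv(1x1, theta*c)-AvgPool(2x2, stride 2)."""

    def __init__(self, c_in: int, compression: float = 0.5, pool: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.pool = pool
        self.c_out = int(np.floor(compression * c_in))
        self.net = nn.Sequential(
            nn.BatchNorm2d(c_in),
            nn.ReLU(),
            nn.Conv2d(c_in, self.c_out, 1, rng=rng),
            nn.AvgPool2d(pool, pool),
        )

    def params(self):
        return self.net.params()

    def train(self):
        self.net.train()

    def eval(self):
        self.net.eval()

    def forward(self, x):
        if x.shape[2] % self.pool or x.shape[3] % self.pool:
            raise ShapeError(
                f"transition needs even spatial dims, got {x.shape[2]}x{x.shape[3]}"
            )
        return self.net.forward(x)

    def backward(self, dy):
        return self.net.backward(dy)


class FeatureExtractor(nn.Layer):
    """Stem + dense blocks + transitions; features read after the last transition."""

    def __init__(self, config: MFFNConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.plan = shape_plan(config)
        self.stem = nn.Sequential(
            nn.Conv2d(config.input_planes, config.stem_filters, config.stem_kernel,
                      stride=config.stem_stride, padding=config.stem_padding, rng=rng),
            nn.BatchNorm2d(config.stem_filters),
            nn.ReLU(),
            nn.MaxPool2d(config.pool_kernel, config.pool_stride, config.pool_padding),
        )
        self.blocks: list[DenseBlock] = []
        self.transitions: list[Transition] = []
        c = config.stem_filters
        for L in config.block_sizes:
            block = DenseBlock(c, L, config.growth_rate, config.bottleneck_factor, rng)
            self.blocks.append(block)
            trans = Transition(block.c_out, config.compression, config.transition_pool, rng)
            self.transitions.append(trans)
            c = trans.c_out
        self.stage_shapes: dict[str, tuple[int, ...]] = {}

    def params(self):
        ps = self.stem.params()
        for b, t in zip(self.blocks, self.transitions):
            ps += b.params() + t.params()
        return ps

    def train(self):
        self.training = True
        self.stem.train()
        for b, t in zip(self.blocks, self.transitions):
            b.train()
            t.train()

    def eval(self):
        self.training = False
        self.stem.eval()
        for b, t in zip(self.blocks, self.transitions):
            b.eval()
            t.eval()

    def forward(self, x):
        # stem records the conv and pool stages separately for shape checks
        h = self.stem.layers[0].forward(x)
        self.stage_shapes["convolution"] = h.shape[1:]
        h = self.stem.layers[1].forward(h)
        h = self.stem.layers[2].forward(h)
        h = self.stem.layers[3].forward(h)
        self.stage_shapes["pooling"] = h.shape[1:]
        for i, (block, trans) in enumerate(zip(self.blocks, self.transitions), start=1):
            h = block.forward(h)
            self.stage_shapes[f"dense_block_{i}"] = h.shape[1:]
            h = trans.forward(h)
            self.stage_shapes[f"transition_{i}"] = h.shape[1:]
        return h

    def backward(self, dy):
        for block, trans in zip(reversed(self.blocks), reversed(self.transitions)):
            dy = trans.backward(dy)
            dy = block.backward(dy)
        return self.stem.backward(dy)


def build_mffn(config: MFFNConfig | None = None) -> FeatureExtractor:
    return FeatureExtractor(config or MFFNConfig())


@dataclass
class FeatureMap:
    """Extraction-point features, [H x W x C], plus the flattened vector."""

    array: np.ndarray

    def __post_init__(self) -> None:
        if self.array.ndim != 3:
            raise ValueError("feature map must be [H, W, C]")
        if not np.all(np.isfinite(self.array)):
            raise ValueError("feature map contains NaN/Inf")

    @property
    def flatten(self) -> np.ndarray:
        return self.array.reshape(-1)


def _to_batch(image) -> np.ndarray:
    """RGBImage / [H,W,3] / [N,H,W,3] -> NCHW float array."""
    if isinstance(image, RGBImage):
        arr = image.pixels
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ShapeError("expected [H, W, 3] or [N, H, W, 3] image data")
    return np.transpose(arr, (0, 3, 1, 2))


def extract_features(model: FeatureExtractor, image) -> FeatureMap | list[FeatureMap]:
    """Run the extractor in evaluation mode; returns [H x W x C] features."""
    single = isinstance(image, RGBImage) or np.asarray(image).ndim == 3
    batch = _to_batch(image)
    if batch.shape[2] != model.config.input_size or batch.shape[3] != model.config.input_size:
        raise ShapeError(
            f"image size {batch.shape[2]}x{batch.shape[3]} != "
            f"configured {model.config.input_size}"
        )
    model.eval()
    out = model.forward(batch)  # [N, C, h, w]
    maps = [FeatureMap(array=np.transpose(o, (1, 2, 0))) for o in out]
    return maps[0] if single else maps


def dense_block_forward(x: np.ndarray, n_layers: int, growth: int,
                        bottleneck_factor: int = 4, seed: int = 0) -> np.ndarray:
    """Functional dense-block pass; n_layers = 0 is the identity."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if n_layers == 0:
        out = x
    else:
        block = DenseBlock(x.shape[1], n_layers, growth, bottleneck_factor,
                           np.random.default_rng(seed))
        block.eval()
        out = block.forward(x)
    return out[0] if squeeze else out


def transition_forward(x: np.ndarray, compression: float = 0.5, seed: int = 0) -> np.ndarray:
    """Functional transition pass: channel compression + 2x2 average pool."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    trans = Transition(x.shape[1], compression, rng=np.random.default_rng(seed))
    trans.eval()
    out = trans.forward(x)
    return out[0] if squeeze else out


def channel_mean_profile(fm: FeatureMap) -> np.ndarray:
    """Spatial mean of each feature channel: [C] vector."""
    return fm.array.mean(axis=(0, 1))
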