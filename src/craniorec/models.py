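"""Two-stage cranial shape-completion network.

Stage one is a volumetric residual encoder--decoder (ResUNet-style): four
encoder levels of residual blocks with 2x max-pooling between them (the
deepest level acting as bottleneck), a mirrored three-level decoder using
transposed-convolution upsampling with encoder features concatenated in at
each level, and a final 1^3 convolution + sigmoid producing a one-channel
occupancy probability at the input resolution.  Fed a defected skull mask,
it is trained to emit the complete (healthy) skull.

Stage two is a lightweight 2x resolution-enhancement network: a small
conv/pool encoder, two transposed-convolution upsamplings to twice the
input size, and a fusion head that concatenates the learned feature
channels with a trilinearly interpolated copy of the input (default
16 + 1 = 17 fused channels) before a final convolution + sigmoid.

Channel widths are configurable; the defaults are desk-scale (base 8).
Parameter counts are a pure function of the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, InputError
from . import nn
from .volio import BinaryVolume, Volume

__all__ = [
    "ModelConfig",
    "NetworkHandle",
    "build_reconstruction_net",
    "build_enhancement_net",
    "forward_reconstruct",
    "forward_enhance",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture sizing.

    ``levels`` encoder levels (the last is the bottleneck; ``levels - 1``
    decoder levels mirror it); channels at level l are
    ``base_channels * growth**(l-1)``.  Input dims must be divisible by
    ``2**levels``.
    """

    input_dims: tuple = (64, 64, 32)
    levels: int = 4
    base_channels: int = 8
    growth: int = 2
    use_residual: bool = True
    enhancement_feature_channels: int = 16
    binarize_tau: float = 0.5

    def __post_init__(self):
        if self.base_channels < 1 or self.levels < 1:
            raise ConfigError("base_channels and levels must be >= 1")
        div = 2**self.levels
        if any(d % div for d in self.input_dims):
            raise ConfigError(
                f"input_dims {self.input_dims} must be divisible by 2^levels={div}"
            )

    def channels(self) -> list[int]:
        return [self.base_channels * self.growth**l for l in range(self.levels)]


class _ReconstructionNet:
    """Residual encoder-decoder with skip concatenation."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = cfg.channels()
        self.enc = []
        cin = 1
        for c in ch:
            self.enc.append(nn.ResBlock(cin, c, rng))
            cin = c
        self.pools = [nn.MaxPool3d() for _ in range(cfg.levels - 1)]
        self.ups = []
        self.dec = []
        for l in range(cfg.levels - 2, -1, -1):
            self.ups.append(nn.ConvTranspose3d(ch[l + 1], ch[l], rng))
            self.dec.append(nn.ResBlock(2 * ch[l], ch[l], rng))
        self.final = nn.Conv3d(ch[0], 1, 1, rng)
        self.sigmoid = nn.Sigmoid()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        skips = []
        h = x
        for l, block in enumerate(self.enc):
            h = block.forward(h, training)
            if l < len(self.pools):
                skips.append(h)
                h = self.pools[l].forward(h, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, training)
        return self.sigmoid.forward(self.final.forward(h, training))

    def backward(self, dprob: np.ndarray) -> None:
        d = self.final.backward(self.sigmoid.backward(dprob))
        dskips = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.dec), self._skip_channels
        ):
            d = dec.backward(d)
            dskip, d = d[:, :c_skip], d[:, c_skip:]
            dskips.append(dskip)
            d = up.backward(d)
        # dskips[l] is the gradient for encoder level l's pre-pool output
        for l in range(len(self.enc) - 1, -1, -1):
            if l < len(self.pools):
                d = self.pools[l].backward(d)
                d = d + dskips[l]
            d = self.enc[l].backward(d)

    def _children(self):
        return list(self.enc) + list(self.ups) + list(self.dec) + [self.final]

    def params(self):
        return [p for c in self._children() for p in c.params()]

    def buffers(self):
        return [b for c in self._children() for b in c.buffers()]


class _EnhancementNet:
    """2x super-resolution head with an interpolated input pathway."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        c = cfg.base_channels
        f = cfg.enhancement_feature_channels
        self.conv1 = nn.Conv3d(1, c, 3, rng)
        self.bn1 = nn.BatchNorm3d(c)
        self.relu1 = nn.ReLU()
        self.pool = nn.MaxPool3d()
        self.conv2 = nn.Conv3d(c, 2 * c, 3, rng)
        self.bn2 = nn.BatchNorm3d(2 * c)
        self.relu2 = nn.ReLU()
        self.up1 = nn.ConvTranspose3d(2 * c, c, rng)
        self.relu3 = nn.ReLU()
        self.up2 = nn.ConvTranspose3d(c, f, rng)
        self.relu4 = nn.ReLU()
        self.final = nn.Conv3d(f + 1, 1, 3, rng)
        self.sigmoid = nn.Sigmoid()
        self.fused_channels = f + 1

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        h = self.pool.forward(h, training)
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, training), training))
        h = self.relu3.forward(self.up1.forward(h, training))
        h = self.relu4.forward(self.up2.forward(h, training))
        interp = nn.trilinear_upsample2(np.asarray(x, dtype=np.float32))
        fused = np.concatenate([h, interp], axis=1)
        return self.sigmoid.forward(self.final.forward(fused, training))

    def backward(self, dprob: np.ndarray) -> None:
        d = self.final.backward(self.sigmoid.backward(dprob))
        d = d[:, : self.cfg.enhancement_feature_channels]  # interp path: no params
        d = self.up2.backward(self.relu4.backward(d))
        d = self.up1.backward(self.relu3.backward(d))
        d = self.conv2.backward(self.bn2.backward(self.relu2.backward(d)))
        d = self.pool.backward(d)
        self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))

    def _children(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.up1, self.up2,
                self.final]

    def params(self):
        return [p for c in self._children() for p in c.params()]

    def buffers(self):
        return [b for c in self._children() for b in c.buffers()]


@dataclass
class NetworkHandle:
    """Opaque handle around a network plus its config."""

    net: object
    config: ModelConfig
    kind: str  # "reconstruction" | "enhancement"

    @property
    def parameter_count(self) -> int:
        return count_parameters(self)


def build_reconstruction_net(cfg: ModelConfig, seed: int = 0) -> NetworkHandle:
    """Build the (seeded, untrained) reconstruction network."""
    rng = np.random.default_rng(seed)
    return NetworkHandle(net=_ReconstructionNet(cfg, rng), config=cfg,
                         kind="reconstruction")


def build_enhancement_net(cfg: ModelConfig, seed: int = 0) -> NetworkHandle:
    """Build the (seeded, untrained) 2x enhancement network."""
    rng = np.random.default_rng(seed)
    return NetworkHandle(net=_EnhancementNet(cfg, rng), config=cfg,
                         kind="enhancement")


def count_parameters(handle: NetworkHandle) -> int:
    """Total trainable scalar parameters."""
    return sum(p.value.size for p in handle.net.params() if p.trainable)


def _as_batch(vol) -> np.ndarray:
    vox = vol.voxels if isinstance(vol, Volume) else np.asarray(vol)
    return vox.astype(np.float32)[None, None]


def forward_reconstruct(handle: NetworkHandle, defected) -> np.ndarray:
    """Inference pass: defected skull mask -> occupancy probabilities.

    Deterministic (batch-norm uses running statistics).
    """
    if handle.kind != "reconstruction":
        raise InputError("handle is not a reconstruction network")
    x = _as_batch(defected)
    if x.shape[2:] != tuple(handle.config.input_dims):
        raise InputError(
            f"input dims {x.shape[2:]} do not match config {handle.config.input_dims}"
        )
    prob = handle.net.forward(x, training=False)
    return prob[0, 0]


def forward_enhance(handle: NetworkHandle, low_res) -> np.ndarray:
    """Inference pass: low-res mask -> 2x-resolution probabilities."""
    if handle.kind != "enhancement":
        raise InputError("handle is not an enhancement network")
    prob = handle.net.forward(_as_batch(low_res), training=False)
    return prob[0, 0]


def save_checkpoint(handle: NetworkHandle, path) -> None:
    """Self-describing checkpoint: config + all parameters and buffers."""
    arrays = {f"p{i}": p.value for i, p in enumerate(handle.net.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(handle.net.buffers())})
    meta = json.dumps({"kind": handle.kind, "config": asdict(handle.config)})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path) -> NetworkHandle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["input_dims"] = tuple(cfg_d["input_dims"])
        cfg = ModelConfig(**cfg_d)
        builder = (build_reconstruction_net if meta["kind"] == "reconstruction"
                   else build_enhancement_net)
        handle = builder(cfg, seed=0)
        for i, p in enumerate(handle.net.params()):
            p.value = data[f"p{i}"].astype(np.float32)
            p.grad = np.zeros_like(p.value)
        for i, b in enumerate(handle.net.buffers()):
            b[...] = data[f"b{i}"]
    return handle
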