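"""U-Net for 10-class tissue segmentation.

Standard encoder-decoder with skip connections; every convolution is
preceded by reflection padding so the output resolution equals the input
resolution at every level, batch normalisation follows each convolution and
leaky ReLU is the activation. The final layer is a per-pixel softmax over
the tissue classes. Decoder upsampling is nearest-neighbour followed by a
convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ..imageio import N_CLASSES, TissueClass
from . import nn


@dataclass(frozen=True)
class NetConfig:
    depth: int = 5
    base_channels: int = 32
    leaky_slope: float = 0.01
    batch_norm: bool = True
    n_classes: int = N_CLASSES
    in_channels: int = 3
    tile_px: int = 512
    max_channels: int = 256

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.tile_px % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"tile size {self.tile_px} not divisible by 2^(depth-1) = {2 ** (self.depth - 1)}"
            )

    def channels(self, level: int) -> int:
        return min(self.base_channels * 2**level, self.max_channels)


class _ConvBlock:
    """(conv 3x3 -> [BN] -> LeakyReLU) x 2."""

    def __init__(self, c_in, c_out, cfg: NetConfig, rng):
        self.layers: list[nn.Layer] = []
        for cin in (c_in, c_out):
            self.layers.append(nn.Conv2d(cin, c_out, 3, rng=rng))
            if cfg.batch_norm:
                self.layers.append(nn.BatchNorm2d(c_out))
            self.layers.append(nn.LeakyReLU(cfg.leaky_slope))

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.depth
        self.enc = []
        cin = config.in_channels
        for lvl in range(d):
            self.enc.append(_ConvBlock(cin, config.channels(lvl), config, rng))
            cin = config.channels(lvl)
        self.pools = [nn.MaxPool2x2() for _ in range(d - 1)]
        self.ups = []
        self.upconvs = []
        self.dec = []
        for lvl in range(d - 2, -1, -1):
            self.ups.append(nn.UpsampleNearest2x())
            self.upconvs.append(nn.Conv2d(config.channels(lvl + 1), config.channels(lvl), 3, rng=rng))
            self.dec.append(_ConvBlock(2 * config.channels(lvl), config.channels(lvl), config, rng))
        self.head = nn.Conv2d(config.channels(0), config.n_classes, 1, rng=rng)
        #: channel order of the output stack, embedded in checkpoints
        self.class_order = [cls.name for cls in TissueClass][: config.n_classes]

    # -- plumbing -----------------------------------------------------------

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.layers)
        out.extend(self.pools)
        for up, upc, blk in zip(self.ups, self.upconvs, self.dec):
            out.append(up)
            out.append(upc)
            out.extend(blk.layers)
        out.append(self.head)
        return out

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """NCHW float input -> NCHW per-pixel class probabilities."""
        d = self.config.depth
        skips = []
        for lvl in range(d):
            x = self.enc[lvl].forward(x, train=train)
            if lvl < d - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x, train=train)
        self._skip_channels = []
        for i, lvl in enumerate(range(d - 2, -1, -1)):
            x = self.ups[i].forward(x, train=train)
            x = self.upconvs[i].forward(x, train=train)
            skip = skips[lvl]
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self.dec[i].forward(x, train=train)
        logits = self.head.forward(x, train=train)
        probs = nn.softmax_channels(logits)
        if train:
            self._probs = probs
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        d = self.config.depth
        dy = nn.softmax_backward(self._probs, dprobs)
        dy = self.head.backward(dy)
        dskips = {}
        for i in range(len(self.dec) - 1, -1, -1):
            lvl = d - 2 - i
            dy = self.dec[i].backward(dy)
            c_skip = self._skip_channels[i]
            dskip, dy = dy[:, :c_skip], dy[:, c_skip:]
            dskips[lvl] = dskip
            dy = self.upconvs[i].backward(dy)
            dy = self.ups[i].backward(dy)
        for lvl in range(d - 1, -1, -1):
            if lvl < d - 1:
                dy = self.pools[lvl].backward(dy)
                dy = dy + dskips[lvl]
            dy = self.enc[lvl].backward(dy)

    # -- convenience --------------------------------------------------------

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        """(H, W, 3) uint8/float image -> (H, W, C) probabilities."""
        x = prepare_input(rgb)
        probs = self.forward(x[None], train=False)[0]
        return probs.transpose(1, 2, 0)

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        return self.predict(rgb)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                arrays[f"p_{i}_{k}"] = v
            for k, v in layer.state().items():
                arrays[f"s_{i}_{k}"] = v
        arrays["config"] = np.frombuffer(
            json.dumps({"net": asdict(self.config), "class_order": self.class_order}).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(path) as data:
            header = json.loads(bytes(data["config"].tobytes()).decode())
            net = cls(NetConfig(**header["net"]))
            net.class_order = header["class_order"]
            for i, layer in enumerate(net.layers()):
                for k in layer.params:
                    layer.params[k][...] = data[f"p_{i}_{k}"]
                state = {k: data[f"s_{i}_{k}"] for k in layer.state()}
                if state:
                    layer.load_state(state)
        return net


def prepare_input(rgb: np.ndarray) -> np.ndarray:
    """(H, W, 3) image -> normalised (3, H, W) float32 in [0, 1]."""
    x = np.asarray(rgb, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    return x.transpose(2, 0, 1)


def build_unet(config: NetConfig | None = None, seed: int = 0) -> UNet:
    """Construct a randomly initialised network for the given configuration."""
    return UNet(config or NetConfig(), seed=seed)
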