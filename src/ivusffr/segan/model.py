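"""Segmentor and critic networks.

The segmentor is a fully convolutional encoder-decoder with U-net-style skip
connections: the encoder downsamples with 4x4 stride-2 convolutions, the
decoder upsamples (nearest-neighbour 2x) and refines with 3x3 stride-1
convolutions on the concatenation of the upsampled features and the matching
encoder level; a final sigmoid gives per-pixel probabilities for the output
channels (lumen and media-adventitia masks).

The critic mirrors the encoder (4x4 stride-2 convolutions) and exposes the
feature map of every layer; the multiscale L1 loss compares these
hierarchical features between the prediction-masked and ground-truth-masked
images.  The raw masked image is included as the level-0 feature, so a
critic configured with zero layers is the identity critic and the loss
reduces to plain MAE of the masked images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, concat, conv2d, leaky_relu, sigmoid, upsample2

__all__ = ["SegmentorConfig", "CriticConfig", "Segmentor", "Critic"]


@dataclass(frozen=True)
class SegmentorConfig:
    input_size: int = 64  # square frames, must be divisible by 2**depth
    in_channels: int = 1
    out_channels: int = 2  # lumen, media-adventitia
    channels: tuple = (8, 16, 32)  # encoder widths, one per level

    def __post_init__(self):
        if self.input_size % (2 ** len(self.channels)) != 0:
            raise ValueError("input_size must be divisible by 2**depth")


@dataclass(frozen=True)
class CriticConfig:
    in_channels: int = 2  # matches segmentor out_channels (masked image stack)
    channels: tuple = (8, 16, 32)  # L = len(channels) conv layers
    include_input_feature: bool = True  # raw masked image as level-0 feature


def _init_conv(rng: np.random.Generator, f, c, kh, kw):
    scale = np.sqrt(2.0 / (c * kh * kw))
    w = Tensor(rng.standard_normal((f, c, kh, kw)) * scale, requires_grad=True)
    b = Tensor(np.zeros(f), requires_grad=True)
    return w, b


@dataclass
class _ConvLayer:
    w: Tensor
    b: Tensor
    stride: int
    pad: int

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    @property
    def params(self):
        return [self.w, self.b]


class Segmentor:
    def __init__(self, config: SegmentorConfig, rng: np.random.Generator):
        self.config = config
        ch = config.channels
        self.enc: list[_ConvLayer] = []
        c_in = config.in_channels
        for c_out in ch:
            w, b = _init_conv(rng, c_out, c_in, 4, 4)
            self.enc.append(_ConvLayer(w, b, stride=2, pad=1))
            c_in = c_out
        # decoder level i consumes up(level i+1 output) ++ skip from encoder
        self.dec: list[_ConvLayer] = []
        skip_ch = list(ch[:-1]) + []  # encoder outputs available as skips
        c_prev = ch[-1]
        for c_out, c_skip in zip(reversed(ch[:-1]), reversed(skip_ch)):
            w, b = _init_conv(rng, c_out, c_prev + c_skip, 3, 3)
            self.dec.append(_ConvLayer(w, b, stride=1, pad=1))
            c_prev = c_out
        # final level back at full resolution, skip = input image
        w, b = _init_conv(rng, ch[0], c_prev + config.in_channels, 3, 3)
        self.dec.append(_ConvLayer(w, b, stride=1, pad=1))
        w, b = _init_conv(rng, config.out_channels, ch[0], 3, 3)
        self.head = _ConvLayer(w, b, stride=1, pad=1)

    @property
    def params(self):
        out = []
        for layer in self.enc + self.dec + [self.head]:
            out += layer.params
        return out

    def __call__(self, x: Tensor) -> Tensor:
        """Per-pixel probabilities, shape (N, out_channels, H, W)."""
        feats = []
        h = x
        for layer in self.enc:
            h = leaky_relu(layer(h))
            feats.append(h)
        skips = feats[:-1][::-1] + [x]
        for layer, skip in zip(self.dec, skips):
            h = leaky_relu(layer(concat([upsample2(h), skip])))
        return sigmoid(self.head(h))


class Critic:
    def __init__(self, config: CriticConfig, rng: np.random.Generator):
        self.config = config
        self.layers: list[_ConvLayer] = []
        c_in = config.in_channels
        for c_out in config.channels:
            w, b = _init_conv(rng, c_out, c_in, 4, 4)
            self.layers.append(_ConvLayer(w, b, stride=2, pad=1))
            c_in = c_out

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params
        return out

    def features(self, x: Tensor) -> list[Tensor]:
        """Hierarchical features; with no conv layers this is just [x]."""
        feats = [x] if (self.config.include_input_feature or not self.layers) else []
        h = x
        for layer in self.layers:
            h = leaky_relu(layer(h))
            feats.append(h)
        return feats

    def clip_weights(self, clip: float):
        for layer in self.layers:
            np.clip(layer.w.data, -clip, clip, out=layer.w.data)
            np.clip(layer.b.data, -clip, clip, out=layer.b.data)


def save_networks(path, segmentor: Segmentor, critic: Critic):
    """Persist both networks (npz of parameter arrays + embedded config)."""
    arrays = {}
    for i, p in enumerate(segmentor.params):
        arrays[f"s{i}"] = p.data
    for i, p in enumerate(critic.params):
        arrays[f"c{i}"] = p.data
    meta = {
        "segmentor": {
            "input_size": segmentor.config.input_size,
            "in_channels": segmentor.config.in_channels,
            "out_channels": segmentor.config.out_channels,
            "channels": list(segmentor.config.channels),
        },
        "critic": {
            "in_channels": critic.config.in_channels,
            "channels": list(critic.config.channels),
            "include_input_feature": critic.config.include_input_feature,
        },
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_networks(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        s_cfg = SegmentorConfig(
            input_size=meta["segmentor"]["input_size"],
            in_channels=meta["segmentor"]["in_channels"],
            out_channels=meta["segmentor"]["out_channels"],
            channels=tuple(meta["segmentor"]["channels"]),
        )
        c_cfg = CriticConfig(
            in_channels=meta["critic"]["in_channels"],
            channels=tuple(meta["critic"]["channels"]),
            include_input_feature=meta["critic"]["include_input_feature"],
        )
        rng = np.random.default_rng(0)
        seg = Segmentor(s_cfg, rng)
        crit = Critic(c_cfg, rng)
        for i, p in enumerate(seg.params):
            p.data = z[f"s{i}"].astype(np.float32)
        for i, p in enumerate(crit.params):
            p.data = z[f"c{i}"].astype(np.float32)
    return seg, crit
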