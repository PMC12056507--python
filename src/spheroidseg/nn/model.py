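"""U-Net-style encoder–decoder assembled from the NumPy layers.

The architecture is the classical contracting/expanding scheme with
skip connections: ``depth`` encoder stages (3×3 conv + ReLU, 2×2 max
pool), a bottleneck conv, and mirrored decoder stages (nearest ×2
upsample, concat skip, 3×3 conv + ReLU).  A 1×1 conv head emits
two-class scores turned into per-pixel probabilities by softmax.

``encoder_id`` names the encoder variant; only the built-in compact
encoder ``"plain"`` ships with the package, but the hook keeps heavier
pretrained backbones pluggable where their weights are locally
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..io import GrayImage, resize_image, to_8bit, upscale_probmap
from .layers import Concat, Conv1x1, Conv3x3, MaxPool2, ReLU, Upsample2

__all__ = ["ModelConfig", "ProbMap", "UNet", "build_model", "predict_probmap"]


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 3  # encoder stages
    base_channels: int = 8  # channels at the first stage
    input_size: tuple[int, int] = (128, 128)
    encoder_id: str = "plain"
    pretrained: bool = False

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        h, w = self.input_size
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^depth = {f}"
            )
        if self.encoder_id != "plain":
            raise ValueError(
                f"encoder {self.encoder_id!r} has no locally available weights; "
                "only the built-in 'plain' encoder ships with the package"
            )
        if self.pretrained:
            raise ValueError("no pretrained weights are bundled; set pretrained=False")


@dataclass(frozen=True)
class ProbMap:
    """Per-pixel spheroid probability in [0, 1] on the native grid."""

    values: np.ndarray
    source_size: tuple[int, int]
    trained: bool = True  # False flags output of an untrained model


def softmax2(logits: np.ndarray) -> np.ndarray:
    """Class softmax for (N, H, W, 2) two-class scores."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class UNet:
    """Encoder–decoder with skip connections; forward/backward on NumPy."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, base = config.depth, config.base_channels
        chans = [base * 2**i for i in range(d + 1)]  # per stage + bottleneck
        self.enc_convs = []
        self.enc_relus = []
        self.pools = []
        c_in = 1
        for i in range(d):
            self.enc_convs.append(Conv3x3(c_in, chans[i], rng))
            self.enc_relus.append(ReLU())
            self.pools.append(MaxPool2())
            c_in = chans[i]
        self.bottleneck = Conv3x3(c_in, chans[d], rng)
        self.bottleneck_relu = ReLU()
        self.ups = []
        self.concats = []
        self.dec_convs = []
        self.dec_relus = []
        c_in = chans[d]
        for i in reversed(range(d)):
            self.ups.append(Upsample2())
            self.concats.append(Concat())
            self.dec_convs.append(Conv3x3(c_in + chans[i], chans[i], rng))
            self.dec_relus.append(ReLU())
            c_in = chans[i]
        self.head = Conv1x1(c_in, 2, rng)
        self.trained = False

    # -- parameter plumbing -------------------------------------------------

    def _layers_with_params(self):
        yield from self.enc_convs
        yield self.bottleneck
        yield from self.dec_convs
        yield self.head

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers_with_params()):
            for k, v in layer.params.items():
                out[f"l{i}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers_with_params()):
            for k, v in layer.grads.items():
                out[f"l{i}.{k}"] = v
        return out

    def zero_grad(self) -> None:
        for layer in self._layers_with_params():
            for g in layer.grads.values():
                g[...] = 0

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            raise ValueError("checkpoint does not match this architecture")
        for k, v in state.items():
            params[k][...] = v

    def save(self, path: str | Path) -> None:
        meta = dict(
            depth=self.config.depth,
            base_channels=self.config.base_channels,
            input_h=self.config.input_size[0],
            input_w=self.config.input_size[1],
            trained=int(self.trained),
        )
        np.savez(path, __meta__=np.array(list(meta.items()), dtype=object), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        data = np.load(path, allow_pickle=True)
        meta = dict(data["__meta__"])
        config = ModelConfig(
            depth=int(meta["depth"]),
            base_channels=int(meta["base_channels"]),
            input_size=(int(meta["input_h"]), int(meta["input_w"])),
        )
        model = cls(config)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        model.trained = bool(int(meta["trained"]))
        return model

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W, 1) float32 in [0, 1] → (N, H, W, 2) logits."""
        if x.ndim != 4 or x.shape[-1] != 1:
            raise ValueError(f"expected (N, H, W, 1), got {x.shape}")
        h, w = x.shape[1:3]
        f = 2**self.config.depth
        if h % f or w % f:
            raise ValueError(f"input {h}x{w} not divisible by {f}")
        skips = []
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            x = relu.forward(conv.forward(x))
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck_relu.forward(self.bottleneck.forward(x))
        for up, cat, conv, relu, skip in zip(
            self.ups, self.concats, self.dec_convs, self.dec_relus, reversed(skips)
        ):
            x = cat.forward(up.forward(x), skip)
            x = relu.forward(conv.forward(x))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, cat, conv, relu in zip(
            reversed(self.ups),
            reversed(self.concats),
            reversed(self.dec_convs),
            reversed(self.dec_relus),
        ):
            dx = conv.backward(relu.backward(dx))
            dx, dskip = cat.backward(dx)
            dskips.append(dskip)
            dx = up.backward(dx)
        dx = self.bottleneck.backward(self.bottleneck_relu.backward(dx))
        # dskips were collected shallow-first; deepest encoder first here
        for conv, relu, pool, dskip in zip(
            reversed(self.enc_convs),
            reversed(self.enc_relus),
            reversed(self.pools),
            reversed(dskips),
        ):
            dx = pool.backward(dx)
            dx = dx + dskip
            dx = conv.backward(relu.backward(dx))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability map(s), (N, H, W)."""
        return softmax2(self.forward(x))[..., 1]


def build_model(config: ModelConfig, seed: int = 0) -> UNet:
    """Construct a randomly initialized network from its configuration."""
    return UNet(config, seed=seed)


def _pad_to_multiple(arr: np.ndarray, f: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape
    ph = (-h) % f
    pw = (-w) % f
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)), mode="reflect")
    return arr, (h, w)


def predict_probmap(
    model: UNet, image: GrayImage, resize_factor: float = 1.0
) -> ProbMap:
    """Image → probability map on the native grid.

    The image is converted to 8 bit if needed, optionally downscaled
    by ``resize_factor`` for inference, normalized to [0, 1] (division
    by 255), padded to the stride multiple, passed through the network
    and the probability map is bilinearly upscaled back to the native
    resolution so all downstream metrics live on one grid.
    """
    native_shape = image.shape
    img8 = to_8bit(image)
    if resize_factor != 1.0:
        img8 = resize_image(img8, resize_factor)
    x = img8.values.astype(np.float32) / 255.0
    f = 2**model.config.depth
    x, (h, w) = _pad_to_multiple(x, f)
    prob = model.predict_proba(x[None, :, :, None])[0][:h, :w]
    values = upscale_probmap(prob, native_shape)
    return ProbMap(values=values, source_size=native_shape, trained=model.trained)
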