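"""U-Net for single-channel foreground-probability prediction.

Architecture (encoder-decoder with skip connections):

* ``depth`` downscaling blocks, each two conv blocks (padded 3x3 conv ->
  batch norm -> leaky ReLU) followed by 2x2 max pooling;
* kernels start at ``base_channels`` (default 32) and double with each
  downscaling block, capped at ``channel_cap`` (default 512);
* a two-conv-block bottleneck at the capped width;
* a mirrored decoder with bilinear 2x upsampling, skip concatenation and
  channel halving;
* a 1x1 conv head to a single logit channel; probabilities via sigmoid.

With 7 downscaling blocks one pixel of the deepest feature map spans
2^7 = 128 input pixels per axis — the cumulative downsampling factor.
(The *effective* receptive field additionally grows with every 3x3
convolution and exceeds this span; this module reports the downsampling
factor.)

Inputs are normalised to [0, 1] by the container maximum (255 for 8-bit)
before inference; sides that are not multiples of 2^depth are reflection-
padded and the output cropped back.  The normalisation constant is stored
in checkpoints so they remain portable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..imgio import IntensityImage
from .layers import F32, BatchNorm, BilinearUp2, Conv2d, Layer, LeakyReLU, MaxPool2


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 7
    base_channels: int = 32
    channel_cap: int = 512
    kernel_size: int = 3
    leaky_slope: float = 0.01
    upsample: str = "bilinear"

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.upsample != "bilinear":
            raise ValueError("only bilinear upsampling is supported")

    def channel_schedule(self) -> list[int]:
        """Encoder widths: block i has min(base * 2^i, cap) kernels."""
        return [
            min(self.base_channels * 2**i, self.channel_cap) for i in range(self.depth)
        ]

    def bottleneck_channels(self) -> int:
        return min(self.base_channels * 2**self.depth, self.channel_cap)


def downsampling_factor(config: UNetConfig) -> int:
    """Input pixels spanned per deepest-feature-map pixel along each axis.

    Each downscaling block halves the resolution, so the factor is
    2^depth.  ``trace_downsampling`` verifies the same number by pushing a
    probe through the constructed encoder.
    """
    return 2**config.depth


class _ConvBlock:
    def __init__(self, c_in, c_out, cfg: UNetConfig, rng) -> None:
        self.layers = [
            Conv2d(c_in, c_out, cfg.kernel_size, rng, cfg.leaky_slope),
            BatchNorm(c_out),
            LeakyReLU(cfg.leaky_slope),
        ]


class UNet:
    """The model: layer graph + config + input normalisation constant."""

    def __init__(self, config: UNetConfig, rng_seed: int = 0,
                 norm_constant: float = 255.0) -> None:
        self.config = config
        self.norm_constant = norm_constant
        rng = np.random.default_rng(rng_seed)
        ch = config.channel_schedule()
        self.enc_blocks: list[list[Layer]] = []
        c_prev = 1
        for c in ch:
            blk = _ConvBlock(c_prev, c, config, rng).layers + _ConvBlock(
                c, c, config, rng
            ).layers
            self.enc_blocks.append(blk)
            c_prev = c
        self.pools = [MaxPool2() for _ in ch]
        cb = config.bottleneck_channels()
        self.bottleneck = (
            _ConvBlock(c_prev, cb, config, rng).layers
            + _ConvBlock(cb, cb, config, rng).layers
        )
        self.dec_ups: list[BilinearUp2] = []
        self.dec_blocks: list[list[Layer]] = []
        c_prev = cb
        for c in reversed(ch):
            self.dec_ups.append(BilinearUp2())
            blk = _ConvBlock(c_prev + c, c, config, rng).layers + _ConvBlock(
                c, c, config, rng
            ).layers
            self.dec_blocks.append(blk)
            c_prev = c
        self.head = Conv2d(c_prev, 1, 1, rng, config.leaky_slope)
        self._skip_cache: list[np.ndarray] | None = None

    # -- layer bookkeeping --------------------------------------------------
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        for up, blk in zip(self.dec_ups, self.dec_blocks):
            out.append(up)
            out.extend(blk)
        out.append(self.head)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    def param_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for l in self.layers():
            for k in sorted(l.params):
                h.update(np.ascontiguousarray(l.params[k]).tobytes())
        return h.hexdigest()

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, 1) float32 in [0,1] -> logits of the same shape."""
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._concat_splits = []
        for up, blk, skip in zip(self.dec_ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._concat_splits.append(x.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            for layer in blk:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, blk, split in zip(
            reversed(self.dec_ups), reversed(self.dec_blocks),
            reversed(self._concat_splits),
        ):
            for layer in reversed(blk):
                dx = layer.backward(dx)
            dskips.append(dx[..., split:])
            dx = up.backward(np.ascontiguousarray(dx[..., :split]))
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        dskips.reverse()  # now ordered deepest -> shallowest, matching below
        for blk, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), dskips
        ):
            dx = pool.backward(dx) + dskip
            for layer in reversed(blk):
                dx = layer.backward(dx)

    def encoder_trace(self, side: int) -> list[tuple[int, ...]]:
        """Push a real probe of the given side through the encoder.

        Returns the sequence of feature-map shapes after each downscaling
        block (the last entry is the deepest, pre-bottleneck map).
        """
        x = np.zeros((1, side, side, 1), dtype=F32)
        shapes = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                x = layer.forward(x, train=False)
            x = pool.forward(x, train=False)
            shapes.append(x.shape)
        return shapes

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, l in enumerate(self.layers()):
            for k, v in l.params.items():
                state[f"layer{i:03d}.{k}"] = v
            if isinstance(l, BatchNorm):
                state[f"layer{i:03d}.running_mean"] = l.running_mean
                state[f"layer{i:03d}.running_var"] = l.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers()):
            for k in l.params:
                l.params[k][...] = state[f"layer{i:03d}.{k}"]
            if isinstance(l, BatchNorm):
                l.running_mean[...] = state[f"layer{i:03d}.running_mean"]
                l.running_var[...] = state[f"layer{i:03d}.running_var"]

    def save(self, path: str | Path) -> None:
        meta = {"config": asdict(self.config), "norm_constant": self.norm_constant}
        np.savez(
            path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.state_arrays(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(UNetConfig(**meta["config"]), norm_constant=meta["norm_constant"])
            model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        return model

    def copy(self) -> "UNet":
        clone = UNet(self.config, norm_constant=self.norm_constant)
        clone.load_state_arrays(
            {k: v.copy() for k, v in self.state_arrays().items()}
        )
        return clone


def build_model(config: UNetConfig, rng_seed: int = 0) -> UNet:
    """Construct a randomly initialised U-Net (He init from ``rng_seed``)."""
    return UNet(config, rng_seed=rng_seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict(model: UNet, img: IntensityImage | np.ndarray) -> np.ndarray:
    """Foreground probability map, same shape as the input image.

    Uses evaluation mode (batch-norm running statistics), so repeated calls
    are bit-identical.  Sides that are not multiples of 2^depth are
    reflection-padded before inference and cropped after.
    """
    if isinstance(img, IntensityImage):
        arr = img.pixels.astype(F32) / F32(2**img.bit_depth - 1)
    else:
        arr = np.asarray(img, dtype=F32)
        if arr.max(initial=0.0) > 1.0:
            arr = arr / F32(model.norm_constant)
    h, w = arr.shape
    f = downsampling_factor(model.config)
    if h < f or w < f:
        raise ValueError(
            f"image {h}x{w} smaller than the minimum side {f} (= 2^depth)"
        )
    ph = (-h) % f
    pw = (-w) % f
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)), mode="reflect")
    logits = model.forward_logits(arr[None, :, :, None], train=False)
    prob = _sigmoid(logits[0, :, :, 0].astype(np.float64))
    return prob[:h, :w]
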