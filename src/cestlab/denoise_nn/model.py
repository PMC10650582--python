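"""UNet / ResUNet denoising autoencoders on offsets-as-channels images.

Both architectures share the encoder/latent/decoder topology: ``depth``
"down" stages of two 3x3 convolutions (ResUNet adds an identity shortcut
through a 1x1 channel-matching convolution), a latent space of two residual
blocks that doubles the feature count, and "up" stages that upsample,
concatenate the skip connection and convolve back down.  The output has the
same channel count as the input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import Conv2d, MaxPool2, Param, ReLU, UpsampleNearest2

__all__ = ["ModelConfig", "DenoiseNet", "build_model", "apply_denoiser",
           "save_checkpoint", "load_checkpoint"]

#: Output clamp range for denoised Z-values.
CLAMP = (0.0, 1.5)


@dataclass(frozen=True)
class ModelConfig:
    arch: str = "resunet"          # "unet" | "resunet"
    noise_estimation: bool = True  # NE-yes: predict noise, subtract
    depth: int = 4
    in_channels: int = 41
    base_channels: int = 64

    def __post_init__(self) -> None:
        if self.arch not in ("unet", "resunet"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.depth < 1 or self.in_channels < 1 or self.base_channels < 1:
            raise ValueError("invalid model dimensions")

    @property
    def name(self) -> str:
        ne = "NE-yes" if self.noise_estimation else "NE-no"
        return f"{'ResUNet' if self.arch == 'resunet' else 'UNet'}-{ne}"


class _Block:
    """Two 3x3 conv+ReLU; optionally residual with a 1x1 shortcut."""

    def __init__(self, in_ch: int, out_ch: int, residual: bool,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.relu2 = ReLU()
        self.residual = residual
        self.shortcut = Conv2d(in_ch, out_ch, 1, rng) if residual else None

    @property
    def params(self) -> list[Param]:
        out = self.conv1.params + self.conv2.params
        if self.shortcut is not None:
            out += self.shortcut.params
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        if self.residual:
            y = y + self.shortcut.forward(x)
        return self.relu2.forward(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(dy)
        dx = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(dy)))
        if self.residual:
            dx = dx + self.shortcut.backward(dy)
        return dx


class DenoiseNet:
    """Encoder / latent / decoder network built from ``ModelConfig``."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c, d = cfg.base_channels, cfg.depth
        res = cfg.arch == "resunet"

        self.enc = []
        ch_in = cfg.in_channels
        for i in range(d):
            ch_out = c * 2 ** i
            self.enc.append(_Block(ch_in, ch_out, res, rng))
            ch_in = ch_out
        self.pools = [MaxPool2() for _ in range(d)]

        # latent: two residual blocks, the first doubling the features
        self.latent = [_Block(ch_in, ch_in * 2, True, rng),
                       _Block(ch_in * 2, ch_in * 2, True, rng)]

        self.ups = []
        self.up_convs = []
        self.dec = []
        ch = ch_in * 2
        for i in range(d):
            skip_ch = c * 2 ** (d - 1 - i)
            self.ups.append(UpsampleNearest2())
            self.up_convs.append(Conv2d(ch, skip_ch, 3, rng))
            self.dec.append(_Block(2 * skip_ch, skip_ch, res, rng))
            ch = skip_ch
        self.head = Conv2d(ch, cfg.in_channels, 1, rng)

    @property
    def params(self) -> list[Param]:
        out = []
        for blk in self.enc + self.latent + self.dec:
            out += blk.params
        for conv in self.up_convs:
            out += conv.params
        out += self.head.params
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError("channel count mismatch")
        if x.shape[2] % 2 ** self.cfg.depth or x.shape[3] % 2 ** self.cfg.depth:
            raise ValueError(
                f"spatial size must be divisible by {2 ** self.cfg.depth}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for blk in self.latent:
            x = blk.forward(x)
        self._skip_ch = []
        for up, conv, blk, skip in zip(self.ups, self.up_convs, self.dec,
                                       reversed(skips)):
            x = conv.forward(up.forward(x))
            self._skip_ch.append(skip.shape[1])
            x = blk.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        dskips = []
        for up, conv, blk, sc in zip(reversed(self.ups),
                                     reversed(self.up_convs),
                                     reversed(self.dec),
                                     reversed(self._skip_ch)):
            dcat = blk.backward(dy)
            dskips.append(dcat[:, :sc])
            dy = up.backward(conv.backward(dcat[:, sc:]))
        for blk in reversed(self.latent):
            dy = blk.backward(dy)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = blk.backward(pool.backward(dy) + dskip)
        return dy

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("checkpoint/model parameter count mismatch")
        for i, p in enumerate(params):
            val = np.asarray(state[f"p{i}"])
            if val.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value = val.astype(np.float64)


def build_model(cfg: ModelConfig, seed: int = 0) -> DenoiseNet:
    return DenoiseNet(cfg, seed=seed)


def apply_denoiser(model: DenoiseNet, vol):
    """Denoise a CestVolume; NE-yes subtracts the predicted noise."""
    x = vol.data.transpose(2, 0, 1)[None]
    y = model.forward(x)[0].transpose(1, 2, 0)
    out = vol.data - y if model.cfg.noise_estimation else y
    out = np.clip(out, *CLAMP)
    return vol.copy_with(data=out,
                         meta={**vol.meta, "method": model.cfg.name})


def save_checkpoint(path: str, model: DenoiseNet) -> None:
    np.savez(path, __config__=json.dumps(asdict(model.cfg)),
             **model.state_dict())


def load_checkpoint(path: str) -> DenoiseNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["__config__"])))
        model = DenoiseNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model
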