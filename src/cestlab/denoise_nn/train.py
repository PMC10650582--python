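"""Training loop: Adam + ReduceLROnPlateau, k-space noise augmentation.

Each epoch draws, per phantom, a fresh noise level sigma ~ U(sigma_range), a
fresh noise realisation injected in k-space, and a fresh contiguous 41-offset
window.  NE-yes models regress the injected noise (noisy - clean); NE-no
models regress the clean cropped volume.  Loss is MSE; validation follows a
fixed 90/10 phantom split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..bm_simulator import CestVolume
from ..noise import CROP_DYN, NoiseSpec, add_kspace_noise
from .model import DenoiseNet

__all__ = ["TrainConfig", "Adam", "ReduceLROnPlateau", "train"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 40
    lr: float = 0.01
    weight_decay: float = 1e-6
    scheduler_patience: int = 3
    scheduler_factor: float = 0.1
    sigma_range: tuple[float, float] = (0.0, 0.2)
    loss: str = "mse"
    seed: int = 0
    val_fraction: float = 0.1
    crop_dyn: int = CROP_DYN
    spatial_crop: int | None = None  # random HxW training crops if set

    def __post_init__(self) -> None:
        if self.loss != "mse":
            raise ValueError("only MSE loss is supported")
        if not 0 <= self.sigma_range[0] <= self.sigma_range[1]:
            raise ValueError("invalid sigma range")


class Adam:
    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: Adam, patience: int = 3,
                 factor: float = 0.1, min_lr: float = 1e-8):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


def _make_sample(vol: CestVolume, tc: TrainConfig, rng: np.random.Generator,
                 noise_target: bool) -> tuple[np.ndarray, np.ndarray]:
    """One (input, target) pair: fresh sigma, fresh noise, fresh crop."""
    sigma = rng.uniform(*tc.sigma_range)
    noisy = add_kspace_noise(vol, NoiseSpec(sigma=sigma,
                                            seed=int(rng.integers(2 ** 31))))
    start = int(rng.integers(0, vol.dyn - tc.crop_dyn + 1)) \
        if vol.dyn > tc.crop_dyn else 0
    sl = slice(start, start + tc.crop_dyn)
    x = noisy.data[:, :, sl].transpose(2, 0, 1)
    clean = vol.data[:, :, sl].transpose(2, 0, 1)
    if tc.spatial_crop is not None and tc.spatial_crop < min(x.shape[1:]):
        cs = tc.spatial_crop
        oy = int(rng.integers(0, x.shape[1] - cs + 1))
        ox = int(rng.integers(0, x.shape[2] - cs + 1))
        x = x[:, oy:oy + cs, ox:ox + cs]
        clean = clean[:, oy:oy + cs, ox:ox + cs]
    target = (x - clean) if noise_target else clean
    return x, target


def _epoch_pass(model: DenoiseNet, vols, tc: TrainConfig,
                rng: np.random.Generator, opt: Adam | None) -> float:
    """One pass over ``vols``; trains when ``opt`` is given, else evaluates."""
    losses = []
    order = rng.permutation(len(vols)) if opt is not None \
        else np.arange(len(vols))
    for i0 in range(0, len(order), tc.batch_size):
        idx = order[i0:i0 + tc.batch_size]
        xs, ts = zip(*(_make_sample(vols[i], tc, rng,
                                    model.cfg.noise_estimation)
                       for i in idx))
        x, t = np.stack(xs), np.stack(ts)
        y = model.forward(x)
        diff = y - t
        loss = float(np.mean(diff * diff))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss {loss}; check lr/data scaling")
        losses.append(loss)
        if opt is not None:
            model.zero_grad()
            model.backward(2.0 * diff / diff.size)
            opt.step()
    return float(np.mean(losses))


def train(model: DenoiseNet, phantoms: list[CestVolume],
          tc: TrainConfig) -> tuple[DenoiseNet, dict]:
    """Train in place; returns the model and a per-epoch history dict."""
    if not phantoms:
        raise ValueError("empty training set")
    dyns = {v.dyn for v in phantoms}
    if len(dyns) != 1:
        raise ValueError("all phantoms must share one offset count")
    if min(dyns) < tc.crop_dyn:
        raise ValueError(f"phantoms must have >= {tc.crop_dyn} offsets")

    rng = np.random.default_rng(tc.seed)
    idx = rng.permutation(len(phantoms))
    n_val = max(1, int(round(tc.val_fraction * len(phantoms)))) \
        if len(phantoms) > 1 else 0
    val = [phantoms[i] for i in idx[:n_val]]
    trn = [phantoms[i] for i in idx[n_val:]]

    opt = Adam(model.params, lr=tc.lr, weight_decay=tc.weight_decay)
    sched = ReduceLROnPlateau(opt, patience=tc.scheduler_patience,
                              factor=tc.scheduler_factor)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    val_rng_seed = int(rng.integers(2 ** 31))
    for _ in range(tc.epochs):
        train_loss = _epoch_pass(model, trn, tc, rng, opt)
        # fixed noise draws for validation so the scheduler sees a stable metric
        val_rng = np.random.default_rng(val_rng_seed)
        val_loss = _epoch_pass(model, val, tc, val_rng, None) \
            if val else train_loss
        sched.step(val_loss)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
    return model, history
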