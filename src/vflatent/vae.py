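"""An MMD-regularized variational autoencoder for 12x12 visual-field images.

The encoder is deterministic: two 3x3 stride-2 convolutions (12x12 -> 6x6 ->
3x3), a flattening step, and a dense layer with identity activation onto the
L latent features.  The decoder mirrors it: dense layer, reshape to 3x3
feature maps, two 3x3 stride-2 deconvolutions (3 -> 6 -> 12), and a 3x3
sigmoid output head, so reconstructions live strictly in (0, 1); the decoder
output is interpreted as the mean of a Gaussian observation model, i.e. the
generated fields are de-noised.

Instead of a per-point KL term, the aggregate latent distribution is pulled
toward a standard normal prior with the (biased, V-statistic) squared
maximum mean discrepancy under a Gaussian kernel — the InfoVAE/MMD-VAE
formulation.  The total loss on a batch is

    pixel MSE over all 144 pixels  +  lambda * MMD^2(encode(batch), prior sample)

optimized with Adam; the training epoch with the minimal validation loss is
selected and its parameters restored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import _nn
from .core import NormalizationSpec

__all__ = ["VAEConfig", "TrainedVAE", "mmd", "loss", "train",
           "encode", "decode", "sweep_latent_dims",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class VAEConfig:
    latent_dim: int = 8
    encoder_channels: tuple[int, int] = (32, 64)
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 100
    mmd_weight: float = 1000.0
    mmd_kernel_bandwidth: float | None = None  # default sigma^2 = latent_dim
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    @property
    def sigma(self) -> float:
        if self.mmd_kernel_bandwidth is not None:
            return float(self.mmd_kernel_bandwidth)
        return float(np.sqrt(self.latent_dim))


class _Autoencoder:
    """Parameter container + forward/backward passes (see module docstring)."""

    def __init__(self, config: VAEConfig, rng: np.random.Generator):
        c1, c2 = config.encoder_channels
        L = config.latent_dim
        self.config = config
        self.enc_c1 = _nn.Conv2dStride2(1, c1, rng)    # 12 -> 6
        self.enc_a1 = _nn.ReLU()
        self.enc_c2 = _nn.Conv2dStride2(c1, c2, rng)   # 6 -> 3
        self.enc_a2 = _nn.ReLU()
        self.enc_f1 = _nn.Dense(9 * c2, L, rng)        # identity activation
        self.dec_f2 = _nn.Dense(L, 9 * c2, rng)
        self.dec_a0 = _nn.ReLU()
        self.dec_d1 = _nn.ConvT2dStride2(c2, c1, rng)  # 3 -> 6
        self.dec_a1 = _nn.ReLU()
        self.dec_d2 = _nn.ConvT2dStride2(c1, c1, rng)  # 6 -> 12
        self.dec_a2 = _nn.ReLU()
        self.dec_d3 = _nn.Conv2dSame(c1, 1, rng)       # 12 -> 12
        self.dec_a3 = _nn.Sigmoid()
        self._c2 = c2

    def layers(self) -> list:
        return [self.enc_c1, self.enc_c2, self.enc_f1,
                self.dec_f2, self.dec_d1, self.dec_d2, self.dec_d3]

    # -- forward -----------------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        h = self.enc_a1.forward(self.enc_c1.forward(x[:, :, :, None]))
        h = self.enc_a2.forward(self.enc_c2.forward(h))
        self._enc_shape = h.shape
        return self.enc_f1.forward(h.reshape(h.shape[0], -1))

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_a0.forward(self.dec_f2.forward(z))
        h = h.reshape(h.shape[0], 3, 3, self._c2)
        h = self.dec_a1.forward(self.dec_d1.forward(h))
        h = self.dec_a2.forward(self.dec_d2.forward(h))
        return self.dec_a3.forward(self.dec_d3.forward(h))[:, :, :, 0]

    # -- backward (mirrors of the above, in reverse) -----------------------
    def decode_backward(self, dxhat: np.ndarray) -> np.ndarray:
        d = self.dec_a3.backward(dxhat[:, :, :, None])
        d = self.dec_d3.backward(d)
        d = self.dec_d2.backward(self.dec_a2.backward(d))
        d = self.dec_d1.backward(self.dec_a1.backward(d))
        d = self.dec_a0.backward(d.reshape(d.shape[0], -1))
        return self.dec_f2.backward(d)

    def encode_backward(self, dz: np.ndarray) -> None:
        d = self.enc_f1.backward(dz).reshape(self._enc_shape)
        d = self.enc_c2.backward(self.enc_a2.backward(d))
        self.enc_c1.backward(self.enc_a1.backward(d))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers() for p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers() for p in layer.params()]
        for p, w in zip(flat, weights):
            p[...] = w


@dataclass
class TrainedVAE:
    """A trained autoencoder plus the bookkeeping needed to reuse it."""

    net: _Autoencoder
    config: VAEConfig
    norm: NormalizationSpec = field(default_factory=NormalizationSpec)
    selected_epoch: int = 0
    loss_history: pd.DataFrame | None = None

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim


def _check_images(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[1:] != (12, 12):
        raise ValueError(f"expected N x 12 x 12 images, got shape {images.shape}")
    return images


def encode(model: TrainedVAE, images: np.ndarray) -> np.ndarray:
    """Deterministically map N images to their N x L latent features."""
    return model.net.encode(_check_images(images))


def decode(model: TrainedVAE, z: np.ndarray) -> np.ndarray:
    """Map latent rows back to N x 12 x 12 mean images in (0, 1)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != model.latent_dim:
        raise ValueError(f"z must have {model.latent_dim} columns, got {z.shape[1]}")
    return model.net.decode(z)


def mmd(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Biased (V-statistic) squared MMD with Gaussian kernel bandwidth sigma.

    mean_ij k(x_i, x_j) + mean_ij k(y_i, y_j) - 2 mean_ij k(x_i, y_j) with
    k(a, b) = exp(-||a - b||^2 / (2 sigma^2)); nonnegative by construction.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("mmd requires nonempty samples")
    if x.shape[1] != y.shape[1]:
        raise ValueError("samples must share the feature dimension")
    kxx = _kernel(x, x, sigma).mean()
    kyy = _kernel(y, y, sigma).mean()
    kxy = _kernel(x, y, sigma).mean()
    return float(kxx + kyy - 2.0 * kxy)


def _kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _mmd_grad_x(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """Gradient of the biased squared MMD with respect to the rows of x."""
    n, m = x.shape[0], y.shape[0]
    kxx = _kernel(x, x, sigma)
    kxy = _kernel(x, y, sigma)
    # d k(a,b)/da = k(a,b) (b - a) / sigma^2
    diff_xx = x[None, :, :] - x[:, None, :]          # [i, j, :] = x_j - x_i
    diff_xy = y[None, :, :] - x[:, None, :]
    g_xx = 2.0 * (kxx[:, :, None] * diff_xx).sum(1) / (n * n)
    g_xy = -2.0 * (kxy[:, :, None] * diff_xy).sum(1) / (n * m)
    return (g_xx + g_xy) / sigma ** 2


def loss(model: TrainedVAE | _Autoencoder, batch: np.ndarray,
         rng: np.random.Generator | None = None,
         prior_sample: np.ndarray | None = None) -> tuple[float, float, float]:
    """(total, reconstruction, regularization) on a batch of images.

    Reconstruction is the MSE over all 144 pixels; regularization is
    lambda x MMD^2 between the encoded batch and a standard-normal prior
    sample (freshly drawn unless supplied).
    """
    net = model.net if isinstance(model, TrainedVAE) else model
    batch = _check_images(batch)
    z = net.encode(batch)
    xhat = net.decode(z)
    recon = float(np.mean((xhat - batch) ** 2))
    cfg = net.config
    if cfg.mmd_weight == 0.0:
        return recon, recon, 0.0
    if prior_sample is None:
        rng = rng or np.random.default_rng(cfg.seed)
        prior_sample = rng.standard_normal((batch.shape[0], cfg.latent_dim))
    reg = cfg.mmd_weight * mmd(z, prior_sample, cfg.sigma)
    return recon + reg, recon, reg


def _train_step(net: _Autoencoder, batch: np.ndarray, opt: _nn.Adam,
                rng: np.random.Generator) -> tuple[float, float, float]:
    cfg = net.config
    z = net.encode(batch)
    xhat = net.decode(z)
    resid = xhat - batch
    recon = float(np.mean(resid ** 2))
    dxhat = 2.0 * resid / resid.size
    dz = net.decode_backward(dxhat)
    if cfg.mmd_weight != 0.0:
        prior = rng.standard_normal((batch.shape[0], cfg.latent_dim))
        reg = cfg.mmd_weight * mmd(z, prior, cfg.sigma)
        dz = dz + cfg.mmd_weight * _mmd_grad_x(z, prior, cfg.sigma)
    else:
        reg = 0.0
    net.encode_backward(dz)
    opt.step()
    return recon + reg, recon, reg


def _epoch_losses(net: _Autoencoder, images: np.ndarray, batch_size: int,
                  rng: np.random.Generator) -> tuple[float, float, float]:
    """Average per-batch losses over a full pass (no shuffling, no updates)."""
    totals = np.zeros(3)
    n_batches = 0
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        totals += loss(net, batch, rng=rng)
        n_batches += 1
    return tuple(totals / max(n_batches, 1))


def train(train_images: np.ndarray, val_images: np.ndarray,
          config: VAEConfig | None = None,
          norm: NormalizationSpec = NormalizationSpec(),
          verbose: bool = False) -> TrainedVAE:
    """Train with Adam, record per-epoch losses, restore the best-validation epoch."""
    config = config or VAEConfig()
    train_images = _check_images(train_images)
    val_images = _check_images(val_images)
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("training and validation sets must be nonempty")

    rng = np.random.default_rng(config.seed)
    net = _Autoencoder(config, rng)
    opt = _nn.Adam(net.layers(), lr=config.lr)

    history = []
    best = (np.inf, None, -1)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_images))
        tr_sum = np.zeros(3)
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = train_images[order[start:start + config.batch_size]]
            step_losses = _train_step(net, batch, opt, rng)
            if not np.isfinite(step_losses[0]):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}; "
                    "reduce the learning rate or the MMD weight")
            tr_sum += step_losses
            n_batches += 1
        # Training loss is the running mean over the epoch's batches
        # (pre-update per batch); validation is a fresh full pass.
        tr = tuple(tr_sum / n_batches)
        va = _epoch_losses(net, val_images, config.batch_size, rng)
        history.append((epoch, *tr, *va))
        if verbose:
            print(f"epoch {epoch:3d}  train {tr[0]:.5f}  val {va[0]:.5f}")
        if va[0] < best[0]:
            best = (va[0], net.get_weights(), epoch)

    if best[1] is not None:
        net.set_weights(best[1])
    hist = pd.DataFrame(history, columns=[
        "epoch", "train_total", "train_reconstruction", "train_regularization",
        "val_total", "val_reconstruction", "val_regularization"])
    return TrainedVAE(net=net, config=config, norm=norm,
                      selected_epoch=best[2], loss_history=hist)


def sweep_latent_dims(train_images: np.ndarray, val_images: np.ndarray,
                      dims: Iterable[int] = range(1, 16),
                      config: VAEConfig | None = None,
                      verbose: bool = False) -> dict[int, TrainedVAE]:
    """Train one model per latent dimension with a shared config and seed."""
    base = config or VAEConfig()
    out = {}
    for L in dims:
        cfg = dataclasses.replace(base, latent_dim=L)
        out[L] = train(train_images, val_images, cfg, verbose=verbose)
    return out


# ---------------------------------------------------------------------------
# Checkpoints: weights as .npz plus a JSON header.

def save_checkpoint(model: TrainedVAE, path: str | Path) -> None:
    path = Path(path)
    weights = model.net.get_weights()
    header = {
        "config": asdict(model.config),
        "norm": asdict(model.norm),
        "selected_epoch": model.selected_epoch,
    }
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    if model.loss_history is not None:
        arrays["loss_history"] = model.loss_history.to_numpy()
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TrainedVAE:
    data = np.load(path, allow_pickle=False)
    header = json.loads(bytes(data["header"]).decode())
    cfg_d = header["config"]
    cfg_d["encoder_channels"] = tuple(cfg_d["encoder_channels"])
    config = VAEConfig(**cfg_d)
    norm = NormalizationSpec(**header["norm"])
    net = _Autoencoder(config, np.random.default_rng(0))
    weights = [data[f"w{i}"] for i in range(len(net.get_weights()))]
    net.set_weights(weights)
    hist = None
    if "loss_history" in data:
        hist = pd.DataFrame(data["loss_history"], columns=[
            "epoch", "train_total", "train_reconstruction", "train_regularization",
            "val_total", "val_reconstruction", "val_regularization"])
    return TrainedVAE(net=net, config=config, norm=norm,
                      selected_epoch=int(header["selected_epoch"]), loss_history=hist)
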