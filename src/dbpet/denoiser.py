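"""Residual convolutional denoiser mapping low-count slices toward full-count.

The network is the large-kernel residual CNN used for dbPET denoising:
``n_conv_layers`` same-size convolutions (default five, 15x15 kernels);
each hidden layer has ``n_filters`` channels (default 128) followed by batch
normalization and PReLU; the final convolution projects to one channel with
no activation, and the input is added back through a skip connection, so the
network learns the residual (FC - LC) rather than the image itself.

The final convolution is zero-initialized, making the untrained model an
exact identity map — a stable, testable starting point.  Training minimizes
the mean squared error to the paired full-count slice with Adam.  Slices are
fed in raw SUV units; an optional max-normalization switch is recorded in
the config.  The architecture is fully convolutional, so inference accepts
any slice size.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .volume import PETVolume

__all__ = [
    "DenoiserConfig",
    "TrainedDenoiser",
    "build_denoiser",
    "split_train_val",
    "train_denoiser",
    "denoise_volume",
    "parameter_count",
]


@dataclass
class DenoiserConfig:
    n_conv_layers: int = 5
    kernel: int = 15
    n_filters: int = 128
    input_shape: tuple[int, int] = (236, 132)
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 100
    val_fraction: float = 0.10
    normalize_input: bool = False
    prelu_init_slope: float = 0.25
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be a positive odd integer")
        if self.n_conv_layers < 2:
            raise ValueError("need at least 2 convolutional layers")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class TrainedDenoiser:
    """Architecture + (possibly untrained) weights + per-epoch loss history."""

    config: DenoiserConfig
    network: nn.Sequential
    history: list = field(default_factory=list)

    def predict_slice(self, img: np.ndarray) -> np.ndarray:
        """Denoise one 2D slice (inference mode, running BN statistics)."""
        img = np.asarray(img, dtype=np.float64)
        if not np.all(np.isfinite(img)):
            raise ValueError("input slice contains non-finite values")
        scale = float(img.max()) if self.config.normalize_input else 1.0
        if scale <= 0:
            scale = 1.0
        x = (img / scale).astype(np.float32)[None, None]
        resid = self.network.forward(x, training=False)
        return img + resid[0, 0].astype(np.float64) * scale


def build_denoiser(config: DenoiserConfig) -> TrainedDenoiser:
    """Assemble the residual network; untrained it is the identity map."""
    rng = np.random.default_rng(config.seed)
    layers: list = []
    c_in = 1
    for _ in range(config.n_conv_layers - 1):
        layers.append(nn.Conv2d(c_in, config.n_filters, config.kernel, rng))
        layers.append(nn.BatchNorm2d(config.n_filters, eps=config.bn_eps,
                                     momentum=config.bn_momentum))
        layers.append(nn.PReLU(config.n_filters, init_slope=config.prelu_init_slope))
        c_in = config.n_filters
    layers.append(nn.Conv2d(c_in, 1, config.kernel, rng, init="zeros"))
    return TrainedDenoiser(config=config, network=nn.Sequential(layers))


def parameter_count(config: DenoiserConfig) -> int:
    """Closed-form count of trainable parameters for the architecture."""
    k2 = config.kernel**2
    nf = config.n_filters
    total = 0
    c_in = 1
    for _ in range(config.n_conv_layers - 1):
        total += (c_in * k2 + 1) * nf  # conv weights + bias
        total += 2 * nf  # BN gamma/beta
        total += nf  # PReLU slopes
        c_in = nf
    total += c_in * k2 + 1  # final 1-channel projection
    return total


def split_train_val(slices: list, val_fraction: float, seed: int):
    """Random slice-level split; validation size = round(fraction * total)."""
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must lie in (0, 1)")
    slices = list(slices)
    if not slices:
        raise ValueError("cannot split an empty slice list")
    n = len(slices)
    n_val = int(round(val_fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [slices[i] for i in range(n) if i not in val_idx]
    val = [slices[i] for i in range(n) if i in val_idx]
    return train, val


def _stack_pairs(pairs, normalize: bool):
    lcs, fcs, scales = [], [], []
    for lc, fc in pairs:
        lc = np.asarray(lc, dtype=np.float64)
        fc = np.asarray(fc, dtype=np.float64)
        if lc.shape != fc.shape:
            raise ValueError(
                f"LC/FC shape mismatch within a pair: {lc.shape} vs {fc.shape}")
        s = float(lc.max()) if normalize else 1.0
        if s <= 0:
            s = 1.0
        lcs.append(lc / s)
        fcs.append(fc / s)
        scales.append(s)
    return (np.asarray(lcs, dtype=np.float32)[:, None],
            np.asarray(fcs, dtype=np.float32)[:, None])


def _eval_mse(model: TrainedDenoiser, x: np.ndarray, y: np.ndarray,
              batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        xb, yb = x[i:i + batch], y[i:i + batch]
        pred = xb + model.network.forward(xb, training=False)
        total += float(np.sum((pred.astype(np.float64) - yb) ** 2))
        n += yb.size
    return total / n


def train_denoiser(model: TrainedDenoiser, pairs, config: DenoiserConfig | None = None,
                   val_pairs=None) -> TrainedDenoiser:
    """Fit the residual network on paired (LC slice, FC slice) data.

    Minimizes MSE between ``LC + network(LC)`` and FC with Adam for
    ``config.epochs`` epochs at ``config.learning_rate``, shuffling
    minibatches with the seeded generator.  If ``val_pairs`` is None a
    validation split of ``config.val_fraction`` is carved from ``pairs``.
    ``history`` records per-epoch training and validation MSE.
    ``epochs=0`` returns the model untouched with empty history.
    """
    if config is None:
        config = model.config
    pairs = list(pairs)
    if config.epochs == 0:
        model.history = []
        return model
    if len(pairs) < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} training pairs, "
            f"got {len(pairs)}")
    if val_pairs is None:
        pairs, val_pairs = split_train_val(pairs, config.val_fraction,
                                           config.seed + 1)
    x_tr, y_tr = _stack_pairs(pairs, config.normalize_input)
    x_va, y_va = _stack_pairs(val_pairs, config.normalize_input)

    rng = np.random.default_rng(config.seed + 2)
    opt = nn.Adam(model.network.parameters, lr=config.learning_rate)
    model.history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            if len(idx) < 2:  # BN needs more than a single sample
                continue
            xb, yb = x_tr[idx], y_tr[idx]
            model.network.zero_grad()
            resid = model.network.forward(xb, training=True)
            loss, dpred = nn.mse_loss(xb + resid, yb)
            model.network.backward(dpred)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_mse = _eval_mse(model, x_va, y_va, config.batch_size)
        model.history.append({
            "train_mse": epoch_loss / max(n_batches, 1),
            "val_mse": val_mse,
        })
        if not np.isfinite(val_mse):
            raise FloatingPointError("validation MSE diverged to non-finite")
    return model


def denoise_volume(model: TrainedDenoiser, vol: PETVolume) -> PETVolume:
    """Apply the network slice-by-slice along the axial direction.

    Inference is deterministic (batch normalization uses the stored running
    statistics); the output is tagged as the DL-denoised set.
    """
    if not np.all(np.isfinite(vol.values)):
        raise ValueError("input volume contains non-finite values")
    out = np.empty_like(vol.values)
    for i in range(vol.n_slices):
        out[i] = model.predict_slice(vol.values[i])
    return vol.with_values(out, meta=vol.meta + "+DL")
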