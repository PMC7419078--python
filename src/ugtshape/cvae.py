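"""Convolutional variational autoencoder over binary contact matrices.

The encoder is three 3×3 convolutions with strides 1, 2, 1 followed by a
fully connected layer producing the Gaussian posterior (mean, log-variance);
the decoder mirrors it (fully connected, then three transposed convolutions
with the stride pattern reversed) and emits per-pixel Bernoulli logits. The
objective is the plain VAE bound: element-wise binary cross-entropy plus the
KL divergence of the posterior from a standard normal, optimised with
RMSProp at learning rate 0.001.

The implementation is a self-contained numpy network: im2col/col2im
convolution primitives with hand-written backward passes. Matrices here are
tiny (≤ 22×22) and filter counts small, so CPU training of a few thousand
frames takes seconds per epoch. All randomness (weight init, minibatch
shuffling, posterior sampling) is driven by the single config seed, making
training runs bit-reproducible on one machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .contacts import ContactDataset
from .errors import EmptyInputError, TrainingDivergedError


# ---------------------------------------------------------------------------
# Convolution primitives (im2col / col2im)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N, C, H, W) into one big column matrix (C·k·k, N·Ho·Wo).

    The batch axis is folded into the column axis so that every convolution
    becomes a single large GEMM instead of a stack of tiny ones.
    """
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)).reshape(
        c * k * k, n * ho * wo
    )
    return cols, (n, ho, wo)


def _fold_batch(t: np.ndarray) -> np.ndarray:
    """(N, F, H, W) → (F, N·H·W)."""
    n, f = t.shape[:2]
    return np.ascontiguousarray(t.transpose(1, 0, 2, 3)).reshape(f, -1)


def conv_forward(x, W, b, stride, pad):
    """out = W * x + b for W of shape (F, C, k, k); returns (out, cols)."""
    f = W.shape[0]
    k = W.shape[2]
    cols, (n, ho, wo) = _im2col(x, k, stride, pad)
    out = (W.reshape(f, -1) @ cols).reshape(f, n, ho, wo).transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b[None, :, None, None]
    return out, cols


def conv_backward_weight(cols, dout, w_shape):
    dW = _fold_batch(dout) @ cols.T
    db = dout.sum(axis=(0, 2, 3))
    return dW.reshape(w_shape), db


def conv_backward_input(dout, W, input_hw, stride, pad):
    """Adjoint of conv_forward with respect to its input (col2im scatter)."""
    n, f, ho, wo = dout.shape
    c, k = W.shape[1], W.shape[2]
    dcols = (W.reshape(f, -1).T @ _fold_batch(dout)).reshape(c, k, k, n, ho, wo)
    h, w = input_hw
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += (
                dcols[:, ki, kj].transpose(1, 0, 2, 3)
            )
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv(_Layer):
    def __init__(self, in_ch, out_ch, k, stride, pad, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, k, k)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.stride, self.pad, self.k = stride, pad, k
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._in_hw = x.shape[2:]
        out, self._cols = conv_forward(x, self.W, self.b, self.stride, self.pad)
        return out

    def backward(self, dout):
        dW, db = conv_backward_weight(self._cols, dout, self.W.shape)
        self.grads[0][...] = dW
        self.grads[1][...] = db
        return conv_backward_input(dout, self.W, self._in_hw, self.stride, self.pad)


class ConvTranspose(_Layer):
    """Transposed convolution expressed as the adjoint of a conv.

    The layer maps (N, in_ch, in_size, in_size) → (N, out_ch, out_size,
    out_size); ``out_size`` is given explicitly, which subsumes the usual
    output_padding bookkeeping for odd sizes.
    """

    def __init__(self, in_ch, out_ch, k, stride, pad, in_size, out_size, rng,
                 dtype=np.float32):
        if conv_out_size(out_size, k, stride, pad) != in_size:
            raise ValueError(
                f"incompatible transposed-conv geometry: {out_size} → "
                f"{conv_out_size(out_size, k, stride, pad)} != {in_size}"
            )
        scale = np.sqrt(2.0 / (in_ch * k * k))
        # Weight laid out as the virtual forward conv (in_ch, out_ch, k, k).
        self.W = rng.normal(0.0, scale, size=(in_ch, out_ch, k, k)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.stride, self.pad, self.k = stride, pad, k
        self.out_size = out_size
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        y = conv_backward_input(x, self.W, (self.out_size, self.out_size),
                                self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, dout):
        dx, cols = conv_forward(dout, self.W, None, self.stride, self.pad)
        dW, _ = conv_backward_weight(cols, self._x, self.W.shape)
        self.grads[0][...] = dW
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        return dx


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(_Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CvaeConfig:
    input_size: int = 22
    filters: tuple[int, int, int] = (16, 16, 16)
    latent_dim: int = 3
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    convergence_tol: float = 1e-3
    seed: int = 0
    strides: tuple[int, int, int] = (1, 2, 1)
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epochs and patience must be >= 1")


@dataclass
class LatentEmbedding:
    """Posterior-mean latent codes with their (variant, substrate, frame) labels."""

    codes: np.ndarray
    labels: list[tuple[str, str, int]]
    source: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (n, latent_dim)")
        if len(self.labels) != self.codes.shape[0]:
            raise ValueError("one label per code required")
        if not np.all(np.isfinite(self.codes)):
            raise ValueError("latent codes must be finite")


class _Network:
    """Encoder + decoder stacks with shared parameter/grad registry."""

    def __init__(self, config: CvaeConfig, rng: np.random.Generator):
        s = config.input_size
        k, pad = config.kernel, config.kernel // 2
        f1, f2, f3 = config.filters
        s1 = conv_out_size(s, k, config.strides[0], pad)
        s2 = conv_out_size(s1, k, config.strides[1], pad)
        s3 = conv_out_size(s2, k, config.strides[2], pad)
        self.spatial = (s, s1, s2, s3)
        self.flat = f3 * s3 * s3

        self.enc = [
            Conv(1, f1, k, config.strides[0], pad, rng), ReLU(),
            Conv(f1, f2, k, config.strides[1], pad, rng), ReLU(),
            Conv(f2, f3, k, config.strides[2], pad, rng), ReLU(),
        ]
        self.head = Dense(self.flat, 2 * config.latent_dim, rng)
        self.dec_fc = Dense(config.latent_dim, self.flat, rng)
        self.dec_relu = ReLU()
        self.dec = [
            ConvTranspose(f3, f2, k, config.strides[2], pad, s3, s2, rng), ReLU(),
            ConvTranspose(f2, f1, k, config.strides[1], pad, s2, s1, rng), ReLU(),
            ConvTranspose(f1, 1, k, config.strides[0], pad, s1, s, rng),
        ]
        self.latent_dim = config.latent_dim
        self._f3, self._s3 = f3, s3

        self.layers = self.enc + [self.head, self.dec_fc, self.dec_relu] + self.dec
        self.params = [p for layer in self.layers for p in layer.params]
        self.grads = [g for layer in self.layers for g in layer.grads]

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = x
        for layer in self.enc:
            h = layer.forward(h)
        self._enc_out_shape = h.shape
        stats = self.head.forward(h.reshape(h.shape[0], -1))
        return stats[:, : self.latent_dim], stats[:, self.latent_dim:]

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_relu.forward(self.dec_fc.forward(z))
        h = h.reshape(z.shape[0], self._f3, self._s3, self._s3)
        for layer in self.dec:
            h = layer.forward(h)
        return h  # Bernoulli logits

    def backward(self, dlogits: np.ndarray, dmu_extra: np.ndarray,
                 dlogvar_extra: np.ndarray, eps: np.ndarray, logvar: np.ndarray):
        d = dlogits
        for layer in reversed(self.dec):
            d = layer.backward(d)
        d = self.dec_relu.backward(d.reshape(d.shape[0], -1))
        dz = self.dec_fc.backward(d)
        # z = mu + eps·exp(logvar/2)
        dmu = dz + dmu_extra
        dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar) + dlogvar_extra
        dstats = np.concatenate([dmu, dlogvar], axis=1)
        d = self.head.backward(dstats).reshape(self._enc_out_shape)
        for layer in reversed(self.enc):
            d = layer.backward(d)


@dataclass
class TrainedCVAE:
    config: CvaeConfig
    network: _Network
    history: list[dict[str, float]]
    converged_epoch: int

    def save(self, path: str | Path) -> None:
        weights = {f"p{i}": p for i, p in enumerate(self.network.params)}
        np.savez_compressed(
            path,
            config=np.array(json.dumps(asdict(self.config))),
            history=np.array(json.dumps(self.history)),
            converged_epoch=self.converged_epoch,
            **weights,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedCVAE":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["config"]))
            cfg_dict["filters"] = tuple(cfg_dict["filters"])
            cfg_dict["strides"] = tuple(cfg_dict["strides"])
            config = CvaeConfig(**cfg_dict)
            net = _Network(config, np.random.default_rng(0))
            for i, p in enumerate(net.params):
                p[...] = data[f"p{i}"]
            return cls(
                config=config,
                network=net,
                history=json.loads(str(data["history"])),
                converged_epoch=int(data["converged_epoch"]),
            )


def _bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    # max(l,0) - l·t + log1p(exp(-|l|)) — numerically stable sum.
    terms = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    return float(terms.sum(dtype=np.float64))


class _RMSProp:
    def __init__(self, params, grads, lr, rho=0.9, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, c in zip(self.params, self.grads, self.cache):
            c *= self.rho
            c += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


def _batch_losses(net: _Network, x: np.ndarray, rng: np.random.Generator | None):
    """Forward pass; returns (recon_sum, kl_sum, logits, mu, logvar, eps)."""
    mu, logvar = net.encode(x)
    logvar = np.clip(logvar, -10.0, 10.0)
    if rng is None:
        eps = np.zeros_like(mu)
    else:
        eps = rng.standard_normal(mu.shape, dtype=mu.dtype if mu.dtype == np.float32
                                  else np.float64)
    z = mu + eps * np.exp(0.5 * logvar)
    logits = net.decode(z)
    recon = _bce_with_logits(logits, x)
    kl = float(0.5 * np.sum(np.exp(logvar) + mu * mu - 1.0 - logvar,
                           dtype=np.float64))
    return recon, kl, logits, mu, logvar, eps


def train(dataset: ContactDataset, config: CvaeConfig) -> TrainedCVAE:
    """Fit the CVAE on the dataset's training split.

    Stops when the relative change of both the training and validation loss
    stays below ``convergence_tol`` for ``patience`` consecutive epochs, or
    at ``max_epochs``. Raises :class:`TrainingDivergedError` on non-finite
    loss. Fully seeded; the per-epoch history records the mean per-matrix
    training/validation loss and its reconstruction and KL terms.
    """
    if dataset.size != config.input_size:
        raise ValueError(
            f"dataset matrices are {dataset.size}×{dataset.size} but config.input_size "
            f"is {config.input_size}"
        )
    if dataset.train_indices.size == 0:
        raise EmptyInputError("training split is empty")

    rng = np.random.default_rng(config.seed)
    net = _Network(config, rng)
    opt = _RMSProp(net.params, net.grads, config.learning_rate)

    x_train = dataset.matrices[dataset.train_indices].astype(np.float32)[:, None, :, :]
    x_val = dataset.matrices[dataset.val_indices].astype(np.float32)[:, None, :, :]

    history: list[dict[str, float]] = []
    streak = 0
    prev_train = prev_val = None
    converged_epoch = config.max_epochs

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_train.shape[0])
        recon_total = kl_total = 0.0
        for start in range(0, order.size, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_train[idx]
            nb = xb.shape[0]
            recon, kl, logits, mu, logvar, eps = _batch_losses(net, xb, rng)
            if not np.isfinite(recon + kl):
                raise TrainingDivergedError(epoch)
            recon_total += recon
            kl_total += kl
            # Per-matrix mean objective.
            dlogits = (expit(logits) - xb) / nb
            dmu_extra = mu / nb
            dlogvar_extra = 0.5 * (np.exp(logvar) - 1.0) / nb
            net.backward(dlogits, dmu_extra, dlogvar_extra, eps, logvar)
            opt.step()

        n_train = x_train.shape[0]
        train_loss = (recon_total + kl_total) / n_train
        if x_val.shape[0]:
            recon_v, kl_v, *_ = _batch_losses(net, x_val, rng=None)
            val_loss = (recon_v + kl_v) / x_val.shape[0]
        else:
            val_loss = train_loss
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)
        history.append({
            "epoch": epoch,
            "train_loss": train_loss,
            "val_loss": val_loss,
            "reconstruction_term": recon_total / n_train,
            "kl_term": kl_total / n_train,
        })

        if prev_train is not None:
            rel_t = abs(train_loss - prev_train) / max(abs(prev_train), 1e-12)
            rel_v = abs(val_loss - prev_val) / max(abs(prev_val), 1e-12)
            streak = streak + 1 if (rel_t < config.convergence_tol and
                                    rel_v < config.convergence_tol) else 0
            if streak >= config.patience:
                converged_epoch = epoch
                break
        prev_train, prev_val = train_loss, val_loss
    else:
        converged_epoch = config.max_epochs

    return TrainedCVAE(config=config, network=net, history=history,
                       converged_epoch=converged_epoch)


def encode(model: TrainedCVAE, dataset: ContactDataset, batch_size: int = 256) -> LatentEmbedding:
    """Deterministic posterior-mean codes for every matrix in the dataset.

    The whole dataset (training and validation splits alike) is projected:
    the split exists only for the convergence check, while latent-space
    profiles are read from full ensembles.
    """
    if dataset.size != model.config.input_size:
        raise ValueError(
            f"dataset matrices are {dataset.size}×{dataset.size} but the model expects "
            f"{model.config.input_size}"
        )
    x = dataset.matrices.astype(np.float32)[:, None, :, :]
    codes = np.empty((x.shape[0], model.config.latent_dim))
    for start in range(0, x.shape[0], batch_size):
        mu, _ = model.network.encode(x[start:start + batch_size])
        codes[start:start + mu.shape[0]] = mu
    return LatentEmbedding(codes=codes, labels=list(dataset.labels),
                           source=f"cvae(seed={model.config.seed})")


def export_embedding_tsv(embedding: LatentEmbedding, path: str | Path) -> None:
    import pandas as pd

    frame = pd.DataFrame(embedding.labels, columns=["variant", "substrate", "frame"])
    for d in range(embedding.codes.shape[1]):
        frame[f"z{d}"] = embedding.codes[:, d]
    frame.to_csv(path, sep="\t", index=False)


def load_embedding_tsv(path: str | Path) -> LatentEmbedding:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    z_cols = sorted((c for c in frame.columns if c.startswith("z")),
                    key=lambda c: int(c[1:]))
    labels = [
        (str(v), str(s), int(f))
        for v, s, f in zip(frame["variant"], frame["substrate"], frame["frame"])
    ]
    return LatentEmbedding(codes=frame[z_cols].to_numpy(), labels=labels,
                           source=str(path))
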