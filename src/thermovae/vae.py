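"""Convolutional variational autoencoder for 8x8 thermal patches.

Gaussian encoder and Gaussian decoder with per-pixel mean and variance,
trained by minimizing the negative evidence lower bound (reconstruction
negative log-likelihood plus KL of the latent posterior against N(0, I)).

Architecture (input 1x8x8 patch, latent dimension 6 by default):

    encoder:  Conv(16, 2x2, stride 2) -> BatchNorm -> ReLU
              Conv(32, 2x2, stride 2) -> BatchNorm -> ReLU
              FC -> (mu_z, logvar_z)            spatial chain 8 -> 4 -> 2
    decoder:  FC -> BatchNorm -> ReLU -> reshape 32x2x2
              ConvT(32, 2x2, stride 2) -> BatchNorm -> ReLU
              ConvT(16, 2x2, stride 2) -> BatchNorm -> ReLU
              two parallel ConvT(1, 4x4, stride 1, same) heads
              -> (mu_x, logvar_x), each 8x8      spatial chain 2 -> 4 -> 8

The two stride-1 4x4 heads emit the per-pixel reconstruction mean and
log-variance; no activation follows them (a ReLU would forbid negative
log-variances), and the log-variance is floored for numerical stability
of the inverse-variance anomaly score.

Implemented directly on numpy with hand-derived backpropagation and an
Adam optimizer.  The stride-2 2x2 (de)convolutions have kernel == stride,
so they reduce exactly to per-block matrix products, which keeps both
passes simple and fast on CPU.  Everything is seeded and single-threaded
deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import PATCH_SIZE, Patch, PatchSet

#: compute dtype for training (weights, activations, optimizer state);
#: inference with float64 inputs upcasts automatically
DTYPE = np.float32

__all__ = [
    "VaeConfig",
    "EncoderOutput",
    "DecoderOutput",
    "TrainedVae",
    "encode",
    "decode",
    "reparameterize",
    "elbo_loss",
    "train_vae",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class VaeConfig:
    """Training hyperparameters.

    Defaults: 6 latent dimensions, 15 epochs, batch size 128, Adam with
    learning rate 1e-3.  ``n_candidates`` independent seeded initializations
    are trained and the model with the lowest final epoch loss is kept
    ("best model" selection).  ``variance_floor`` bounds the decoder's
    per-pixel variance from below so the inverse-variance score cannot
    diverge.
    """

    latent_dim: int = 6
    epochs: int = 15
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    variance_floor: float = 1e-4
    n_candidates: int = 3

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("latent_dim, batch_size and epochs must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass
class EncoderOutput:
    mu_z: np.ndarray      # (latent_dim,) or (n, latent_dim)
    logvar_z: np.ndarray


@dataclass
class DecoderOutput:
    mu_x: np.ndarray      # (8, 8) or (n, 8, 8)
    logvar_x: np.ndarray


# ---------------------------------------------------------------------------
# layers (forward caches live on the instance; backward fills .grads)

class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        s = math.sqrt(2.0 / nin)
        self.params = {"W": rng.normal(0.0, s, (nin, nout)).astype(DTYPE), "b": np.zeros(nout, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class _BlockConv:
    """2x2 convolution with stride 2 (kernel == stride -> block matmul)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        nin = cin * 4
        s = math.sqrt(2.0 / nin)
        self.cin, self.cout = cin, cout
        self.params = {"W": rng.normal(0.0, s, (nin, cout)).astype(DTYPE), "b": np.zeros(cout, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        blocks = (
            x.reshape(n, c, oh, 2, ow, 2)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n * oh * ow, c * 4)
        )
        self._blocks, self._shape = blocks, (n, c, h, w)
        y = blocks @ self.params["W"] + self.params["b"]
        return y.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        oh, ow = h // 2, w // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.cout)
        self.grads["W"][...] = self._blocks.T @ dyf
        self.grads["b"][...] = dyf.sum(axis=0)
        dblocks = dyf @ self.params["W"].T
        return (
            dblocks.reshape(n, oh, ow, c, 2, 2)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(n, c, h, w)
        )


class _BlockConvT:
    """2x2 transposed convolution with stride 2 (pixel -> 2x2 block)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        s = math.sqrt(2.0 / cin)
        self.cin, self.cout = cin, cout
        self.params = {"W": rng.normal(0.0, s, (cin, cout * 4)).astype(DTYPE), "b": np.zeros(cout, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self._flat, self._shape = flat, (n, c, h, w)
        y = flat @ self.params["W"]
        y = (
            y.reshape(n, h, w, self.cout, 2, 2)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(n, self.cout, 2 * h, 2 * w)
        )
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        self.grads["b"][...] = dy.sum(axis=(0, 2, 3))
        dyf = (
            dy.reshape(n, self.cout, h, 2, w, 2)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n * h * w, self.cout * 4)
        )
        self.grads["W"][...] = self._flat.T @ dyf
        dflat = dyf @ self.params["W"].T
        return dflat.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class _SameConv4:
    """4x4 stride-1 head with same-padding (8x8 -> 8x8).

    With stride 1 a transposed convolution is an ordinary convolution up
    to kernel flip, so the head is parameterized directly as a
    correlation; padding is 1 before / 2 after along each axis.
    """

    K = 4

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        nin = cin * self.K * self.K
        s = math.sqrt(2.0 / nin)
        self.cin, self.cout = cin, cout
        self.params = {
            "W": rng.normal(0.0, s, (cin, self.K * self.K, cout)).astype(DTYPE),
            "b": np.zeros(cout, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 2), (1, 2)))
        # im2col via a sliding-window view, materialized once as a matmul
        # operand of shape (n*h*w, c*16)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.K, self.K), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.K * self.K)
        self._cols, self._shape = cols, (n, c, h, w)
        y = cols @ self.params["W"].reshape(c * self.K * self.K, self.cout)
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2) + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        kk = self.K * self.K
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.grads["W"][...] = (self._cols.T @ dyf).reshape(c, kk, self.cout)
        self.grads["b"][...] = dyf.sum(axis=0)
        # input gradient = correlation of dy (padded 2 before / 1 after,
        # mirroring the forward padding) with the spatially flipped kernel
        dyp = np.pad(dy, ((0, 0), (0, 0), (2, 1), (2, 1)))
        win = np.lib.stride_tricks.sliding_window_view(dyp, (self.K, self.K), axis=(2, 3))
        colsd = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, self.cout * kk)
        wflip = self.params["W"].reshape(c, self.K, self.K, self.cout)[:, ::-1, ::-1, :]
        wback = wflip.reshape(c, kk, self.cout).transpose(2, 1, 0).reshape(self.cout * kk, c)
        return (colsd @ wback).reshape(n, h, w, c).transpose(0, 3, 1, 2)


class _BatchNorm:
    """Batch normalization over the channel axis (conv) or features (dense)."""

    def __init__(self, c: int, conv: bool, momentum: float = 0.1, eps: float = 1e-5):
        self.conv = conv
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(c, dtype=DTYPE), "beta": np.zeros(c, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def _axes(self) -> tuple[int, ...]:
        return (0, 2, 3) if self.conv else (0,)

    def _bc(self, v: np.ndarray) -> np.ndarray:
        return v[None, :, None, None] if self.conv else v[None, :]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = self._axes()
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) / self._bc(std)
        self._xhat, self._std, self._train = xhat, std, train
        return self._bc(self.params["gamma"]) * xhat + self._bc(self.params["beta"])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = self._axes()
        xhat = self._xhat
        self.grads["gamma"][...] = (dy * xhat).sum(axis=axes)
        self.grads["beta"][...] = dy.sum(axis=axes)
        dxhat = dy * self._bc(self.params["gamma"])
        if not self._train:
            return dxhat / self._bc(self._std)
        m = dy.size // dy.shape[1]
        return (
            dxhat
            - self._bc(dxhat.sum(axis=axes) / m)
            - xhat * self._bc((dxhat * xhat).sum(axes) / m)
        ) / self._bc(self._std)


class _ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


# ---------------------------------------------------------------------------
# network

class VaeNetwork:
    """Encoder + decoder parameter container with explicit passes."""

    def __init__(self, config: VaeConfig, rng: np.random.Generator):
        self.config = config
        d = config.latent_dim
        self.enc_layers = [
            _BlockConv(1, 16, rng), _BatchNorm(16, conv=True), _ReLU(),
            _BlockConv(16, 32, rng), _BatchNorm(32, conv=True), _ReLU(),
        ]
        self.enc_fc = _Dense(32 * 2 * 2, 2 * d, rng)
        self.dec_fc = _Dense(d, 32 * 2 * 2, rng)
        self.dec_layers = [
            _BatchNorm(32 * 2 * 2, conv=False), _ReLU(),
        ]
        self.dec_convs = [
            _BlockConvT(32, 32, rng), _BatchNorm(32, conv=True), _ReLU(),
            _BlockConvT(32, 16, rng), _BatchNorm(16, conv=True), _ReLU(),
        ]
        self.head_mu = _SameConv4(16, 1, rng)
        self.head_logvar = _SameConv4(16, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _modules(self) -> list:
        return (
            self.enc_layers + [self.enc_fc, self.dec_fc] + self.dec_layers
            + self.dec_convs + [self.head_mu, self.head_logvar]
        )

    def parameters(self) -> list[tuple[int, str, np.ndarray]]:
        out = []
        for i, m in enumerate(self._modules()):
            for name, p in m.params.items():
                out.append((i, name, p))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, m in enumerate(self._modules()):
            for name, p in m.params.items():
                state[f"m{i}.{name}"] = p
            if isinstance(m, _BatchNorm):
                state[f"m{i}.running_mean"] = m.running_mean
                state[f"m{i}.running_var"] = m.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self._modules()):
            for name in m.params:
                m.params[name] = state[f"m{i}.{name}"].astype(DTYPE)
            if isinstance(m, _BatchNorm):
                m.running_mean = state[f"m{i}.running_mean"].astype(DTYPE)
                m.running_var = state[f"m{i}.running_var"].astype(DTYPE)

    # -- passes -------------------------------------------------------------
    def encode_batch(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """x: (n, 1, 8, 8) -> (mu_z, logvar_z), each (n, latent_dim)."""
        h = x
        for layer in self.enc_layers:
            h = layer.forward(h, train)
        h = h.reshape(h.shape[0], -1)
        out = self.enc_fc.forward(h, train)
        d = self.config.latent_dim
        return out[:, :d], out[:, d:]

    def decode_batch(self, z: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """z: (n, latent_dim) -> (mu_x, logvar_x), each (n, 1, 8, 8)."""
        h = self.dec_fc.forward(z, train)
        for layer in self.dec_layers:
            h = layer.forward(h, train)
        h = h.reshape(h.shape[0], 32, 2, 2)
        for layer in self.dec_convs:
            h = layer.forward(h, train)
        mu_x = self.head_mu.forward(h, train)
        logvar_raw = self.head_logvar.forward(h, train)
        lo = math.log(self.config.variance_floor)
        self._logvar_mask = (logvar_raw > lo) & (logvar_raw < 10.0)
        return mu_x, np.clip(logvar_raw, lo, 10.0)

    def backward_decoder(self, dmu_x: np.ndarray, dlogvar_x: np.ndarray) -> np.ndarray:
        """Backpropagate output gradients through the decoder; returns dz."""
        dh = self.head_mu.backward(dmu_x)
        dh += self.head_logvar.backward(dlogvar_x * self._logvar_mask)
        for layer in reversed(self.dec_convs):
            dh = layer.backward(dh)
        dh = dh.reshape(dh.shape[0], -1)
        for layer in reversed(self.dec_layers):
            dh = layer.backward(dh)
        return self.dec_fc.backward(dh)

    def backward_encoder(self, dmu_z: np.ndarray, dlogvar_z: np.ndarray) -> None:
        """Backpropagate latent gradients through the encoder."""
        dout = np.concatenate([dmu_z, dlogvar_z], axis=1)
        dh = self.enc_fc.backward(dout)
        dh = dh.reshape(dh.shape[0], 32, 2, 2)
        for layer in reversed(self.enc_layers):
            dh = layer.backward(dh)


@dataclass
class TrainedVae:
    """A fitted patch VAE plus its config and per-epoch mean loss."""

    network: VaeNetwork
    config: VaeConfig
    training_loss_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# public functional surface

def _as_batch(patch: Patch | np.ndarray) -> np.ndarray:
    x = patch.pixels if isinstance(patch, Patch) else np.asarray(patch, dtype=float)
    if x.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"invalid-input: expected {PATCH_SIZE}x{PATCH_SIZE} patch, got {x.shape}")
    return x[None, None]


def encode(patch: Patch | np.ndarray, model: TrainedVae) -> EncoderOutput:
    """Deterministic inference-mode encoding of one patch."""
    mu, lv = model.network.encode_batch(_as_batch(patch), train=False)
    return EncoderOutput(mu_z=mu[0], logvar_z=lv[0])


def decode(z: np.ndarray, model: TrainedVae) -> DecoderOutput:
    """Deterministic inference-mode decoding of one latent vector."""
    z = np.asarray(z, dtype=float)
    if z.shape != (model.config.latent_dim,):
        raise ValueError(f"invalid-input: expected latent of length {model.config.latent_dim}")
    mu, lv = model.network.decode_batch(z[None], train=False)
    return DecoderOutput(mu_x=mu[0, 0], logvar_x=lv[0, 0])


def reparameterize(enc: EncoderOutput, rng: np.random.Generator) -> np.ndarray:
    """Sample z = mu + sigma * eps with eps ~ N(0, I) (training-time only)."""
    eps = rng.standard_normal(enc.mu_z.shape)
    return enc.mu_z + np.exp(0.5 * enc.logvar_z) * eps


def elbo_loss(
    patch: Patch | np.ndarray, enc: EncoderOutput, dec: DecoderOutput
) -> float:
    """Negative ELBO of one patch (reconstruction NLL + KL), up to constants.

    loss = sum_i [ (mu_xi - x_i)^2 / (2 sigma^2_xi) + 0.5 log sigma^2_xi ]
         + 0.5 sum_j [ mu_zj^2 + exp(logvar_zj) - logvar_zj - 1 ]
    """
    x = patch.pixels if isinstance(patch, Patch) else np.asarray(patch, dtype=float)
    var = np.exp(dec.logvar_x)
    recon = np.sum((dec.mu_x - x) ** 2 / (2.0 * var) + 0.5 * dec.logvar_x)
    kl = 0.5 * np.sum(enc.mu_z**2 + np.exp(enc.logvar_z) - enc.logvar_z - 1.0)
    total = float(recon + kl)
    if not np.isfinite(total):
        raise FloatingPointError("numerical-failure: non-finite ELBO")
    return total


class _Adam:
    def __init__(self, net: VaeNetwork, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, b1, b2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, _, p in net.parameters()]
        self.v = [np.zeros_like(p) for _, _, p in net.parameters()]

    def step(self) -> None:
        self.t += 1
        mods = self.net._modules()
        k = 0
        for i, name, p in self.net.parameters():
            g = mods[i].grads[name]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            k += 1


def _train_once(X: np.ndarray, config: VaeConfig, seed_key: list[int]) -> tuple[VaeNetwork, list[float]]:
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    net = VaeNetwork(config, rng)
    opt = _Adam(net, config.learning_rate)
    n = X.shape[0]
    history: list[float] = []
    lo = math.log(config.variance_floor)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            nb = xb.shape[0]
            mu_z, logvar_z = net.encode_batch(xb, train=True)
            eps = rng.standard_normal(mu_z.shape).astype(DTYPE)
            sigma_z = np.exp(0.5 * logvar_z)
            z = mu_z + sigma_z * eps
            mu_x, logvar_x = net.decode_batch(z, train=True)
            var_x = np.exp(logvar_x)
            resid = mu_x - xb
            recon = np.sum(resid**2 / (2 * var_x) + 0.5 * logvar_x)
            kl = 0.5 * np.sum(mu_z**2 + np.exp(logvar_z) - logvar_z - 1.0)
            loss = (recon + kl) / nb
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training-failure: non-finite loss at epoch {epoch + 1}"
                )
            total += float(loss) * nb
            # gradients of the batch-mean loss
            dmu_x = resid / var_x / nb
            dlogvar_x = (0.5 - resid**2 / (2 * var_x)) / nb
            dz = net.backward_decoder(dmu_x, dlogvar_x)
            # latent grads: KL term plus the reparameterization path
            dmu_z = mu_z / nb + dz
            dlogvar_z = 0.5 * (np.exp(logvar_z) - 1.0) / nb + dz * eps * 0.5 * sigma_z
            net.backward_encoder(dmu_z, dlogvar_z)
            opt.step()
        history.append(total / n)
    return net, history


def train_vae(learning: PatchSet, config: VaeConfig | None = None) -> TrainedVae:
    """Train the patch VAE, selecting the best of several seeded inits.

    ``config.n_candidates`` networks are trained from independent seeded
    initializations; the one with the lowest final epoch loss is returned
    along with its per-epoch mean loss history (``config.epochs`` entries).
    """
    if config is None:
        config = VaeConfig()
    if learning.role != "learning":
        raise ValueError("invalid-input: patch set role must be 'learning'")
    if len(learning) < config.batch_size:
        raise ValueError("invalid-input: need at least one full batch of patches")
    X = learning.as_array()[:, None, :, :].astype(DTYPE)
    best: tuple[VaeNetwork, list[float]] | None = None
    for cand in range(config.n_candidates):
        net, hist = _train_once(X, config, [int(config.seed), 3, cand])
        if best is None or hist[-1] < best[1][-1]:
            best = (net, hist)
    assert best is not None
    return TrainedVae(network=best[0], config=config, training_loss_history=best[1])


# ---------------------------------------------------------------------------
# persistence: npz weights + JSON sidecar

def save_model(model: TrainedVae, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out_dir / "weights.npz", **model.network.state_arrays())
    sidecar = {
        "config": asdict(model.config),
        "training_loss_history": model.training_loss_history,
    }
    (out_dir / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(model_dir: str | Path) -> TrainedVae:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    config = VaeConfig(**sidecar["config"])
    net = VaeNetwork(config, np.random.default_rng(0))
    with np.load(model_dir / "weights.npz") as z:
        net.load_state_arrays({k: z[k] for k in z.files})
    return TrainedVae(
        network=net, config=config,
        training_loss_history=list(sidecar["training_loss_history"]),
    )
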