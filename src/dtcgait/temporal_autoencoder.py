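"""Temporal autoencoder (TAE) for fixed-length gait-cycle rows.

Encoder: one 1D convolution (kernel 10, stride 1, same padding) with leaky
ReLU, max pooling, then two bidirectional LSTM layers whose hidden widths
default to 50 and 1.  The second Bi-LSTM's forward/backward outputs form
the latent sequence z of shape (T_in / pool_size) x 2.  Decoder:
nearest-neighbour upsampling by the pool size followed by a transposed
convolution (kernel 10, stride 1, same padding, linear output).

Pretraining minimizes the mean squared reconstruction error with Adam.
All computation runs in float64 on the package's autodiff tape, so runs
are bit-reproducible for a given seed and thread-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._autodiff import Var, concat, split_cols, stack_time, unfold1d, unstack_time
from .gait_io import GaitTensor

__all__ = ["TAEConfig", "TAE", "mse_loss", "pretrain", "AdamOptimizer"]


@dataclass
class TAEConfig:
    kernel_size: int = 10
    stride: int = 1
    pool_size: int = 10
    conv_channels: int = 50
    hidden1: int = 50
    hidden2: int = 1
    leaky_slope: float = 0.01
    pretrain_epochs: int = 10
    pretrain_lr: float = 0.001
    batch_size: int = 32
    seed: int = 0
    multichannel: bool = False  # present rows as 6 channels x T instead of 1 x 6T

    def __post_init__(self):
        for name in ("kernel_size", "pool_size", "conv_channels", "hidden1",
                     "hidden2", "pretrain_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported (same-padding design)")


def mse_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared reconstruction error over all instances and features."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def _mse_var(x: Var, x_hat: Var) -> Var:
    return ((x - x_hat) ** 2).mean()


class TAE:
    """The temporal autoencoder with explicit float64 parameters."""

    def __init__(self, config: TAEConfig, input_length: int):
        self.config = config
        self.input_length = input_length
        cfg = config
        if cfg.multichannel:
            if input_length % 6 != 0:
                raise ValueError("multichannel mode needs input length divisible by 6")
            self.in_channels, self.seq_len = 6, input_length // 6
        else:
            self.in_channels, self.seq_len = 1, input_length
        if self.seq_len % cfg.pool_size != 0:
            need = cfg.pool_size - self.seq_len % cfg.pool_size
            raise ValueError(
                f"sequence length {self.seq_len} not divisible by pool_size "
                f"{cfg.pool_size}; pad input to {self.seq_len + need}"
            )
        self.latent_steps = self.seq_len // cfg.pool_size
        self.latent_width = 2 * cfg.hidden2
        self.latent_dim = self.latent_steps * self.latent_width

        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Var] = {}

        def param(name, shape, scale):
            self.params[name] = Var(
                rng.uniform(-scale, scale, shape), requires_grad=True
            )

        k, cc = cfg.kernel_size, cfg.conv_channels
        param("conv_w", (k * self.in_channels, cc), 1.0 / np.sqrt(k * self.in_channels))
        param("conv_b", (cc,), 1.0 / np.sqrt(k * self.in_channels))
        for layer, (din, h) in enumerate(
            [(cc, cfg.hidden1), (2 * cfg.hidden1, cfg.hidden2)], start=1
        ):
            s = 1.0 / np.sqrt(h)
            for d in ("f", "b"):
                param(f"lstm{layer}{d}_wx", (din, 4 * h), s)
                param(f"lstm{layer}{d}_wh", (h, 4 * h), s)
                param(f"lstm{layer}{d}_b", (4 * h,), s)
        kd = k * self.latent_width
        param("dec_w", (kd, self.in_channels), 1.0 / np.sqrt(kd))
        param("dec_b", (self.in_channels,), 1.0 / np.sqrt(kd))

    # -- layers ---------------------------------------------------------

    def _lstm_dir(self, x: Var, prefix: str, hidden: int, reverse: bool) -> list[Var]:
        n, steps = x.shape[0], x.shape[1]
        wx, wh, b = (self.params[f"{prefix}_{s}"] for s in ("wx", "wh", "b"))
        # input-to-hidden contribution for all steps in one matmul
        xw = unstack_time((x @ wx + b).reshape(n, steps, 4 * hidden))
        h = Var(np.zeros((n, hidden)))
        c = Var(np.zeros((n, hidden)))
        order = range(steps - 1, -1, -1) if reverse else range(steps)
        outs: list[Var | None] = [None] * steps
        for t in order:
            gates = xw[t] + h @ wh
            i, f, g, o = split_cols(gates, 4)
            c = f.sigmoid() * c + i.sigmoid() * g.tanh()
            h = o.sigmoid() * c.tanh()
            outs[t] = h
        return outs  # type: ignore[return-value]

    def _bilstm(self, x: Var, layer: int, hidden: int) -> Var:
        fwd = self._lstm_dir(x, f"lstm{layer}f", hidden, reverse=False)
        bwd = self._lstm_dir(x, f"lstm{layer}b", hidden, reverse=True)
        return concat([stack_time(fwd), stack_time(bwd)], axis=2)  # (N, steps, 2H)

    def encode(self, x) -> Var:
        """Rows (N, F) -> latent sequence (N, latent_steps, 2*hidden2)."""
        cfg = self.config
        x = x if isinstance(x, Var) else Var(x)
        n = x.shape[0]
        if x.shape[1] != self.input_length:
            raise ValueError(f"expected rows of length {self.input_length}")
        # (N, F) -> (N, T, C): multichannel rows are channel blocks concatenated
        xc = x.reshape(n, self.in_channels, self.seq_len).transpose(0, 2, 1)
        k = cfg.kernel_size
        cols = unfold1d(xc, k, (k - 1) // 2, k // 2)
        conv = (cols @ self.params["conv_w"] + self.params["conv_b"]).leaky_relu(
            cfg.leaky_slope
        )
        pooled = conv.reshape(
            n, self.latent_steps, cfg.pool_size, cfg.conv_channels
        ).max(axis=2)
        h1 = self._bilstm(pooled, 1, cfg.hidden1)
        return self._bilstm(h1, 2, cfg.hidden2)

    def decode(self, z: Var) -> Var:
        """Latent (N, latent_steps, 2*hidden2) -> reconstruction rows (N, F)."""
        cfg = self.config
        z = z if isinstance(z, Var) else Var(z)
        if z.shape[1:] != (self.latent_steps, self.latent_width):
            raise ValueError(
                f"latent shape {z.shape[1:]} != "
                f"({self.latent_steps}, {self.latent_width})"
            )
        n = z.shape[0]
        up = z.repeat(cfg.pool_size, axis=1)  # (N, seq_len, 2*hidden2)
        k = cfg.kernel_size
        cols = unfold1d(up, k, k // 2, (k - 1) // 2)
        rec = cols @ self.params["dec_w"] + self.params["dec_b"]  # (N, seq_len, C)
        return rec.transpose(0, 2, 1).reshape(n, self.input_length)

    def forward(self, x) -> tuple[Var, Var]:
        z = self.encode(x)
        return z, self.decode(z)

    def latent_matrix(self, rows: np.ndarray) -> np.ndarray:
        """Flattened latent features (N, latent_dim) without gradient tape."""
        return self.encode(rows).data.reshape(len(rows), self.latent_dim)

    # -- state ----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in self.params.items():
            v.data = np.array(state[k], dtype=np.float64).reshape(v.data.shape)

    def save(self, path):
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, config: TAEConfig, input_length: int) -> "TAE":
        model = cls(config, input_length)
        with np.load(path) as st:
            model.load_state_dict(dict(st))
        return model


class AdamOptimizer:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params: list[Var], lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def pretrain(tensor: GaitTensor | np.ndarray, config: TAEConfig | None = None
             ) -> tuple[TAE, list[float]]:
    """Pretrain a TAE on the cohort rows, minimizing reconstruction MSE.

    Returns the model and the per-epoch loss history (full-data loss
    evaluated with the parameters at the end of each epoch).  Minibatch
    order is drawn from the config seed.
    """
    config = config or TAEConfig()
    rows = tensor.matrix if isinstance(tensor, GaitTensor) else np.asarray(tensor)
    n = rows.shape[0]
    model = TAE(config, rows.shape[1])
    opt = AdamOptimizer(list(model.params.values()), config.pretrain_lr)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = rows[order[start : start + config.batch_size]]
            opt.zero_grad()
            _, xhat = model.forward(batch)
            loss = _mse_var(Var(batch), xhat)
            loss.backward()
            if not np.isfinite(loss.data):
                raise FloatingPointError("NaN/inf reconstruction loss")
            opt.step()
        _, xhat = model.forward(rows)
        epoch_loss = mse_loss(rows, xhat.data)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError("NaN/inf reconstruction loss")
        history.append(epoch_loss)
    return model, history


def clone_config(config: TAEConfig, **changes) -> TAEConfig:
    return replace(config, **changes)
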