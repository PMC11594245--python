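"""The spectral embedding network f: R^D -> R^M and its optimizer.

The network is a stack of identical blocks, each BatchNorm -> Linear ->
LeakyReLU.  Batch normalization sits *before* the linear layer so that the
raw spectrum itself is rescaled on entry — reflectance bands differ in scale
and this stabilizes training on NIR data.  The first linear layer maps the
D retained bands to the hidden width (default 256); all later blocks are
width-preserving, so the embedding dimension M equals the hidden width.

Forward passes in training mode return an explicit cache (a tape) so that
several forward passes (e.g. support set and query batch of one episode) can
be back-propagated independently within one optimization step; gradients
accumulate into ``EmbeddingNetwork.grads``.  Inference uses the running
batch-norm statistics, making the embedding of a spectrum independent of
whatever else is in its batch.

Implemented directly on numpy arrays with hand-derived gradients; a
finite-difference check in the test suite pins the backward pass to the
forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = ["NetworkConfig", "EmbeddingNetwork", "Adam"]


@dataclass
class NetworkConfig:
    input_dim: int
    hidden_dim: int = 256
    n_blocks: int = 4
    negative_slope: float = 0.01  # LeakyReLU
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise InputError("input_dim must be >= 1")
        if self.n_blocks < 1:
            raise InputError("n_blocks must be >= 1")

    @property
    def embedding_dim(self) -> int:
        return self.hidden_dim


class _BatchNorm:
    """1-D batch normalization with affine parameters and running statistics."""

    def __init__(self, dim: int, eps: float, momentum: float):
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: np.ndarray, training: bool):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)  # biased, used for normalization
            n = x.shape[0]
            unbiased = var * n / (n - 1) if n > 1 else var
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mu) * inv_std
        out = self.gamma * x_hat + self.beta
        cache = (x_hat, inv_std, training)
        return out, cache

    def backward(self, dout: np.ndarray, cache, grads: dict, prefix: str):
        x_hat, inv_std, training = cache
        grads[prefix + "gamma"] += (dout * x_hat).sum(axis=0)
        grads[prefix + "beta"] += dout.sum(axis=0)
        if not training:
            return dout * self.gamma * inv_std
        n = dout.shape[0]
        dxhat = dout * self.gamma
        # batch statistics participate in the forward pass
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - x_hat * (dxhat * x_hat).sum(axis=0))
        )


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b, x

    def backward(self, dout: np.ndarray, cache, grads: dict, prefix: str):
        x = cache
        grads[prefix + "W"] += x.T @ dout
        grads[prefix + "b"] += dout.sum(axis=0)
        return dout @ self.W.T


class EmbeddingNetwork:
    """Stack of BatchNorm -> Linear -> LeakyReLU blocks."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.bns: list[_BatchNorm] = []
        self.linears: list[_Linear] = []
        d_in = config.input_dim
        for _ in range(config.n_blocks):
            self.bns.append(_BatchNorm(d_in, config.bn_eps, config.bn_momentum))
            self.linears.append(_Linear(d_in, config.hidden_dim, rng))
            d_in = config.hidden_dim
        self.grads: dict[str, np.ndarray] = {}
        self.zero_grads()

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        params = {}
        for i, (bn, lin) in enumerate(zip(self.bns, self.linears)):
            params[f"b{i}.bn.gamma"] = bn.gamma
            params[f"b{i}.bn.beta"] = bn.beta
            params[f"b{i}.lin.W"] = lin.W
            params[f"b{i}.lin.b"] = lin.b
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = dict(self.parameters())
        for i, bn in enumerate(self.bns):
            state[f"b{i}.bn.running_mean"] = bn.running_mean
            state[f"b{i}.bn.running_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (bn, lin) in enumerate(zip(self.bns, self.linears)):
            bn.gamma = np.array(state[f"b{i}.bn.gamma"])
            bn.beta = np.array(state[f"b{i}.bn.beta"])
            bn.running_mean = np.array(state[f"b{i}.bn.running_mean"])
            bn.running_var = np.array(state[f"b{i}.bn.running_var"])
            lin.W = np.array(state[f"b{i}.lin.W"])
            lin.b = np.array(state[f"b{i}.lin.b"])

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.parameters().items()}

    # -- forward / backward ----------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.config.input_dim:
            raise InputError(
                f"expected spectra with D={self.config.input_dim}, got {x.shape[1]}"
            )
        return x

    def forward_train(self, x: np.ndarray):
        """Training-mode forward; returns (embeddings, tape for backward)."""
        x = self._check_input(x)
        tape = []
        for bn, lin in zip(self.bns, self.linears):
            x, bn_cache = bn.forward(x, training=True)
            x, lin_cache = lin.forward(x)
            relu_mask = np.where(x > 0, 1.0, self.config.negative_slope)
            x = x * relu_mask
            tape.append((bn_cache, lin_cache, relu_mask))
        return x, tape

    def backward(self, dout: np.ndarray, tape) -> np.ndarray:
        """Accumulate parameter gradients for one taped forward pass."""
        for i in reversed(range(len(tape))):
            bn_cache, lin_cache, relu_mask = tape[i]
            dout = dout * relu_mask
            dout = self.linears[i].backward(dout, lin_cache, self.grads, f"b{i}.lin.")
            dout = self.bns[i].backward(dout, bn_cache, self.grads, f"b{i}.bn.")
        return dout

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode embedding N x D -> N x M using running statistics."""
        x = self._check_input(x)
        for bn, lin in zip(self.bns, self.linears):
            x, _ = bn.forward(x, training=False)
            x, _ = lin.forward(x)
            x = np.where(x > 0, x, self.config.negative_slope * x)
        return x


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)
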