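"""Neural layers for the recurrent extractor: embedding, bidirectional
LSTM/GRU, dropout, dense, and the Adam optimizer.

All layers operate on per-timestep batches: a sequence is a list of T
tensors of shape (batch, features), which keeps the graph 2-D throughout
and makes bidirectional scans explicit.
"""
from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int, cols: int) -> np.ndarray:
    """Orthogonal recurrent init (stacked column blocks for fused gates)."""
    blocks = []
    for _ in range(cols // n):
        a = rng.standard_normal((n, n))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


class Layer:
    def params(self) -> list[Tensor]:
        raise NotImplementedError


class Embedding(Layer):
    """Maps integer residue indices to dense vectors."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weights = Tensor(rng.normal(0.0, 0.1, size=(vocab_size, dim)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return ag.embedding_lookup(self.weights, indices)

    def params(self):
        return [self.weights]


class Dense(Layer):
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, fan_in, fan_out, (fan_in, fan_out)))
        self.b = Tensor(np.zeros(fan_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.W) + self.b

    def params(self):
        return [self.W, self.b]


class _LSTMDirection:
    """One direction of an LSTM with fused gate weights (order i, f, g, o)."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = Tensor(_glorot(rng, input_dim, units, (input_dim, 4 * units)))
        self.Wh = Tensor(_orthogonal(rng, units, 4 * units))
        bias = np.zeros(4 * units)
        bias[units: 2 * units] = 1.0  # forget-gate bias: remember by default
        self.b = Tensor(bias)

    def scan(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.units)), requires_grad=False)
        c = Tensor(np.zeros((batch, self.units)), requires_grad=False)
        H = self.units
        outputs = []
        for x in xs:
            z = ag.matmul(x, self.Wx) + ag.matmul(h, self.Wh) + self.b
            i = ag.sigmoid(ag.slice_cols(z, 0, H))
            f = ag.sigmoid(ag.slice_cols(z, H, 2 * H))
            g = ag.tanh(ag.slice_cols(z, 2 * H, 3 * H))
            o = ag.sigmoid(ag.slice_cols(z, 3 * H, 4 * H))
            c = f * c + i * g
            h = o * ag.tanh(c)
            outputs.append(h)
        return outputs

    def params(self):
        return [self.Wx, self.Wh, self.b]


class _GRUDirection:
    """One direction of a GRU (update/reset gates, no memory cell)."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx_zr = Tensor(_glorot(rng, input_dim, units, (input_dim, 2 * units)))
        self.Wh_zr = Tensor(_orthogonal(rng, units, 2 * units))
        self.b_zr = Tensor(np.zeros(2 * units))
        self.Wx_n = Tensor(_glorot(rng, input_dim, units, (input_dim, units)))
        self.Wh_n = Tensor(_orthogonal(rng, units, units))
        self.b_n = Tensor(np.zeros(units))

    def scan(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.units)), requires_grad=False)
        H = self.units
        outputs = []
        for x in xs:
            zr = ag.sigmoid(ag.matmul(x, self.Wx_zr) + ag.matmul(h, self.Wh_zr) + self.b_zr)
            z = ag.slice_cols(zr, 0, H)
            r = ag.slice_cols(zr, H, 2 * H)
            n = ag.tanh(ag.matmul(x, self.Wx_n) + r * ag.matmul(h, self.Wh_n) + self.b_n)
            h = n + z * (h - n)  # z=1 keeps past state, z=0 takes the candidate
            outputs.append(h)
        return outputs

    def params(self):
        return [self.Wx_zr, self.Wh_zr, self.b_zr, self.Wx_n, self.Wh_n, self.b_n]


class _Bidirectional(Layer):
    """Runs a forward and a backward scan and concatenates them per position."""

    def __init__(self, forward, backward):
        self.forward = forward
        self.backward = backward

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        fwd = self.forward.scan(xs)
        bwd = list(reversed(self.backward.scan(list(reversed(xs)))))
        return [ag.concat([f, b], axis=1) for f, b in zip(fwd, bwd)]

    def params(self):
        return self.forward.params() + self.backward.params()


class BiLSTM(_Bidirectional):
    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        super().__init__(
            _LSTMDirection(input_dim, units, rng), _LSTMDirection(input_dim, units, rng)
        )


class BiGRU(_Bidirectional):
    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        super().__init__(
            _GRUDirection(input_dim, units, rng), _GRUDirection(input_dim, units, rng)
        )


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask, requires_grad=False)

    def params(self):
        return []


class Adam:
    """Adam optimizer over a fixed parameter list; zeroes grads after step()."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            p.grad = None
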