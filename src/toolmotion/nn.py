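"""NumPy building blocks for the sequence classifier.

Implements the standard LSTM cell (one hidden layer, tanh cell activation),
a one-hidden-layer ReLU MLP head with a single sigmoid output unit applied
per timestep, inverted dropout, the Adam optimizer, and the class-weighted
binary cross-entropy loss.  Everything is batch-vectorized and fully
deterministic given a ``numpy.random.Generator``.

Shapes: feature sequences are ``(B, T, D)``; hidden sequences ``(B, T, H)``;
per-timestep probabilities ``(B, T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Clipping bound for probabilities inside the cross-entropy.
EPS = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class LSTM:
    """Single-layer LSTM, hidden size H, causal by construction.

    Gate order in the stacked weight matrices is (i, f, g, o): input gate,
    forget gate, candidate (tanh), output gate.  The forget-gate bias is
    initialized to 1, a common stabilizer for short-sequence training.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        H = hidden_dim
        self.W = glorot(rng, input_dim, 4 * H)
        self.U = glorot(rng, H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "U": self.U, "b": self.b}

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Run the recurrence over (B, T, D); return hidden states (B, T, H)."""
        B, T, D = X.shape
        H = self.hidden_dim
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = X[:, t] @ self.W + h @ self.U + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if train:
                cache.append((X[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            Hs[:, t] = h
        self._cache = cache if train else None
        return Hs

    def backward(self, dHs: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """BPTT given upstream gradients on every hidden state."""
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward")
        B, T, H = dHs.shape
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.empty((B, T, self.input_dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dHs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return {"W": dW, "U": dU, "b": db}, dX


class MLPHead:
    """One hidden ReLU layer + single sigmoid output unit, applied per timestep."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.W1 = glorot(rng, input_dim, hidden_dim)
        self.b1 = np.zeros(hidden_dim)
        self.w2 = glorot(rng, hidden_dim, 1)
        self.b2 = np.zeros(1)
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def forward(self, Hs: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, T, H) -> per-timestep probabilities (B, T), all in (0, 1)."""
        B, T, H = Hs.shape
        flat = Hs.reshape(B * T, H)
        a = flat @ self.W1 + self.b1
        relu = np.maximum(a, 0.0)
        z = relu @ self.w2 + self.b2
        p = sigmoid(z).reshape(B, T)
        if train:
            self._cache = (flat, relu, p)
        return p

    def backward(self, dz: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backprop from gradients on the pre-sigmoid logit (B, T)."""
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward")
        flat, relu, p = self._cache
        B, T = dz.shape
        dzf = dz.reshape(B * T, 1)
        dw2 = relu.T @ dzf
        db2 = dzf.sum(axis=0)
        drelu = dzf @ self.w2.T
        da = drelu * (relu > 0)
        dW1 = flat.T @ da
        db1 = da.sum(axis=0)
        dflat = da @ self.W1.T
        return (
            {"W1": dW1, "b1": db1, "w2": dw2, "b2": db2},
            dflat.reshape(B, T, -1),
        )


class Dropout:
    """Inverted dropout; identity at rate 0 or in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, rng: np.random.Generator, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dx: np.ndarray) -> np.ndarray:
        return dx if self._mask is None else dx * self._mask


@dataclass
class Adam:
    """Adam with the standard bias correction; one state slot per parameter id."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        for key, p in params.items():
            g = grads[key]
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            mhat = m / (1 - self.beta1**self._t)
            vhat = v / (1 - self.beta2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_bce(
    p: np.ndarray, y: np.ndarray, class_weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Class-weighted binary cross-entropy, averaged over timesteps and batch.

    ``p`` is (B, T) (or (T,)), ``y`` is the per-sequence 0/1 label;
    ``class_weights`` are (w_negative, w_positive).  Probabilities are
    clipped to [EPS, 1-EPS].  Reduces to plain BCE at unit weights and
    scales linearly in the weight of the true class.
    """
    p = np.atleast_2d(np.clip(p, EPS, 1.0 - EPS))
    y = np.atleast_1d(y).astype(float)
    w = np.where(y == 1, class_weights[1], class_weights[0])
    per_seq = -(y[:, None] * np.log(p) + (1 - y[:, None]) * np.log(1 - p)).mean(axis=1)
    return float((w * per_seq).mean())


def weighted_bce_logit_grad(
    p: np.ndarray, y: np.ndarray, class_weights: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """d(loss)/d(logit) for the loss above: w_y * (p - y) / (T * B)."""
    B, T = p.shape
    y = y.astype(float)
    w = np.where(y == 1, class_weights[1], class_weights[0])
    return (w[:, None] * (p - y[:, None])) / (T * B)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float = 5.0) -> None:
    """Global-norm gradient clipping, in place."""
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
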