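"""Neural-network layers and the Adam optimizer on top of the autodiff engine.

Layers follow the usual conventions: inputs are batched ``(B, T, D)`` or
``(B, D)`` tensors, parameters are float64, initialisation is Glorot-uniform
drawn from a caller-supplied :class:`numpy.random.Generator` so every model in
the package is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, exp, relu, sigmoid, stack, tanh

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "MultiheadSelfAttention",
    "PositionwiseFFN", "LSTM", "Adam", "softmax", "clip_grad_norm",
    "sinusoidal_positional_encoding",
]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def sinusoidal_positional_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine position code from the original attention paper."""
    pos = np.arange(n_positions)[:, None].astype(np.float64)
    i = np.arange(dim)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.zeros((n_positions, dim))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data.copy()
            elif isinstance(v, Module):
                for k, arr in v.state_dict().items():
                    out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_dict().items():
                            out[f"{name}.{i}.{k}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in state.items():
            obj = self
            *path, leaf = key.split(".")
            for part in path:
                obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
            getattr(obj, leaf).data[...] = arr


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, d_in, d_out, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps) ** 0.5 * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only when the caller passes a generator."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if rng is None or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiheadSelfAttention(Module):
    """Multihead self-attention with optional key-padding mask.

    Per-head projections map ``model_dim -> head_dim``; the concatenated
    ``n_heads * head_dim`` output is projected back to ``model_dim`` before
    the residual add (head_dim need not tile model_dim).
    """

    def __init__(self, model_dim: int, n_heads: int, head_dim: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.head_dim = head_dim
        inner = n_heads * head_dim
        self.Wq = Tensor(_glorot(rng, model_dim, inner, (model_dim, inner)), requires_grad=True)
        self.Wk = Tensor(_glorot(rng, model_dim, inner, (model_dim, inner)), requires_grad=True)
        self.Wv = Tensor(_glorot(rng, model_dim, inner, (model_dim, inner)), requires_grad=True)
        self.Wo = Tensor(_glorot(rng, inner, model_dim, (inner, model_dim)), requires_grad=True)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """x: (B, T, D); mask: (B, T) boolean, True = real token."""
        B, T, _ = x.shape
        H, dh = self.n_heads, self.head_dim

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).swapaxes(1, 2)  # (B, H, T, dh)

        q = split_heads(x @ self.Wq)
        k = split_heads(x @ self.Wk)
        v = split_heads(x @ self.Wv)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))  # (B, H, T, T)
        # padded keys get -inf-like additive bias so they draw zero attention
        bias = np.where(mask[:, None, None, :], 0.0, -1e9)
        attn = softmax(scores + Tensor(bias), axis=-1)
        ctx = attn @ v  # (B, H, T, dh)
        ctx = ctx.swapaxes(1, 2).reshape(B, T, H * dh)
        out = ctx @ self.Wo
        # fully padded rows produce uniform attention over -1e9 biases; zero them
        return out * Tensor(mask[:, :, None].astype(np.float64))


class PositionwiseFFN(Module):
    def __init__(self, model_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(model_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, model_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


class LSTM(Module):
    """Single-layer LSTM returning the full hidden-state sequence (B, T, H)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.Wx = Tensor(_glorot(rng, d_in, 4 * d_hidden, (d_in, 4 * d_hidden)), requires_grad=True)
        self.Wh = Tensor(
            _glorot(rng, d_hidden, 4 * d_hidden, (d_hidden, 4 * d_hidden)), requires_grad=True
        )
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.d_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        # one fused input projection for all timesteps
        xz = x @ self.Wx  # (B, T, 4H)
        outs: list[Tensor] = []
        for t in range(T):
            z = xz[:, t, :] + h @ self.Wh + self.b
            i = sigmoid(z[:, 0:H])
            f = sigmoid(z[:, H : 2 * H])
            g = tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * tanh(c)
            outs.append(h)
        return stack(outs, axis=1)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
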