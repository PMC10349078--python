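"""Neural-network building blocks for the interaction model.

Shapes follow the (batch, length, channels) convention throughout. Padding
is handled with additive key masks: masked keys receive a -1e30 score, so
after the softmax their attention weight underflows to exactly zero.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, relu, softmax

_NEG_INF = -1e30


class Module:
    """Base class: tracks parameters of attributes recursively."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            for m in _collect_modules(value):
                mods.append(m)
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
        for v in vars(value).values():
            yield from _collect_modules(v)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self._rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.o_proj = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 key_mask: np.ndarray | None = None) -> Tensor:
        """key_mask: (B, Lk) boolean, True where the key position is valid."""
        B, Lq, _ = query.shape
        Lk = key.shape[1]
        q = self._split(self.q_proj(query), B, Lq)
        k = self._split(self.k_proj(key), B, Lk)
        v = self._split(self.v_proj(value), B, Lk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        if key_mask is not None:
            add = np.where(key_mask[:, None, None, :], 0.0, _NEG_INF)
            scores = scores + Tensor(add)
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        ctx = attn @ v
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, Lq, self.n_heads * self.d_head)
        return self.o_proj(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


class EncoderLayer(Module):
    """Post-norm transformer encoder layer (self-attention + FFN)."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x, x, x, mask)))
        x = self.norm2(x + self.drop2(self.ffn(x)))
        return x


class DecoderLayer(Module):
    """Transformer decoder layer without causal masking.

    The query sequence self-attends (over valid queries), cross-attends to
    the encoder memory, then passes through the position-wise FFN.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.norm3 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.drop3 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, memory: Tensor,
                 self_mask: np.ndarray | None,
                 memory_mask: np.ndarray | None) -> Tensor:
        x = self.norm1(x + self.drop1(self.self_attn(x, x, x, self_mask)))
        x = self.norm2(x + self.drop2(self.cross_attn(x, memory, memory, memory_mask)))
        x = self.norm3(x + self.drop3(self.ffn(x)))
        return x


class GraphConvLayer(Module):
    """One graph-convolution layer: H' = act(N H W + b).

    ``N`` is the symmetrically normalized self-looped adjacency
    D^{-1/2} A D^{-1/2}, supplied per batch as a constant.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.linear = Linear(d_in, d_out, rng)

    def __call__(self, x: Tensor, norm_adj: np.ndarray) -> Tensor:
        return relu(Tensor(norm_adj) @ self.linear(x))


def normalize_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} A D^{-1/2} of a self-looped adjacency.

    Rows with zero degree (padding) are left as zero.
    """
    deg = adj.sum(axis=-1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, deg**-0.5, 0.0)
    return adj * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]
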