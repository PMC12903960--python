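"""Minimal NumPy neural-network core: reverse-mode autodiff, layers, Adam.

Provides exactly the primitives the ddG regressor needs — broadcasted
arithmetic, batched matmul, ReLU, softmax, layer normalization, dropout,
row selection and concatenation — each with a hand-derived backward pass
checked against finite differences in the test suite.  No external deep
learning framework is involved; everything runs on float64 ndarrays.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ShapeError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- primitives ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = back
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = back
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def back(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.data.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.data.shape)

        out._backward = back
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        out._backward = back
        return out

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=-1, keepdims=True)
                self.grad += y * (g - dot)

        out._backward = back
        return out

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * 0.5 / y

        out._backward = back
        return out

    def square(self) -> "Tensor":
        return self * self

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self.grad += np.full_like(self.data, float(g) / self.data.size)

        out._backward = back
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = back
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        out._backward = back
        return out

    def select_row(self, index: int) -> "Tensor":
        """Select one row along axis -2 (e.g. the mutation-site row)."""
        out = Tensor(self.data[..., index, :], self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                scatter = np.zeros_like(self.data)
                scatter[..., index, :] = g
                self.grad += scatter

        out._backward = back
        return out

    def dropout(self, rate: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when rate is 0 or rng is None (eval)."""
        if rate <= 0.0 or rng is None:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * Tensor(mask)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_last(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the last axis."""
    data = np.concatenate([t.data for t in tensors], axis=-1)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[-1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t.grad += g[..., a:b]

    out._backward = back
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(
        gamma.data * xhat + beta.data,
        x.requires_grad or gamma.requires_grad or beta.requires_grad,
        parents=(x, gamma, beta),
    )
    def back(g):
        if gamma.requires_grad:
            gamma.grad += _unbroadcast(g * xhat, gamma.data.shape)
        if beta.requires_grad:
            beta.grad += _unbroadcast(g, beta.data.shape)
        if x.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x.grad += inv * (gx - m1 - xhat * m2)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# parameters and layers


class Parameter(Tensor):
    """A trainable tensor with a name (for checkpoints)."""

    __slots__ = ("name",)

    def __init__(self, data, name: str):
        super().__init__(data, requires_grad=True)
        self.name = name


class Module:
    """Base class: collects parameters recursively by attribute walk."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        out.extend(v.parameters())
                    elif isinstance(v, Parameter):
                        out.append(v)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise ShapeError(f"missing parameter {p.name!r} in state")
            if state[p.name].shape != p.data.shape:
                raise ShapeError(
                    f"parameter {p.name!r}: shape {state[p.name].shape} "
                    f"vs expected {p.data.shape}"
                )
            p.data = state[p.name].astype(np.float64).copy()


class Linear(Module):
    """Affine layer y = xW + b with He-style fan-in initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str):
        scale = np.sqrt(2.0 / d_in)
        self.W = Parameter(rng.standard_normal((d_in, d_out)) * scale, f"{name}.W")
        self.b = Parameter(np.zeros(d_out), f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.W) + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, name: str):
        self.gamma = Parameter(np.ones(dim), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with h heads over (B, L, d)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, name: str):
        if dim % heads:
            raise ShapeError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.d_head = dim, heads, dim // heads
        self.wq = Linear(dim, dim, rng, f"{name}.wq")
        self.wk = Linear(dim, dim, rng, f"{name}.wk")
        self.wv = Linear(dim, dim, rng, f"{name}.wv")
        self.wo = Linear(dim, dim, rng, f"{name}.wo")

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape

        def split(t: Tensor) -> Tensor:  # (B, L, d) -> (B, h, L, d_head)
            return t.reshape(B, L, self.heads, self.d_head).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q.matmul(k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax()
        ctx = attn.matmul(v)  # (B, h, L, d_head)
        merged = ctx.transpose((0, 2, 1, 3)).reshape(B, L, self.dim)
        return self.wo(merged)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: attention and feedforward sublayers, each
    wrapped in dropout, residual connection and layer normalization."""

    def __init__(self, dim: int, heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator, name: str):
        self.attn = MultiHeadSelfAttention(dim, heads, rng, f"{name}.attn")
        self.ff1 = Linear(dim, d_ff, rng, f"{name}.ff1")
        self.ff2 = Linear(d_ff, dim, rng, f"{name}.ff2")
        self.ln1 = LayerNorm(dim, f"{name}.ln1")
        self.ln2 = LayerNorm(dim, f"{name}.ln2")
        self.rate = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        a = self.attn(x).dropout(self.rate, rng)
        x = self.ln1(x + a)
        f = self.ff2(self.ff1(x).relu()).dropout(self.rate, rng)
        return self.ln2(x + f)


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
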