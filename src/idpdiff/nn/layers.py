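"""Transformer building blocks on top of the autodiff tensors.

Includes the two conditioning mechanisms used by the models in this
package: additive per-pair attention biases (used by the structural
autoencoder to inject the distance matrix) and adaLN-Zero modulation
(used by the diffusion noise-prediction network to inject timestep and
sequence embeddings), with residual gates initialized to zero so that a
freshly initialized conditioned block is the identity map.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, fused_gelu, fused_layer_norm, fused_softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MLP",
    "SelfAttention",
    "TransformerBlock",
    "AdaLNBlock",
    "sinusoidal_embedding",
    "softmax",
    "gelu",
]


softmax = fused_softmax
gelu = fused_gelu


def sinusoidal_embedding(positions: np.ndarray, dim: int, base: float = 10000.0) -> np.ndarray:
    """Standard transformer sine/cosine embedding of integer positions."""
    positions = np.asarray(positions, dtype=np.float64)
    half = dim // 2
    freqs = np.exp(-np.log(base) * np.arange(half) / max(half - 1, 1))
    args = positions[..., None] * freqs
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=-1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros(emb.shape[:-1] + (1,))], axis=-1)
    return emb.astype(np.float32)


class Module:
    """Tiny parameter-container base: recursive discovery over attributes."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        zero_init: bool = False,
        scale: float | None = None,
    ):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            std = scale if scale is not None else (1.0 / np.sqrt(d_in))
            w = std * rng.standard_normal((d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, affine: bool = True, eps: float = 1e-5):
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Tensor(np.ones(dim), requires_grad=True)
            self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        normed = fused_layer_norm(x, self.eps)
        if self.affine:
            return normed * self.gamma + self.beta
        return normed


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class SelfAttention(Module):
    """Multi-head self-attention with an optional additive logit bias.

    ``bias`` has shape (B, H, L, L) or is broadcastable to it; it is added
    to the attention logits before the softmax, which is how pairwise
    (distance) features enter an otherwise per-residue transformer.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.d_head = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, bias: Tensor | None = None) -> Tensor:
        B, L, D = x.shape
        qkv = self.qkv(x).reshape(B, L, 3, self.heads, self.d_head)
        qkv = qkv.swapaxes(1, 3)  # B, heads, 3, L, d_head
        q = qkv[:, :, 0]
        k = qkv[:, :, 1]
        v = qkv[:, :, 2]
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        if bias is not None:
            logits = logits + bias
        att = softmax(logits, axis=-1)
        out = (att @ v).swapaxes(1, 2).reshape(B, L, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-LN transformer block with optional attention bias."""

    def __init__(self, dim: int, heads: int, mlp_mult: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_mult * dim, rng)

    def __call__(self, x: Tensor, bias: Tensor | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), bias=bias)
        return x + self.mlp(self.ln2(x))


class AdaLNBlock(Module):
    """Transformer block conditioned through adaLN-Zero modulation.

    The per-token condition embedding produces layer-norm scales/shifts and
    residual gates via a zero-initialized linear map, so at initialization
    the block is exactly the identity.  Optionally the (perturbed) input of
    the whole network is re-injected at the block entrance through a
    concatenation + linear map initialized to pass-through.
    """

    def __init__(
        self,
        dim: int,
        heads: int,
        mlp_mult: int,
        cond_dim: int,
        rng: np.random.Generator,
        inject_dim: int | None = None,
    ):
        self.ln1 = LayerNorm(dim, affine=False)
        self.attn = SelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim, affine=False)
        self.mlp = MLP(dim, mlp_mult * dim, rng)
        self.mod = Linear(cond_dim, 6 * dim, rng, zero_init=True)
        self.inject: Linear | None = None
        if inject_dim is not None:
            self.inject = Linear(dim + inject_dim, dim, rng, zero_init=True)
            # pass-through init: identity on the hidden stream, zero on the
            # injected channels, so the zero-output property at init holds
            w = self.inject.weight.data
            w[:dim, :] = np.eye(dim, dtype=np.float32)
            self.dim = dim

    def __call__(self, x: Tensor, cond: Tensor, inject: Tensor | None = None) -> Tensor:
        if self.inject is not None:
            if inject is None:
                raise ValueError("block built with input injection; none given")
            x = self.inject(concatenate([x, inject], axis=-1))
        m = self.mod(cond)
        D = x.shape[-1]
        s1, b1, g1 = m[..., 0:D], m[..., D : 2 * D], m[..., 2 * D : 3 * D]
        s2, b2, g2 = m[..., 3 * D : 4 * D], m[..., 4 * D : 5 * D], m[..., 5 * D :]
        x = x + g1 * self.attn(self.ln1(x) * (1.0 + s1) + b1)
        return x + g2 * self.mlp(self.ln2(x) * (1.0 + s2) + b2)
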