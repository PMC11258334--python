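"""Graph readouts: standard pooling and the Set Transformer adaptive readout.

A readout aggregates per-node embeddings into a single molecule-level vector.
Standard readouts (sum / mean / max) are fixed, parameter-free column-wise
reductions.  The adaptive readout is a Set Transformer: an encoder chain of
multi-head attention blocks (MAB), pooling by multi-head attention (PMA) with
a learnable seed vector, an optional decoder chain of MABs, and a final
linear projection whose output is averaged over head-specific slices:

    ST(H)   = (1/K) Σ_k [Decoder(Encoder(H))]_k
    Encoder = MAB^n(H, H)
    Decoder = FF(MAB^m(PMA(Z), PMA(Z)))
    PMA(Z)  = MAB(s, FF(Z))
    MAB(X,Y)= A + FF(A),   A = X + MultiHead(X, Y, Y)

There are no positional encodings and no dropout; padding rows are zeros and
are NOT masked inside attention by default (an optional mask flag exists).
The graph-embedding width ``out_dim`` is decoupled from the node width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, glorot
from .molgraph import ConfigurationError


class DegenerateInputError(ValueError):
    """Empty node matrix passed to a readout."""


class PaddingContractError(ValueError):
    """Set Transformer input does not have exactly M rows."""


@dataclass
class ReadoutConfig:
    kind: str = "set_transformer"          # sum | mean | max | set_transformer
    K: int = 4                             # attention heads
    n: int = 1                             # encoder MAB blocks
    m: int = 1                             # decoder MAB blocks
    hidden_dim: int = 64                   # attention/FF width
    out_dim: int = 64                      # graph-embedding width
    M: int = 32                            # max nodes (padding capacity)
    mask_padding: bool = False

    def __post_init__(self):
        if self.kind not in ("sum", "mean", "max", "set_transformer"):
            raise ConfigurationError(f"unknown readout kind {self.kind!r}")
        if self.kind == "set_transformer":
            if self.K < 1 or self.n < 1 or self.m < 0 or self.out_dim < 1:
                raise ConfigurationError("invalid Set Transformer configuration")
            if self.hidden_dim % self.K != 0:
                raise ConfigurationError("hidden_dim must be divisible by K")

    @property
    def embedding_dim(self) -> int:
        """Width of the graph-level vector this readout emits (given node width D)."""
        return self.out_dim if self.kind == "set_transformer" else -1  # -1: D of input

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("kind", "K", "n", "m", "hidden_dim", "out_dim", "M", "mask_padding")}

    @classmethod
    def from_dict(cls, d: dict) -> "ReadoutConfig":
        return cls(**d)


# --------------------------------------------------------------------------- #
# Standard readouts
# --------------------------------------------------------------------------- #

def standard_readout(h, kind: str):
    """Column-wise sum / mean / max over node rows; permutation invariant.

    Accepts a 2D numpy array (returns numpy) or a 2D autodiff Tensor
    (returns a Tensor so gradients flow during training).
    """
    if kind not in ("sum", "mean", "max"):
        raise ConfigurationError(f"unknown standard readout {kind!r}")
    is_tensor = isinstance(h, Tensor)
    n = h.shape[0] if h.ndim == 2 else 0
    if h.ndim != 2 or n == 0:
        raise DegenerateInputError("readout requires a non-empty 2D node matrix")
    if is_tensor:
        return {"sum": h.sum, "mean": h.mean, "max": h.max}[kind](axis=0)
    h = np.asarray(h, dtype=float)
    return {"sum": h.sum, "mean": h.mean, "max": h.max}[kind](axis=0)


# --------------------------------------------------------------------------- #
# Set Transformer parameters
# --------------------------------------------------------------------------- #

def _ff_params(rng, width: int) -> dict:
    """Two-layer feed-forward block with a smooth (tanh) nonlinearity."""
    return {"w1": glorot(rng, width, width), "b1": Tensor(np.zeros(width), True),
            "w2": glorot(rng, width, width), "b2": Tensor(np.zeros(width), True)}


def _mab_params(rng, width: int) -> dict:
    return {"wq": glorot(rng, width, width), "wk": glorot(rng, width, width),
            "wv": glorot(rng, width, width), "wo": glorot(rng, width, width),
            "ff": _ff_params(rng, width)}


@dataclass
class SetTransformerParams:
    """Learnable weights of the Set Transformer readout."""

    input_proj: Tensor                     # D_node -> hidden_dim
    encoder: list                          # n MAB blocks
    pma_ff: dict                           # FF applied to Z inside PMA
    seed: Tensor                           # 1 × hidden_dim learnable seed s
    pma: dict                              # the PMA's MAB
    decoder: list                          # m MAB blocks
    out_proj: Tensor                       # hidden_dim -> K * out_dim (final FF)
    out_bias: Tensor = None
    d_node: int = 0

    def parameters(self) -> list:
        ps = [self.input_proj, self.seed, self.out_proj, self.out_bias]

        def add(block):
            for k, v in block.items():
                if isinstance(v, dict):
                    add(v)
                else:
                    ps.append(v)
        for b in self.encoder:
            add(b)
        add(self.pma_ff)
        add(self.pma)
        for b in self.decoder:
            add(b)
        return ps


def init_set_transformer(rng: np.random.Generator, d_node: int,
                         config: ReadoutConfig) -> SetTransformerParams:
    h = config.hidden_dim
    return SetTransformerParams(
        input_proj=glorot(rng, d_node, h),
        encoder=[_mab_params(rng, h) for _ in range(config.n)],
        pma_ff=_ff_params(rng, h),
        seed=Tensor(rng.normal(0.0, 1.0, size=(1, h)), True),
        pma=_mab_params(rng, h),
        decoder=[_mab_params(rng, h) for _ in range(config.m)],
        out_proj=glorot(rng, h, config.K * config.out_dim),
        out_bias=Tensor(np.zeros(config.K * config.out_dim), True),
        d_node=d_node,
    )


# --------------------------------------------------------------------------- #
# Attention blocks
# --------------------------------------------------------------------------- #

def _as3d(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    return t.reshape(1, *t.shape) if t.ndim == 2 else t


def _ff(x: Tensor, p: dict) -> Tensor:
    return (x @ p["w1"] + p["b1"]).tanh() @ p["w2"] + p["b2"]


def _split_heads(x: Tensor, k: int) -> Tensor:
    b, n, h = x.shape
    return x.reshape(b, n, k, h // k).swapaxes(1, 2)   # (B, K, N, dh)


def _merge_heads(x: Tensor) -> Tensor:
    b, k, n, dh = x.shape
    return x.swapaxes(1, 2).reshape(b, n, k * dh)


def multihead_attention_block(x, y, params: dict, k_heads: int,
                              key_mask: np.ndarray | None = None) -> Tensor:
    """MAB(X, Y) = A + FF(A) with A = X + MultiHead(X, Y, Y).

    ``x`` and ``y`` are (B × N × hidden) (a leading batch axis is added for 2D
    inputs); ``key_mask`` (B × Ny), if given, excludes padding rows of Y from
    the softmax.  Invariant to permutations of Y's rows; equivariant in X's.
    """
    x3, y3 = _as3d(x), _as3d(y)
    if x3.shape[-1] != y3.shape[-1]:
        raise ConfigurationError("MAB: X and Y widths differ")
    if x3.shape[-1] != params["wq"].shape[0]:
        raise ConfigurationError("MAB: input width does not match parameters")
    q = _split_heads(x3 @ params["wq"], k_heads)
    k = _split_heads(y3 @ params["wk"], k_heads)
    v = _split_heads(y3 @ params["wv"], k_heads)
    dh = q.shape[-1]
    scores = (q @ k.T) * (1.0 / np.sqrt(dh))            # (B, K, Nx, Ny)
    if key_mask is not None:
        bias = np.where(np.asarray(key_mask, bool), 0.0, -1e9)
        scores = scores + Tensor(bias[:, None, None, :])
    attn = scores.softmax(axis=-1)
    heads = _merge_heads(attn @ v)
    a = x3 + heads @ params["wo"]
    out = a + _ff(a, params["ff"])
    return out if (isinstance(x, Tensor) and x.ndim == 3) or \
        (not isinstance(x, Tensor) and np.asarray(x).ndim == 3) else out[0]


def pooling_by_multihead_attention(z, params: SetTransformerParams, k_heads: int,
                                   key_mask: np.ndarray | None = None) -> Tensor:
    """PMA(Z) = MAB(s, FF(Z)); one seed row ⇒ one pooled row per graph."""
    if params.seed is None:
        raise ValueError("PMA seed vector is uninitialized")
    z3 = _as3d(z)
    # the single learnable seed broadcasts across the batch inside attention
    s = params.seed.reshape(1, 1, -1)
    out = multihead_attention_block(s, _ff(z3, params.pma_ff), params.pma,
                                    k_heads, key_mask=key_mask)
    return out if (isinstance(z, Tensor) and z.ndim == 3) or \
        (not isinstance(z, Tensor) and np.asarray(z).ndim == 3) else out[0]


def set_transformer_forward(h: Tensor, params: SetTransformerParams,
                            config: ReadoutConfig,
                            key_mask: np.ndarray | None = None) -> Tensor:
    """Batched ST over (B × M × D_node) padded node matrices -> (B × out_dim)."""
    if h.shape[-1] != params.input_proj.shape[0]:
        raise ConfigurationError("node width does not match Set Transformer input")
    mask = key_mask if config.mask_padding else None
    z = h @ params.input_proj
    for blk in params.encoder:
        z = multihead_attention_block(z, z, blk, config.K, key_mask=mask)
    pooled = pooling_by_multihead_attention(z, params, config.K, key_mask=mask)
    for blk in params.decoder:
        pooled = multihead_attention_block(pooled, pooled, blk, config.K)
    proj = pooled @ params.out_proj + params.out_bias    # (B, 1, K*out_dim)
    b = proj.shape[0]
    slices = proj.reshape(b, config.K, config.out_dim)   # head-specific slices
    return slices.mean(axis=1)                           # (B, out_dim)


def set_transformer_readout(h, params: SetTransformerParams,
                            config: ReadoutConfig) -> np.ndarray:
    """Single-graph adaptive readout on an M-row zero-padded node matrix.

    Returns the out_dim graph embedding as a numpy vector (inference path);
    training uses :func:`set_transformer_forward` directly.
    """
    arr = h.data if isinstance(h, Tensor) else np.asarray(h, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != config.M:
        raise PaddingContractError(
            f"expected a padded {config.M}-row matrix, got shape {arr.shape}")
    mask = (np.abs(arr).sum(axis=1) > 0)[None, :]
    out = set_transformer_forward(Tensor(arr[None]), params, config,
                                  key_mask=mask)
    return out.data[0]
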