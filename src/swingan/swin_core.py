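"""Shifted-window attention building blocks.

Implements window partitioning, windowed multi-head self-attention with a
learnable relative-position bias, the Swin transformer layer (STL:
pre-norm attention + pre-norm GELU MLP, each with a residual connection),
and the residual Swin transformer block (RSTB: a stack of STLs followed by a
3x3 convolution, added to the block input).

Feature maps are ``(batch, channel, row, col)``; token windows are
``(window, token, channel)`` with ``m**2`` tokens per ``m x m`` window in
raster order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import autograd.numpy as anp
import numpy as np

from ._ops import (
    conv2d,
    cyclic_shift,
    fused_window_attention,
    gelu,
    layer_norm,
    reflect_pad2d,
    softmax,
    trunc_normal,
)

__all__ = [
    "SwinConfig",
    "RelPosBias",
    "window_partition",
    "window_reverse",
    "relative_position_index",
    "attention_mask",
    "window_attention",
    "swin_layer_forward",
    "rstb_forward",
    "init_stl_params",
    "init_rstb_params",
]

MASK_VALUE = -1e9


class InvalidConfigError(ValueError):
    """Raised when a window/attention configuration is inconsistent."""


class DimensionMismatchError(ValueError):
    """Raised when array shapes disagree with the declared geometry."""


@dataclass(frozen=True)
class SwinConfig:
    """Configuration of one windowed-attention layer."""

    window_size: int = 8
    embed_dim: int = 60
    num_heads: int = 6
    shift: int = 0
    mlp_ratio: float = 2.0

    def __post_init__(self):
        if self.window_size < 2:
            raise InvalidConfigError(f"window_size must be >= 2, got {self.window_size}")
        if self.embed_dim <= 0 or self.num_heads <= 0:
            raise InvalidConfigError("embed_dim and num_heads must be positive")
        if self.embed_dim % self.num_heads:
            raise InvalidConfigError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}"
            )
        if not 0 <= self.shift < self.window_size:
            raise InvalidConfigError(
                f"shift must satisfy 0 <= s < window_size, got {self.shift}"
            )
        if self.mlp_ratio <= 0:
            raise InvalidConfigError("mlp_ratio must be positive")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads


@dataclass
class RelPosBias:
    """Learnable per-head bias over all (2m-1)^2 relative token offsets."""

    table: np.ndarray  # ((2m-1)^2, heads)
    index: np.ndarray  # (m^2, m^2) int lookup, depends only on m

    @classmethod
    def create(cls, rng: np.random.Generator, m: int, num_heads: int,
               dtype=np.float32) -> "RelPosBias":
        table = trunc_normal(rng, ((2 * m - 1) ** 2, num_heads), dtype=dtype)
        return cls(table=table, index=relative_position_index(m))


# ---------------------------------------------------------------------------
# window geometry
# ---------------------------------------------------------------------------


def window_partition(fmap, m: int):
    """(B, C, H, W) -> (B * nW, m*m, C) non-overlapping windows, raster order."""
    b, c, h, w = fmap.shape
    if m <= 0 or m > min(h, w):
        raise InvalidConfigError(f"window size {m} invalid for {h}x{w} map")
    if h % m or w % m:
        raise DimensionMismatchError(f"{h}x{w} not a multiple of window size {m}")
    x = anp.transpose(fmap, (0, 2, 3, 1))                       # B, H, W, C
    x = anp.reshape(x, (b, h // m, m, w // m, m, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))                    # B, nh, nw, m, m, C
    return anp.reshape(x, (b * (h // m) * (w // m), m * m, c))


def window_reverse(windows, m: int, h: int, w: int):
    """Exact inverse of :func:`window_partition` -> (B, C, H, W)."""
    n_win, tokens, c = windows.shape
    if tokens != m * m:
        raise DimensionMismatchError(f"{tokens} tokens inconsistent with m={m}")
    per_image = (h // m) * (w // m)
    if h % m or w % m or n_win % per_image:
        raise DimensionMismatchError(
            f"{n_win} windows inconsistent with {h}x{w}, m={m}"
        )
    b = n_win // per_image
    x = anp.reshape(windows, (b, h // m, w // m, m, m, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))                    # B, nh, m, nw, m, C
    x = anp.reshape(x, (b, h, w, c))
    return anp.transpose(x, (0, 3, 1, 2))


_INDEX_CACHE: dict[int, np.ndarray] = {}


def relative_position_index(m: int) -> np.ndarray:
    """(m^2, m^2) lookup into the (2m-1)^2 bias table; depends only on m."""
    if m not in _INDEX_CACHE:
        coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))
        flat = coords.reshape(2, -1)                            # (2, m^2)
        rel = flat[:, :, None] - flat[:, None, :]               # (2, m^2, m^2)
        rel = rel + (m - 1)                                     # shift to >= 0
        _INDEX_CACHE[m] = rel[0] * (2 * m - 1) + rel[1]
    return _INDEX_CACHE[m]


_MASK_CACHE: dict[tuple, np.ndarray | None] = {}


def attention_mask(h: int, w: int, m: int, s: int, dtype=np.float64):
    """Additive mask (nW, m^2, m^2) for cyclically shifted windows.

    Tokens wrapped in from the opposite border must not attend across the
    original image boundary; those pairs get ``MASK_VALUE``.  Returns ``None``
    for an unshifted layer.
    """
    if s == 0:
        return None
    key = (h, w, m, s, np.dtype(dtype).str)
    if key not in _MASK_CACHE:
        # region ids are laid out in the post-shift frame: the last m-band
        # mixes wrapped (last s rows/cols) and non-wrapped content
        region = np.zeros((h, w), dtype=np.int64)
        rid = 0
        for rs in (slice(0, -m), slice(-m, -s), slice(-s, None)):
            for cs in (slice(0, -m), slice(-m, -s), slice(-s, None)):
                region[rs, cs] = rid
                rid += 1
        wins = window_partition(region[None, None].astype(np.float64), m)
        wins = wins[:, :, 0].astype(np.int64)                   # (nW, m^2)
        diff = wins[:, :, None] != wins[:, None, :]
        _MASK_CACHE[key] = np.where(diff, MASK_VALUE, 0.0).astype(dtype)
    return _MASK_CACHE[key]


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def window_attention(windows, qkv_weights, bias: RelPosBias, mask=None,
                     return_weights=False):
    """Multi-head self-attention within each window.

    Per head: ``softmax(Q K^T / sqrt(d) + B + mask) V`` with ``d`` the head
    dimension; heads are concatenated and linearly projected.

    Parameters
    ----------
    windows : (nW_total, m^2, C)
    qkv_weights : dict with ``qkv_w (C, 3C)``, ``qkv_b (3C,)``,
        ``proj_w (C, C)``, ``proj_b (C,)``
    bias : :class:`RelPosBias`; the number of heads is ``bias.table.shape[1]``
    mask : optional (nW_per_image, m^2, m^2) additive mask
    """
    n_win, t, c = windows.shape
    heads = bias.table.shape[1]
    if c % heads:
        raise InvalidConfigError(f"channels {c} not divisible by heads {heads}")

    if not return_weights:
        return fused_window_attention(
            windows, qkv_weights["qkv_w"], qkv_weights["qkv_b"],
            qkv_weights["proj_w"], qkv_weights["proj_b"],
            bias.table, bias.index, heads, mask,
        )

    # slow path (visualization only): also return the softmax weights
    d = c // heads
    qkv = anp.matmul(windows, qkv_weights["qkv_w"]) + qkv_weights["qkv_b"]
    qkv = anp.reshape(qkv, (n_win, t, 3, heads, d))
    qkv = anp.transpose(qkv, (2, 0, 3, 1, 4))                   # 3, nW, h, t, d
    q, k, v = qkv[0], qkv[1], qkv[2]

    # python-float scale keeps float32 activations float32
    attn = anp.matmul(q, anp.swapaxes(k, -2, -1)) * (1.0 / float(np.sqrt(d)))
    b_term = anp.transpose(bias.table[bias.index.reshape(-1)], (1, 0))
    attn = attn + anp.reshape(b_term, (heads, t, t))[None]
    if mask is not None:
        nw = mask.shape[0]
        attn = anp.reshape(attn, (n_win // nw, nw, heads, t, t))
        attn = attn + mask[None, :, None]
        attn = anp.reshape(attn, (n_win, heads, t, t))
    weights = softmax(attn)
    if not np.all(np.isfinite(np.asarray(getattr(weights, "_value", weights)))):
        raise FloatingPointError("non-finite attention weights")

    out = anp.matmul(weights, v)                                # nW, h, t, d
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (n_win, t, c))
    out = anp.matmul(out, qkv_weights["proj_w"]) + qkv_weights["proj_b"]
    return out, weights


# ---------------------------------------------------------------------------
# Swin transformer layer / residual block
# ---------------------------------------------------------------------------


def init_stl_params(rng: np.random.Generator, cfg: SwinConfig, dtype=np.float32):
    c = cfg.embed_dim
    hid = int(round(cfg.mlp_ratio * c))
    return {
        "ln1_g": np.ones(c, dtype=dtype),
        "ln1_b": np.zeros(c, dtype=dtype),
        "attn": {
            "qkv_w": trunc_normal(rng, (c, 3 * c), dtype=dtype),
            "qkv_b": np.zeros(3 * c, dtype=dtype),
            "proj_w": trunc_normal(rng, (c, c), dtype=dtype),
            "proj_b": np.zeros(c, dtype=dtype),
        },
        "bias_table": trunc_normal(rng, ((2 * cfg.window_size - 1) ** 2,
                                         cfg.num_heads), dtype=dtype),
        "ln2_g": np.ones(c, dtype=dtype),
        "ln2_b": np.zeros(c, dtype=dtype),
        "fc1_w": trunc_normal(rng, (c, hid), dtype=dtype),
        "fc1_b": np.zeros(hid, dtype=dtype),
        "fc2_w": trunc_normal(rng, (hid, c), dtype=dtype),
        "fc2_b": np.zeros(c, dtype=dtype),
    }


def _pad_to_multiple(fmap, m):
    h, w = fmap.shape[2], fmap.shape[3]
    pb = (-h) % m
    pr = (-w) % m
    if pb or pr:
        fmap = reflect_pad2d(fmap, pb, pr)
    return fmap, h, w


def swin_layer_forward(fmap, cfg: SwinConfig, params, capture=None):
    """One STL: LN -> (shifted) window attention -> +res -> LN -> MLP -> +res.

    ``capture``, if a list, receives the raw attention-weight array — used by
    the generator's attention-map extraction.
    """
    m, s = cfg.window_size, cfg.shift
    fmap, h0, w0 = _pad_to_multiple(fmap, m)
    b, c, h, w = fmap.shape
    if min(h, w) < m:
        raise InvalidConfigError(f"{h}x{w} map smaller than window {m}")

    tokens = anp.transpose(fmap, (0, 2, 3, 1))                  # B, H, W, C
    x = layer_norm(tokens, params["ln1_g"], params["ln1_b"])
    x = anp.transpose(x, (0, 3, 1, 2))
    if s:
        x = cyclic_shift(x, -s, -s)
    wins = window_partition(x, m)
    bias = RelPosBias(table=params["bias_table"], index=relative_position_index(m))
    # float32 mask: 0 / -1e9 are exact, and it never upcasts float32 activations
    mask = attention_mask(h, w, m, s, dtype=np.float32)
    att = window_attention(wins, params["attn"], bias, mask=mask,
                           return_weights=capture is not None)
    if capture is not None:
        att, wts = att
        capture.append((np.asarray(getattr(wts, "_value", wts)), (b, h, w, m, s)))
    x = window_reverse(att, m, h, w)
    if s:
        x = cyclic_shift(x, s, s)
    tokens = tokens + anp.transpose(x, (0, 2, 3, 1))

    y = layer_norm(tokens, params["ln2_g"], params["ln2_b"])
    y = gelu(anp.matmul(y, params["fc1_w"]) + params["fc1_b"])
    y = anp.matmul(y, params["fc2_w"]) + params["fc2_b"]
    tokens = tokens + y

    out = anp.transpose(tokens, (0, 3, 1, 2))
    if (h, w) != (h0, w0):
        out = out[:, :, :h0, :w0]
    return out


def stl_stack_configs(base: SwinConfig, n_stl: int) -> list[SwinConfig]:
    """Alternate unshifted / shifted-by-m//2 layers, starting unshifted."""
    return [replace(base, shift=0 if i % 2 == 0 else base.window_size // 2)
            for i in range(n_stl)]


def init_rstb_params(rng: np.random.Generator, cfg: SwinConfig, n_stl: int,
                     dtype=np.float32):
    c = cfg.embed_dim
    conv_w = (rng.standard_normal((c, c, 3, 3)) * np.sqrt(2.0 / (9 * c))).astype(dtype)
    return {
        "stls": [init_stl_params(rng, cfg, dtype=dtype) for _ in range(n_stl)],
        "conv_w": conv_w,
        "conv_b": np.zeros(c, dtype=dtype),
    }


def rstb_forward(fmap, cfg: SwinConfig, params, capture=None):
    """Residual block: Conv3x3(STL_n(...STL_1(x))) + x."""
    x = fmap
    for stl_cfg, stl_params in zip(stl_stack_configs(cfg, len(params["stls"])),
                                   params["stls"]):
        x = swin_layer_forward(x, stl_cfg, stl_params, capture=capture)
    x = conv2d(x, params["conv_w"], 1, 1) + anp.reshape(params["conv_b"], (1, -1, 1, 1))
    return x + fmap
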