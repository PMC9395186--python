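"""Swin-transformer generator for same-resolution modality translation.

Pipeline: shallow 3x3 conv embedding -> stack of residual Swin blocks ->
post-body 3x3 conv -> long skip from the shallow features -> recovery head
(3x3 conv to one channel, or an equivalent factor-1 subpixel head) ->
sigmoid, so outputs always lie in [0, 1].

A ``use_swin=False`` config swaps every STL for a plain 3x3 conv + GELU
block of the same width (the convolutional ablation baseline); the residual
block structure and all other plumbing are unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from ._ops import conv2d, gelu, he_normal, sigmoid
from .swin_core import (
    InvalidConfigError,
    SwinConfig,
    init_rstb_params,
    rstb_forward,
)

__all__ = [
    "GeneratorConfig",
    "init_generator_params",
    "stg_forward",
    "extract_attention_maps",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    n_rstb: int = 4
    n_stl_per_rstb: int = 6
    swin: SwinConfig = field(default_factory=SwinConfig)
    in_channels: int = 1
    out_channels: int = 1
    use_swin: bool = True
    subpixel_head: bool = False  # factor-1 pixel shuffle == plain conv

    def __post_init__(self):
        if min(self.n_rstb, self.n_stl_per_rstb,
               self.in_channels, self.out_channels) < 1:
            raise InvalidConfigError("generator config fields must be positive")


def _init_conv(rng, out_c, in_c, dtype=np.float32):
    return {
        "w": he_normal(rng, (out_c, in_c, 3, 3), fan_in=9 * in_c, dtype=dtype),
        "b": np.zeros(out_c, dtype=dtype),
    }


def _init_conv_block(rng, cfg: SwinConfig, n, dtype=np.float32):
    """Conv-only stand-in for an STL stack (ablation baseline)."""
    c = cfg.embed_dim
    return {
        "convs": [_init_conv(rng, c, c, dtype) for _ in range(n)],
        "conv_w": he_normal(rng, (c, c, 3, 3), fan_in=9 * c, dtype=dtype),
        "conv_b": np.zeros(c, dtype=dtype),
    }


def init_generator_params(rng: np.random.Generator, cfg: GeneratorConfig,
                          dtype=np.float32):
    c = cfg.swin.embed_dim
    if cfg.use_swin:
        blocks = [init_rstb_params(rng, cfg.swin, cfg.n_stl_per_rstb, dtype=dtype)
                  for _ in range(cfg.n_rstb)]
    else:
        blocks = [_init_conv_block(rng, cfg.swin, cfg.n_stl_per_rstb, dtype=dtype)
                  for _ in range(cfg.n_rstb)]
    return {
        "shallow": _init_conv(rng, c, cfg.in_channels, dtype),
        "blocks": blocks,
        "post": _init_conv(rng, c, c, dtype),
        "head": _init_conv(rng, cfg.out_channels, c, dtype),
    }


def _apply_conv(p, x, stride=1):
    return conv2d(x, p["w"], stride, 1) + anp.reshape(p["b"], (1, -1, 1, 1))


def _conv_block_forward(fmap, params):
    x = fmap
    for p in params["convs"]:
        x = gelu(_apply_conv(p, x))
    x = conv2d(x, params["conv_w"], 1, 1) + anp.reshape(params["conv_b"], (1, -1, 1, 1))
    return x + fmap


def stg_forward(x, cfg: GeneratorConfig, params, capture=None):
    """Translate a source-modality batch; output is in [0, 1], same shape.

    ``capture`` (a list) collects per-STL attention weights when given.
    """
    xv = np.asarray(getattr(x, "_value", x))
    if xv.ndim != 4:
        raise InvalidConfigError(f"expected (B, C, H, W) input, got ndim {xv.ndim}")
    if min(xv.shape[2], xv.shape[3]) < cfg.swin.window_size:
        raise InvalidConfigError(
            f"spatial size {xv.shape[2]}x{xv.shape[3]} below window size "
            f"{cfg.swin.window_size}"
        )
    if xv.min() < 0.0 or xv.max() > 1.0:
        log.warning("generator input outside [0, 1] (min=%g, max=%g); clamping",
                    xv.min(), xv.max())
        x = anp.clip(x, 0.0, 1.0)

    shallow = _apply_conv(params["shallow"], x)
    feat = shallow
    for block in params["blocks"]:
        if cfg.use_swin:
            feat = rstb_forward(feat, cfg.swin, block, capture=capture)
        else:
            feat = _conv_block_forward(feat, block)
    feat = _apply_conv(params["post"], feat)
    feat = feat + shallow  # long skip: low-frequency content bypasses the body
    logits = _apply_conv(params["head"], feat)
    if cfg.subpixel_head:
        # factor-1 subpixel shuffle is the identity rearrangement
        logits = anp.reshape(logits, logits.shape)
    return sigmoid(logits)


def extract_attention_maps(x, cfg: GeneratorConfig, params, layer_index: int):
    """Mean attention received per pixel at one STL, normalized to [0, 1].

    Attention weights are averaged over heads and query tokens within each
    window, assigned back to the key-token pixels, and min-max normalized.
    Returns (B, H, W).
    """
    if not cfg.use_swin:
        raise InvalidConfigError("attention maps require a Swin generator")
    n_layers = cfg.n_rstb * cfg.n_stl_per_rstb
    if not 0 <= layer_index < n_layers:
        raise InvalidConfigError(
            f"layer_index {layer_index} outside [0, {n_layers})"
        )
    capture: list = []
    stg_forward(x, cfg, params, capture=capture)
    weights, (b, h, w, m, s) = capture[layer_index]
    # (B*nW, heads, t, t) -> mean over heads and query tokens -> per-key score
    received = weights.mean(axis=(1, 2))                        # (B*nW, t)
    grid = received.reshape(b, h // m, w // m, m, m)
    grid = grid.transpose(0, 1, 3, 2, 4).reshape(b, h, w)
    if s:  # undo the cyclic shift applied before partitioning
        grid = np.roll(np.roll(grid, s, axis=1), s, axis=2)
    grid = grid[:, : x.shape[2], : x.shape[3]]
    # scale by the per-image max: keeps near-uniform maps near-uniform
    # (attention received is non-negative, so the result stays in [0, 1])
    return grid / grid.max(axis=(1, 2), keepdims=True)
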