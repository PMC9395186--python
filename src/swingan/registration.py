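"""Deformable registration network and warping utilities.

The registration network takes a (moving, fixed) image pair and predicts a
dense displacement field in pixel units, ``(batch, 2, H, W)`` with (row, col)
components.  Warping adds the field to the identity grid and resamples
bilinearly with border clamping, so a zero field is the exact identity.

The encoder is a stride-2 conv / LeakyReLU(0.2) pyramid, optionally
interleaved with Swin transformer layers; the decoder upsamples (nearest +
3x3 conv) with skip connections from matching encoder stages, two
full-resolution convs refine, and a zero-initialized flow head emits the
field — training therefore starts from the identity warp.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from ._ops import bilinear_warp, conv2d, he_normal, leaky_relu, upsample_nearest
from .swin_core import (
    DimensionMismatchError,
    InvalidConfigError,
    SwinConfig,
    init_stl_params,
    stl_stack_configs,
    swin_layer_forward,
)

__all__ = [
    "STRConfig",
    "init_str_params",
    "str_forward",
    "spatial_resample",
    "smoothness_loss",
    "invert_dvf",
]


@dataclass(frozen=True)
class STRConfig:
    levels: int = 4
    base_channels: int = 16
    leaky_slope: float = 0.2
    n_stl_encoder: int = 2
    window_size: int = 4
    num_heads: int = 2
    use_swin: bool = True

    def __post_init__(self):
        if self.levels < 1:
            raise InvalidConfigError("levels must be >= 1")
        if self.base_channels < 1:
            raise InvalidConfigError("base_channels must be >= 1")


def _level_channels(cfg: STRConfig) -> list[int]:
    return [cfg.base_channels * (2 ** min(i, 3)) for i in range(cfg.levels)]


def _init_conv(rng, out_c, in_c, dtype=np.float32):
    return {
        "w": he_normal(rng, (out_c, in_c, 3, 3), fan_in=9 * in_c, dtype=dtype),
        "b": np.zeros(out_c, dtype=dtype),
    }


def _swin_cfg(cfg: STRConfig, channels: int) -> SwinConfig:
    heads = cfg.num_heads if channels % cfg.num_heads == 0 else 1
    return SwinConfig(window_size=cfg.window_size, embed_dim=channels,
                      num_heads=heads, mlp_ratio=2.0)


def init_str_params(rng: np.random.Generator, cfg: STRConfig, dtype=np.float32):
    chans = _level_channels(cfg)
    enc = []
    in_c = 2  # moving + fixed concatenated on the channel axis
    for c in chans:
        stage = {"conv": _init_conv(rng, c, in_c, dtype)}
        if cfg.use_swin and cfg.n_stl_encoder > 0:
            sw = _swin_cfg(cfg, c)
            stage["stls"] = [init_stl_params(rng, sw, dtype=dtype)
                             for _ in range(cfg.n_stl_encoder)]
        enc.append(stage)
        in_c = c
    dec = []
    skip_chans = chans[-2::-1] + [0]  # deepest stage has no deeper skip
    up_in = chans[-1]
    for c, skip_c in zip(chans[::-1], skip_chans):
        dec.append(_init_conv(rng, c, up_in + skip_c, dtype))
        up_in = c
    # the raw (moving, fixed) pair re-enters at full resolution so the flow
    # head sees fine edges that the stride-2 encoder discarded
    refine = [_init_conv(rng, cfg.base_channels, up_in + 2, dtype),
              _init_conv(rng, cfg.base_channels, cfg.base_channels, dtype)]
    flow = {"w": np.zeros((2, cfg.base_channels, 3, 3), dtype=dtype),
            "b": np.zeros(2, dtype=dtype)}
    return {"enc": enc, "dec": dec, "refine": refine, "flow": flow}


def _apply_conv(p, x, stride=1):
    return conv2d(x, p["w"], stride, 1) + anp.reshape(p["b"], (1, -1, 1, 1))


def str_forward(moving, fixed, cfg: STRConfig, params):
    """Predict the displacement field aligning ``moving`` toward ``fixed``.

    Returns (B, 2, H, W) in pixel units at the input resolution.
    """
    mshape = np.asarray(getattr(moving, "_value", moving)).shape
    fshape = np.asarray(getattr(fixed, "_value", fixed)).shape
    if mshape != fshape:
        raise DimensionMismatchError(f"moving {mshape} != fixed {fshape}")
    h0, w0 = mshape[2], mshape[3]
    if h0 % (2 ** cfg.levels) or w0 % (2 ** cfg.levels):
        raise InvalidConfigError(
            f"{h0}x{w0} input not divisible by 2^levels = {2 ** cfg.levels}"
        )

    x = anp.concatenate([moving, fixed], axis=1)
    skips = []
    for stage in params["enc"]:
        x = leaky_relu(_apply_conv(stage["conv"], x, stride=2), cfg.leaky_slope)
        if "stls" in stage:
            c = stage["conv"]["w"].shape[0]
            size = x.shape[2]
            sw = _swin_cfg(cfg, c)
            m = min(sw.window_size, size)
            if m >= 2:
                sw = SwinConfig(window_size=m, embed_dim=sw.embed_dim,
                                num_heads=sw.num_heads, mlp_ratio=sw.mlp_ratio)
                for lcfg, lp in zip(stl_stack_configs(sw, len(stage["stls"])),
                                    stage["stls"]):
                    x = swin_layer_forward(x, lcfg, lp)
        skips.append(x)

    skips = skips[:-1][::-1]  # deepest activation is the decoder input itself
    for i, p in enumerate(params["dec"]):
        x = upsample_nearest(x, 2)
        if i < len(skips):
            x = anp.concatenate([x, skips[i]], axis=1)
        x = leaky_relu(_apply_conv(p, x), cfg.leaky_slope)
    x = anp.concatenate([x, moving, fixed], axis=1)
    for p in params["refine"]:
        x = leaky_relu(_apply_conv(p, x), cfg.leaky_slope)
    return _apply_conv(params["flow"], x)


def spatial_resample(image, dvf):
    """Bilinear resampling of ``image`` at the grid displaced by ``dvf``.

    ``out(p) = image(p + dvf(p))`` with border clamping; differentiable in
    both arguments.  The zero field reproduces ``image`` exactly.
    """
    dv = np.asarray(getattr(dvf, "_value", dvf))
    im = np.asarray(getattr(image, "_value", image))
    if not np.all(np.isfinite(dv)):
        raise FloatingPointError("non-finite displacement field")
    if im.shape[0] != dv.shape[0] or im.shape[2:] != dv.shape[2:] \
            or dv.shape[1] != 2:
        raise DimensionMismatchError(
            f"image {im.shape} incompatible with dvf {dv.shape}"
        )
    return bilinear_warp(image, dvf)


def invert_dvf(dvf, n_iter: int = 20):
    """Fixed-point numerical inverse of a small displacement field.

    Solves ``v(p) = -u(p + v(p))`` by iteration, so that warping by ``v``
    undoes (approximately) a warp by ``u``.  Plain numpy; not differentiable.
    """
    u = np.asarray(dvf, dtype=np.float64)
    v = -u
    for _ in range(n_iter):
        v = -np.asarray(bilinear_warp(u, v))
    return v.astype(dvf.dtype, copy=False)


def smoothness_loss(dvf):
    """Mean squared spatial gradient of the displacement field.

    Forward finite differences; the squared gradient norm is summed over the
    two displacement components, averaged over batch and pixels, and the row
    and column derivative directions are averaged — so a unit-slope
    single-component field scores 0.5.
    """
    dr = dvf[:, :, 1:, :] - dvf[:, :, :-1, :]
    dc = dvf[:, :, :, 1:] - dvf[:, :, :, :-1]
    row_term = anp.sum(anp.mean(dr * dr, axis=(0, 2, 3)))
    col_term = anp.sum(anp.mean(dc * dc, axis=(0, 2, 3)))
    return 0.5 * (row_term + col_term)
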