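"""Low-level differentiable operations shared by all networks.

Everything here is a pure function of numpy arrays so that it can be traced
by ``autograd``.  The two expensive inner loops (3x3 convolution and bilinear
warping) are registered as fused primitives with hand-written vector-Jacobian
products; the rest composes ``autograd.numpy`` ops.

Conventions
-----------
* Images and feature maps are ``(batch, channel, row, col)`` float arrays.
* Parameter collections are nested dicts / lists of numpy arrays ("pytrees");
  see :func:`tree_flatten` for the deterministic traversal order used by the
  optimizer and by checkpoints.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.core import defvjp_argnums
from autograd.extend import defvjp, primitive

__all__ = [
    "conv2d",
    "bilinear_warp",
    "layer_norm",
    "softmax",
    "gelu",
    "leaky_relu",
    "sigmoid",
    "softplus",
    "instance_norm",
    "upsample_nearest",
    "reflect_pad2d",
    "cyclic_shift",
    "trunc_normal",
    "he_normal",
    "tree_flatten",
    "tree_unflatten",
    "tree_map",
    "AdamState",
    "adam_step",
]

# ---------------------------------------------------------------------------
# convolution (im2col based, fused primitive)
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(B, C, Hp, Wp) padded input -> (B, C*kh*kw, ho*wo) patch matrix,
    channel-major to match ``w.reshape(O, C*kh*kw)``."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, kh * kw, ho * wo), dtype=xp.dtype)
    k = 0
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            cols[:, :, k, :] = patch.reshape(b, c, ho * wo)
            k += 1
    return cols.reshape(b, c * kh * kw, ho * wo)


def _col2im(gcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    b, c, h, w = xshape
    gcols = gcols.reshape(b, c, kh * kw, ho * wo)
    gxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    k = 0
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                gcols[:, :, k, :].reshape(b, c, ho, wo)
            )
            k += 1
    if pad:
        gxp = gxp[:, :, pad : pad + h, pad : pad + w]
    return gxp


@primitive
def conv2d(x, w, stride=1, pad=1):
    """2D cross-correlation: x (B,C,H,W), w (O,C,kh,kw) -> (B,O,Ho,Wo)."""
    b, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, ho, wo)
    out = np.matmul(w.reshape(o, -1)[None], cols)
    return out.reshape(b, o, ho, wo)


def _conv2d_vjp_x(ans, x, w, stride=1, pad=1):
    o, c, kh, kw = w.shape

    def vjp(g):
        b, _, ho, wo = g.shape
        gcols = np.matmul(w.reshape(o, -1).T[None], g.reshape(b, o, ho * wo))
        return _col2im(gcols, x.shape, kh, kw, stride, pad, ho, wo)

    return vjp


def _conv2d_vjp_w(ans, x, w, stride=1, pad=1):
    o, c, kh, kw = w.shape

    def vjp(g):
        b, _, ho, wo = g.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        cols = _im2col(xp, kh, kw, stride, ho, wo)
        gw = np.tensordot(g.reshape(b, o, ho * wo), cols, axes=([0, 2], [0, 2]))
        return gw.reshape(o, c, kh, kw).astype(w.dtype, copy=False)

    return vjp


defvjp(conv2d, _conv2d_vjp_x, _conv2d_vjp_w)


# ---------------------------------------------------------------------------
# bilinear warping (fused primitive, differentiable w.r.t. image and field)
# ---------------------------------------------------------------------------


def _warp_coords(dvf, h, w):
    gr, gc = np.meshgrid(np.arange(h, dtype=dvf.dtype),
                         np.arange(w, dtype=dvf.dtype), indexing="ij")
    r = gr[None] + dvf[:, 0]
    c = gc[None] + dvf[:, 1]
    rc = np.clip(r, 0.0, h - 1.0)
    cc = np.clip(c, 0.0, w - 1.0)
    r0 = np.floor(rc).astype(np.int64)
    c0 = np.floor(cc).astype(np.int64)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = rc - r0
    fc = cc - c0
    return r, c, rc, cc, r0, r1, c0, c1, fr, fc


@primitive
def bilinear_warp(x, dvf):
    """Sample ``x`` at the identity grid displaced by ``dvf`` (pixels).

    x : (B, C, H, W); dvf : (B, 2, H, W) with (row, col) displacement.
    Out-of-range coordinates are clamped to the border.  A zero field is the
    exact identity.
    """
    b, ch, h, w = x.shape
    _, _, rc, cc, r0, r1, c0, c1, fr, fc = _warp_coords(dvf, h, w)
    bi = np.arange(b)[:, None, None]
    x00 = x[bi, :, r0, c0].transpose(0, 3, 1, 2)
    x01 = x[bi, :, r0, c1].transpose(0, 3, 1, 2)
    x10 = x[bi, :, r1, c0].transpose(0, 3, 1, 2)
    x11 = x[bi, :, r1, c1].transpose(0, 3, 1, 2)
    fr = fr[:, None]
    fc = fc[:, None]
    return (x00 * (1 - fr) * (1 - fc) + x01 * (1 - fr) * fc
            + x10 * fr * (1 - fc) + x11 * fr * fc)


def _warp_vjp_x(ans, x, dvf):
    b, ch, h, w = x.shape

    def vjp(g):
        _, _, _, _, r0, r1, c0, c1, fr, fc = _warp_coords(dvf, h, w)
        hw = h * w
        # one bincount scatter over (corner, batch, channel, pixel)
        base = (np.arange(b * ch, dtype=np.int64) * hw).reshape(b, ch, 1)
        idx_parts, wgt_parts = [], []
        for rr, cc_, wgt in (
            (r0, c0, (1 - fr) * (1 - fc)),
            (r0, c1, (1 - fr) * fc),
            (r1, c0, fr * (1 - fc)),
            (r1, c1, fr * fc),
        ):
            idx = (rr * w + cc_).reshape(b, 1, hw) + base
            idx_parts.append(np.broadcast_to(idx, (b, ch, hw)).ravel())
            wgt_parts.append((g * wgt[:, None]).reshape(-1))
        gx = np.bincount(np.concatenate(idx_parts),
                         weights=np.concatenate(wgt_parts),
                         minlength=b * ch * hw)
        return gx.reshape(b, ch, h, w).astype(x.dtype, copy=False)

    return vjp


def _warp_vjp_dvf(ans, x, dvf):
    b, ch, h, w = x.shape

    def vjp(g):
        r, c, _, _, r0, r1, c0, c1, fr, fc = _warp_coords(dvf, h, w)
        bi = np.arange(b)[:, None, None]
        x00 = x[bi, :, r0, c0].transpose(0, 3, 1, 2)
        x01 = x[bi, :, r0, c1].transpose(0, 3, 1, 2)
        x10 = x[bi, :, r1, c0].transpose(0, 3, 1, 2)
        x11 = x[bi, :, r1, c1].transpose(0, 3, 1, 2)
        frb = fr[:, None]
        fcb = fc[:, None]
        # d(out)/d(r): interpolate the row-difference along columns
        dr = (x10 - x00) * (1 - fcb) + (x11 - x01) * fcb
        dc = (x01 - x00) * (1 - frb) + (x11 - x10) * frb
        # clamped coordinates have zero derivative w.r.t. the displacement
        in_r = ((r > 0.0) & (r < h - 1.0)).astype(x.dtype)[:, None]
        in_c = ((c > 0.0) & (c < w - 1.0)).astype(x.dtype)[:, None]
        gr = np.sum(g * dr * in_r, axis=1)
        gc = np.sum(g * dc * in_c, axis=1)
        return np.stack([gr, gc], axis=1)

    return vjp


defvjp(bilinear_warp, _warp_vjp_x, _warp_vjp_dvf)


# ---------------------------------------------------------------------------
# fused windowed multi-head attention
# ---------------------------------------------------------------------------


def _attention_internals(x, qkv_w, qkv_b, proj_w, proj_b, table, index,
                         heads, mask):
    n, t, c = x.shape
    d = c // heads
    scale = 1.0 / float(np.sqrt(d))
    qkv = (np.matmul(x, qkv_w) + qkv_b).reshape(n, t, 3, heads, d)
    qkv = qkv.transpose(2, 0, 3, 1, 4)                          # 3, N, h, t, d
    q, k, v = qkv[0], qkv[1], qkv[2]
    s = np.matmul(q, k.transpose(0, 1, 3, 2)) * scale
    s = s + table[index.reshape(-1)].T.reshape(heads, t, t)[None]
    if mask is not None:
        nw = mask.shape[0]
        s = (s.reshape(n // nw, nw, heads, t, t) + mask[None, :, None]
             ).reshape(n, heads, t, t)
    s = s - s.max(axis=-1, keepdims=True)
    p = np.exp(s)
    p /= p.sum(axis=-1, keepdims=True)
    o = np.matmul(p, v)                                         # N, h, t, d
    oc = o.transpose(0, 2, 1, 3).reshape(n, t, c)
    y = np.matmul(oc, proj_w) + proj_b
    return y, (q, k, v, p, oc)


@primitive
def fused_window_attention(x, qkv_w, qkv_b, proj_w, proj_b, table, index,
                           heads, mask):
    """softmax(Q K^T / sqrt(d) + B + mask) V with head concat + projection,
    as a single tape node (one shared backward pass)."""
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite attention input")
    return _attention_internals(x, qkv_w, qkv_b, proj_w, proj_b, table,
                                index, heads, mask)[0]


def _fwa_vjp_argnums(argnums, ans, args, kwargs):
    x, qkv_w, qkv_b, proj_w, proj_b, table, index, heads, mask = args
    n, t, c = x.shape
    d = c // heads
    scale = 1.0 / float(np.sqrt(d))
    cache: list = []  # recompute intermediates lazily, once, at backward time

    def vjp_all(g):
        if not cache:
            cache.append(_attention_internals(*args)[1])
        q, k, v, p, oc = cache[0]
        g_oc = np.matmul(g, proj_w.T).reshape(n, t, heads, d)
        g_o = g_oc.transpose(0, 2, 1, 3)                        # N, h, t, d
        g_p = np.matmul(g_o, v.transpose(0, 1, 3, 2))
        g_v = np.matmul(p.transpose(0, 1, 3, 2), g_o)
        g_s = p * (g_p - np.sum(g_p * p, axis=-1, keepdims=True))
        g_q = np.matmul(g_s, k) * scale
        g_k = np.matmul(g_s.transpose(0, 1, 3, 2), q) * scale
        g_qkv = np.stack([g_q, g_k, g_v])                       # 3, N, h, t, d
        g_qkv = g_qkv.transpose(1, 3, 0, 2, 4).reshape(n, t, 3 * c)

        grads = {}
        if 0 in argnums:
            grads[0] = np.matmul(g_qkv, qkv_w.T)
        if 1 in argnums:
            grads[1] = np.tensordot(x, g_qkv, axes=([0, 1], [0, 1]))
        if 2 in argnums:
            grads[2] = g_qkv.sum(axis=(0, 1))
        if 3 in argnums:
            grads[3] = np.tensordot(oc, g, axes=([0, 1], [0, 1]))
        if 4 in argnums:
            grads[4] = g.sum(axis=(0, 1))
        if 5 in argnums:
            g_b = g_s.sum(axis=0)                               # h, t, t
            gt = np.stack([
                np.bincount(index.reshape(-1), weights=g_b[h].reshape(-1),
                            minlength=table.shape[0])
                for h in range(heads)
            ], axis=1)
            grads[5] = gt.astype(table.dtype, copy=False)
        return tuple(grads[a] for a in argnums)

    return vjp_all


defvjp_argnums(fused_window_attention, _fwa_vjp_argnums)


# ---------------------------------------------------------------------------
# normalization / activations (fused where it pays off)
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


@primitive
def _layer_norm_raw(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * gamma + beta


def _ln_internals(x):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    return xc * inv, inv


def _ln_vjp_x(ans, x, gamma, beta):
    def vjp(g):
        xhat, inv = _ln_internals(x)
        n = x.shape[-1]
        gh = g * gamma
        return inv * (gh - gh.mean(axis=-1, keepdims=True)
                      - xhat * np.mean(gh * xhat, axis=-1, keepdims=True))

    return vjp


def _ln_vjp_gamma(ans, x, gamma, beta):
    def vjp(g):
        xhat, _ = _ln_internals(x)
        gsum = (g * xhat).reshape(-1, x.shape[-1]).sum(axis=0)
        return gsum.astype(gamma.dtype, copy=False)

    return vjp


def _ln_vjp_beta(ans, x, gamma, beta):
    def vjp(g):
        return g.reshape(-1, x.shape[-1]).sum(axis=0).astype(beta.dtype, copy=False)

    return vjp


defvjp(_layer_norm_raw, _ln_vjp_x, _ln_vjp_gamma, _ln_vjp_beta)


def layer_norm(x, gamma, beta):
    """Layer normalization over the last axis with affine parameters."""
    return _layer_norm_raw(x, gamma, beta)


@primitive
def softmax(x):
    """Numerically stable softmax over the last axis."""
    m = np.max(x, axis=-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_vjp(ans, x):
    def vjp(g):
        return ans * (g - np.sum(g * ans, axis=-1, keepdims=True))

    return vjp


defvjp(softmax, _softmax_vjp)

_SQRT2 = float(np.sqrt(2.0))  # python float: never upcasts float32 arrays
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))

from scipy.special import erf as _erf_np  # noqa: E402


@primitive
def gelu(x):
    """Exact (erf-based) GELU, fused forward + backward."""
    return 0.5 * x * (1.0 + _erf_np(x / _SQRT2))


def _gelu_vjp(ans, x):
    def vjp(g):
        cdf = 0.5 * (1.0 + _erf_np(x / _SQRT2))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return g * (cdf + x * pdf)

    return vjp


defvjp(gelu, _gelu_vjp)


def leaky_relu(x, slope=0.2):
    return anp.where(x >= 0, x, slope * x)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def softplus(x):
    """log(1 + exp(x)), computed stably in logit space."""
    return anp.logaddexp(x, 0.0)


def instance_norm(x, eps=1e-5):
    """Per-sample, per-channel spatial normalization (no affine)."""
    mu = anp.mean(x, axis=(2, 3), keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=(2, 3), keepdims=True)
    return (x - mu) / anp.sqrt(var + eps)


def upsample_nearest(x, factor=2):
    """(B, C, H, W) -> (B, C, factor*H, factor*W) by pixel duplication."""
    return anp.repeat(anp.repeat(x, factor, axis=2), factor, axis=3)


def reflect_pad2d(x, pb, pr):
    """Reflect-pad bottom by ``pb`` rows and right by ``pr`` cols (traceable).

    ``autograd`` only differentiates constant-mode ``np.pad``, so reflection
    is built from flipped slices.
    """
    if pb:
        x = anp.concatenate([x, x[:, :, -2 : -2 - pb : -1, :]], axis=2)
    if pr:
        x = anp.concatenate([x, x[:, :, :, -2 : -2 - pr : -1]], axis=3)
    return x


def cyclic_shift(x, sr, sc):
    """np.roll over the two trailing spatial axes (scalar shifts only —
    tuple shifts break autograd's roll VJP)."""
    if sr:
        x = anp.roll(x, sr, axis=2)
    if sc:
        x = anp.roll(x, sc, axis=3)
    return x


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def trunc_normal(rng: np.random.Generator, shape, std=0.02, dtype=np.float32):
    """Normal(0, std) resampled until within 2 std (SwinIR-style init)."""
    out = rng.standard_normal(shape) * std
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.standard_normal(bad.sum()) * std
        bad = np.abs(out) > 2 * std
    return out.astype(dtype)


def he_normal(rng: np.random.Generator, shape, fan_in, dtype=np.float32):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


# ---------------------------------------------------------------------------
# parameter pytrees + Adam
# ---------------------------------------------------------------------------


def tree_flatten(tree, prefix=""):
    """Deterministic (sorted-key) flattening into [(path, array), ...]."""
    if isinstance(tree, dict):
        out = []
        for k in sorted(tree):
            out.extend(tree_flatten(tree[k], f"{prefix}{k}/"))
        return out
    if isinstance(tree, (list, tuple)):
        out = []
        for i, v in enumerate(tree):
            out.extend(tree_flatten(v, f"{prefix}{i}/"))
        return out
    return [(prefix.rstrip("/"), tree)]


def tree_unflatten(template, leaves):
    """Rebuild a pytree shaped like ``template`` from a flat leaf list."""
    it = iter(leaves)

    def rebuild(node):
        if isinstance(node, dict):
            return {k: rebuild(node[k]) for k in sorted(node)}
        if isinstance(node, (list, tuple)):
            return [rebuild(v) for v in node]
        return next(it)

    out = rebuild(template)
    return out


def tree_map(fn, tree):
    if isinstance(tree, dict):
        return {k: tree_map(fn, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return [tree_map(fn, v) for v in tree]
    return fn(tree)


class AdamState:
    """Adam moments for one parameter pytree."""

    def __init__(self, params, lr=1e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)


def adam_step(params, grads, state: AdamState):
    """One in-place-free Adam update; returns the new parameter pytree."""
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    bc1 = 1.0 - b1 ** state.t
    bc2 = 1.0 - b2 ** state.t
    flat_p = tree_flatten(params)
    flat_g = tree_flatten(grads)
    flat_m = tree_flatten(state.m)
    flat_v = tree_flatten(state.v)
    new_p, new_m, new_v = [], [], []
    for (_, p), (_, g), (_, m), (_, v) in zip(flat_p, flat_g, flat_m, flat_v):
        g = np.asarray(g, dtype=p.dtype)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        step = state.lr * (m / bc1) / (np.sqrt(v / bc2) + state.eps)
        new_p.append((p - step).astype(p.dtype, copy=False))
        new_m.append(m)
        new_v.append(v)
    state.m = tree_unflatten(state.m, new_m)
    state.v = tree_unflatten(state.v, new_v)
    return tree_unflatten(params, new_p)
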