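"""Patch discriminator and the training losses.

Losses: a logit-space adversarial term (discriminator and non-saturating
generator forms), the registration-corrected L1 term (target vs. the
generated image warped by the predicted field), and the weighted total
``kappa * adv + lam * corr + mu * smooth`` with defaults (1, 20, 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from ._ops import conv2d, he_normal, instance_norm, leaky_relu, softplus
from .registration import spatial_resample
from .swin_core import DimensionMismatchError, InvalidConfigError

__all__ = [
    "LossWeights",
    "DiscriminatorConfig",
    "init_discriminator_params",
    "discriminator_forward",
    "adversarial_loss",
    "correction_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the three loss components."""

    kappa: float = 1.0
    lam: float = 20.0
    mu: float = 10.0

    def __post_init__(self):
        if min(self.kappa, self.lam, self.mu) < 0:
            raise InvalidConfigError("loss weights must be non-negative")


@dataclass(frozen=True)
class DiscriminatorConfig:
    n_layers: int = 3
    base_channels: int = 64

    def __post_init__(self):
        if self.n_layers < 1 or self.base_channels < 1:
            raise InvalidConfigError("discriminator config fields must be >= 1")


def init_discriminator_params(rng: np.random.Generator, cfg: DiscriminatorConfig,
                              in_channels: int = 1, dtype=np.float32):
    params = []
    in_c = in_channels
    for i in range(cfg.n_layers):
        out_c = cfg.base_channels * (2 ** min(i, 3))
        params.append({
            "w": he_normal(rng, (out_c, in_c, 3, 3), fan_in=9 * in_c, dtype=dtype),
            "b": np.zeros(out_c, dtype=dtype),
        })
        in_c = out_c
    params.append({
        "w": he_normal(rng, (1, in_c, 3, 3), fan_in=9 * in_c, dtype=dtype),
        "b": np.zeros(1, dtype=dtype),
    })
    return {"layers": params}


def discriminator_forward(img, cfg: DiscriminatorConfig, params):
    """Patch logits: ``n_layers`` stride-2 3x3 conv blocks (LeakyReLU 0.2,
    instance norm from the second block) and a final stride-1 conv.

    (B, C, H, W) -> (B, 1, H / 2^n, W / 2^n) real-valued logits; no sigmoid.
    """
    shape = np.asarray(getattr(img, "_value", img)).shape
    if min(shape[2], shape[3]) < 2 ** cfg.n_layers:
        raise InvalidConfigError(
            f"{shape[2]}x{shape[3]} input too small for {cfg.n_layers} "
            "stride-2 reductions"
        )
    x = img
    for i, p in enumerate(params["layers"][:-1]):
        x = conv2d(x, p["w"], 2, 1) + anp.reshape(p["b"], (1, -1, 1, 1))
        if i > 0:
            x = instance_norm(x)
        x = leaky_relu(x, 0.2)
    p = params["layers"][-1]
    return conv2d(x, p["w"], 1, 1) + anp.reshape(p["b"], (1, -1, 1, 1))


def adversarial_loss(real_logits, fake_logits, role: str):
    """Binary-cross-entropy adversarial loss on patch logits.

    role='discriminator':  E[softplus(-D(y))] + E[softplus(D(G(x)))]
        (the minimized negative of the inner GAN objective)
    role='generator':      E[softplus(-D(G(x)))]  (non-saturating form)

    All terms are evaluated in logit space for numeric stability; at
    all-zero logits the discriminator loss is exactly ``2 log 2`` and the
    generator loss ``log 2``.
    """
    if role == "discriminator":
        return anp.mean(softplus(-real_logits)) + anp.mean(softplus(fake_logits))
    if role == "generator":
        return anp.mean(softplus(-fake_logits))
    raise InvalidConfigError(f"unknown role {role!r}")


def correction_loss(y, g_x, dvf):
    """Mean absolute error between ``y`` and the warped generated image:
    ``E[| y - g_x o dvf |]`` — misalignment is treated as label noise that
    the registration field must explain."""
    ys = np.asarray(getattr(y, "_value", y)).shape
    gs = np.asarray(getattr(g_x, "_value", g_x)).shape
    if ys != gs:
        raise DimensionMismatchError(f"target {ys} != generated {gs}")
    warped = spatial_resample(g_x, dvf)
    return anp.mean(anp.abs(y - warped))


def total_loss(adv, corr, smooth, w: LossWeights):
    """``kappa * adv + lam * corr + mu * smooth``."""
    return w.kappa * adv + w.lam * corr + w.mu * smooth
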