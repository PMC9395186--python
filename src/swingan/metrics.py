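"""Image-fidelity metrics: PSNR, MAE, SSIM and absolute-difference error maps.

All metrics assume inputs in [0, 1] with the data range fixed at 1.0.  PSNR
is capped at 100 dB for (near-)identical images.  SSIM is the
gaussian-weighted form (11x11 window, sigma 1.5, population covariance,
K1=0.01, K2=0.03) computed from first principles with scipy filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .swin_core import DimensionMismatchError

__all__ = ["MetricsRecord", "compute_metrics", "error_map", "psnr", "mae", "ssim"]

PSNR_CAP = 100.0
_MSE_FLOOR = 1e-10


@dataclass
class MetricsRecord:
    psnr: np.ndarray        # per image, dB
    mae: np.ndarray         # per image, [0, 1] intensity units
    ssim: np.ndarray        # per image, dimensionless
    psnr_mean: float
    psnr_sd: float
    mae_mean: float
    mae_sd: float
    ssim_mean: float
    ssim_sd: float


def _as_batch(a) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 2:
        a = a[None]
    elif a.ndim == 4:  # (B, 1, H, W)
        a = a[:, 0]
    if a.ndim != 3:
        raise DimensionMismatchError(f"expected 2D/3D/4D image array, got {a.shape}")
    return a


def psnr(pred: np.ndarray, truth: np.ndarray) -> float:
    mse = float(np.mean((np.asarray(pred, dtype=np.float64) - truth) ** 2))
    if mse < _MSE_FLOOR:
        return PSNR_CAP
    return 10.0 * np.log10(1.0 / mse)


def mae(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(pred, dtype=np.float64) - truth)))


def ssim(pred: np.ndarray, truth: np.ndarray, sigma: float = 1.5,
         truncate: float = 3.5, k1: float = 0.01, k2: float = 0.03,
         data_range: float = 1.0) -> float:
    """Gaussian-weighted SSIM of one 2D image pair (Wang et al. convention)."""
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    if x.shape != y.shape:
        raise DimensionMismatchError(f"{x.shape} != {y.shape}")
    fargs = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(x, **fargs)
    uy = gaussian_filter(y, **fargs)
    uxx = gaussian_filter(x * x, **fargs)
    uyy = gaussian_filter(y * y, **fargs)
    uxy = gaussian_filter(x * y, **fargs)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2))
    pad = int(truncate * sigma + 0.5)  # filter radius; exclude boundary ring
    return float(s[pad:-pad, pad:-pad].mean())


def compute_metrics(pred, truth) -> MetricsRecord:
    """Per-image PSNR / MAE / SSIM plus batch mean and standard deviation."""
    p = _as_batch(pred)
    t = _as_batch(truth)
    if p.shape != t.shape:
        raise DimensionMismatchError(f"pred {p.shape} != truth {t.shape}")
    psnrs = np.array([psnr(pi, ti) for pi, ti in zip(p, t)])
    maes = np.array([mae(pi, ti) for pi, ti in zip(p, t)])
    ssims = np.array([ssim(pi, ti) for pi, ti in zip(p, t)])
    return MetricsRecord(
        psnr=psnrs, mae=maes, ssim=ssims,
        psnr_mean=float(psnrs.mean()), psnr_sd=float(psnrs.std()),
        mae_mean=float(maes.mean()), mae_sd=float(maes.std()),
        ssim_mean=float(ssims.mean()), ssim_sd=float(ssims.std()),
    )


def error_map(pred, truth) -> np.ndarray:
    """Per-pixel absolute difference, same shape as the inputs."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise DimensionMismatchError(f"pred {p.shape} != truth {t.shape}")
    return np.abs(p - t)
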