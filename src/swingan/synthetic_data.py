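"""Synthetic multi-modal phantom generator.

Stands in for paired MRI contrasts at desk scale: a shared elliptical
anatomy is rendered under two monotone intensity mappings with *reversed*
tissue ordering (contrast inversion, T1-vs-T2 style), and the observed
target can be pixel-aligned, deformed by a known smooth displacement field,
or drawn from a different sample entirely (unpaired derangement).

Every sample records the ground truth needed for closed-loop testing:
the aligned target and, in misaligned mode, the exact field that produced
the observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .registration import spatial_resample
from .swin_core import InvalidConfigError

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "make_anatomy",
    "modality_transform",
    "random_smooth_dvf",
    "make_dataset",
    "samples_to_arrays",
    "save_dataset",
    "load_dataset",
    "load_image",
    "load_nifti_slice",
]

MODES = ("aligned", "misaligned", "unpaired")


@dataclass(frozen=True)
class PhantomConfig:
    n_samples: int = 50
    image_size: int = 32
    n_shapes: tuple[int, int] = (3, 6)
    noise_sd: float = 0.01
    blur_sd: float = 0.7  # soft tissue edges keep warp interpolation loss low
    deform_amplitude: float = 2.0
    deform_smoothness: float = 4.0
    mode: str = "aligned"
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise InvalidConfigError("image_size must be >= 16")
        if self.noise_sd < 0 or self.deform_amplitude < 0:
            raise InvalidConfigError("noise_sd and deform_amplitude must be >= 0")
        if self.deform_smoothness <= 0:
            raise InvalidConfigError("deform_smoothness must be positive")
        if self.mode not in MODES:
            raise InvalidConfigError(f"mode must be one of {MODES}")
        if self.mode == "unpaired" and self.n_samples < 2:
            raise InvalidConfigError("unpaired mode needs at least 2 samples")


@dataclass
class PhantomSample:
    x: np.ndarray                 # (H, W) source modality, [0, 1]
    y_aligned: np.ndarray         # (H, W) target modality, pixel-aligned with x
    y_observed: np.ndarray        # (H, W) training target per mode
    true_dvf: np.ndarray | None   # (2, H, W) or None
    mode: str


def make_anatomy(seed: int, size: int, n_shapes: tuple[int, int] = (3, 6)) -> np.ndarray:
    """Labeled tissue map: outer head ellipse (label 1) plus random interior
    ellipses (labels 2..K); background is 0.  Deterministic given ``seed``."""
    if size < 16:
        raise InvalidConfigError("size must be >= 16")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:size, 0:size]
    labels = np.zeros((size, size), dtype=np.int64)

    cy = cx = (size - 1) / 2.0
    # outer ellipse inscribed with a margin so background is always present
    ay = size * rng.uniform(0.33, 0.42)
    ax = size * rng.uniform(0.33, 0.42)
    head = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    labels[head] = 1

    k = int(rng.integers(n_shapes[0], n_shapes[1] + 1))
    for i in range(k):
        ecy = cy + rng.uniform(-0.18, 0.18) * size
        ecx = cx + rng.uniform(-0.18, 0.18) * size
        ey = size * rng.uniform(0.05, 0.16)
        ex = size * rng.uniform(0.05, 0.16)
        theta = rng.uniform(0, np.pi)
        dr = rr - ecy
        dc = cc - ecx
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        ell = (u / ey) ** 2 + (v / ex) ** 2 <= 1.0
        labels[ell & head] = i + 2
    return labels


def _luts(n_labels: int) -> tuple[np.ndarray, np.ndarray]:
    """Monotone tissue-intensity tables; modality B reverses A's ordering."""
    lut_a = np.concatenate([[0.0], np.linspace(0.25, 0.9, n_labels - 1)])
    lut_b = np.concatenate([[0.0], np.linspace(0.25, 0.9, n_labels - 1)[::-1]])
    return lut_a, lut_b


def modality_transform(anatomy: np.ndarray, modality: str, noise_sd: float,
                       seed: int, blur_sd: float = 0.5) -> np.ndarray:
    """Render one modality of a tissue map; output in [0, 1].

    Tissue labels map to modality-specific mean intensities (modality "B"
    reverses "A"'s tissue ordering), Gaussian noise is added, then a mild
    blur; clamping to [0, 1] comes last.
    """
    if modality not in ("A", "B"):
        raise InvalidConfigError("modality must be 'A' or 'B'")
    n_labels = int(anatomy.max()) + 1
    lut_a, lut_b = _luts(max(n_labels, 2))
    lut = lut_a if modality == "A" else lut_b
    img = lut[anatomy].astype(np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    if blur_sd > 0:
        img = gaussian_filter(img, blur_sd, mode="nearest")
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def random_smooth_dvf(seed: int, size: int, amplitude: float,
                      smoothness: float) -> np.ndarray:
    """Gaussian-smoothed white-noise field, rescaled so the maximum
    displacement magnitude equals ``amplitude``.  (2, H, W), pixel units."""
    if amplitude < 0:
        raise InvalidConfigError("amplitude must be >= 0")
    if amplitude == 0:
        return np.zeros((2, size, size), dtype=np.float32)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((2, size, size))
    smooth = np.stack([gaussian_filter(raw[i], smoothness, mode="nearest")
                       for i in range(2)])
    mag = np.sqrt((smooth ** 2).sum(axis=0)).max()
    return (smooth * (amplitude / mag)).astype(np.float32)


def make_dataset(cfg: PhantomConfig) -> list[PhantomSample]:
    """Deterministic phantom dataset in the configured sampling mode."""
    root = np.random.SeedSequence(cfg.seed)
    per_sample = root.spawn(cfg.n_samples)
    mode_ss = root.spawn(1)[0]

    samples = []
    for ss in per_sample:
        s_anat, s_na, s_nb, s_dvf = (int(c.generate_state(1)[0])
                                     for c in ss.spawn(4))
        anatomy = make_anatomy(s_anat, cfg.image_size, cfg.n_shapes)
        x = modality_transform(anatomy, "A", cfg.noise_sd, s_na, cfg.blur_sd)
        y = modality_transform(anatomy, "B", cfg.noise_sd, s_nb, cfg.blur_sd)
        if cfg.mode == "misaligned":
            dvf = random_smooth_dvf(s_dvf, cfg.image_size,
                                    cfg.deform_amplitude, cfg.deform_smoothness)
            warped = spatial_resample(y[None, None].astype(np.float32),
                                      dvf[None])[0, 0]
            samples.append(PhantomSample(x, y, np.asarray(warped), dvf, cfg.mode))
        else:
            samples.append(PhantomSample(x, y, y, None, cfg.mode))

    if cfg.mode == "unpaired":
        rng = np.random.default_rng(mode_ss)
        perm = _derangement(rng, cfg.n_samples)
        for i, s in enumerate(samples):
            s.y_observed = samples[perm[i]].y_aligned
    if cfg.mode == "aligned":
        for s in samples:
            s.true_dvf = np.zeros((2, cfg.image_size, cfg.image_size),
                                  dtype=np.float32)
    return samples


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def samples_to_arrays(samples: list[PhantomSample]):
    """Stack a sample list into (x, y_observed, y_aligned, dvf) batches with
    shape (N, 1, H, W) / (N, 2, H, W); dvf is None unless every sample has one."""
    x = np.stack([s.x for s in samples])[:, None].astype(np.float32)
    y_obs = np.stack([s.y_observed for s in samples])[:, None].astype(np.float32)
    y_al = np.stack([s.y_aligned for s in samples])[:, None].astype(np.float32)
    if all(s.true_dvf is not None for s in samples):
        dvf = np.stack([s.true_dvf for s in samples]).astype(np.float32)
    else:
        dvf = None
    return x, y_obs, y_al, dvf


# ---------------------------------------------------------------------------
# I/O: 16-bit PNG datasets, single images, NIfTI slices
# ---------------------------------------------------------------------------


def _write_png16(path: Path, img: np.ndarray) -> None:
    arr = np.round(np.clip(img, 0.0, 1.0) * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path)  # uint16 -> 16-bit grayscale PNG


def _read_png16(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=np.float64)
    scale = 65535.0 if arr.max() > 255 else 255.0
    return (arr / scale).astype(np.float32)


def save_dataset(samples: list[PhantomSample], outdir: str | Path,
                 save_dvf: bool = True) -> Path:
    """Write PNGs plus a JSON manifest (and .npy fields when present)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, s in enumerate(samples):
        rec = {"index": i, "mode": s.mode}
        for name, img in (("x", s.x), ("y_aligned", s.y_aligned),
                          ("y_observed", s.y_observed)):
            fname = f"{i:05d}_{name}.png"
            _write_png16(outdir / fname, img)
            rec[name] = fname
        if save_dvf and s.true_dvf is not None:
            fname = f"{i:05d}_dvf.npy"
            np.save(outdir / fname, s.true_dvf)
            rec["true_dvf"] = fname
        records.append(rec)
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"samples": records}, indent=1))
    return manifest


def load_dataset(manifest_path: str | Path) -> list[PhantomSample]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    meta = json.loads(manifest_path.read_text())
    samples = []
    for rec in meta["samples"]:
        dvf = np.load(root / rec["true_dvf"]) if "true_dvf" in rec else None
        samples.append(PhantomSample(
            x=_read_png16(root / rec["x"]),
            y_aligned=_read_png16(root / rec["y_aligned"]),
            y_observed=_read_png16(root / rec["y_observed"]),
            true_dvf=dvf,
            mode=rec["mode"],
        ))
    return samples


def load_image(path: str | Path) -> np.ndarray:
    """Grayscale PNG -> (H, W) float32 in [0, 1]."""
    img = Image.open(path)
    if img.mode not in ("I;16", "I", "L", "F"):
        img = img.convert("L")
    return _read_png16(Path(path)) if img.mode == "I;16" else (
        np.asarray(img, dtype=np.float32) / (255.0 if img.mode == "L" else 1.0)
    )


def load_nifti_slice(path: str | Path, axis: int = 2, index: int | None = None
                     ) -> np.ndarray:
    """Extract one 2D slice from a NIfTI volume, min-max normalized to [0, 1]."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim > 3:
        vol = vol[..., 0]
    if index is None:
        index = vol.shape[axis] // 2
    sl = np.take(vol, index, axis=axis)
    lo, hi = sl.min(), sl.max()
    if hi > lo:
        sl = (sl - lo) / (hi - lo)
    else:
        sl = np.zeros_like(sl)
    return sl.astype(np.float32)
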