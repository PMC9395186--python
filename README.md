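# swingan

A Swin-transformer GAN for 2D grayscale modality translation (T1→T2-style),
with a deformable registration network that corrects spatial misalignment
between source and target images *during training*: instead of penalizing the
generator for honest anatomical differences, the L1 term compares the target
against the generated image warped by a predicted displacement field
(misalignment as correctable label noise).

Everything runs on plain numpy — the networks are pure functions of
parameter pytrees differentiated with [HIPS autograd](https://github.com/HIPS/autograd),
with fused custom primitives (im2col convolution, bilinear warping, windowed
attention) for CPU speed. No GPU or deep-learning framework is required.

## Components

| module            | contents |
|-------------------|----------|
| `swingan.swin_core`      | window partition/reverse, shifted-window multi-head attention with relative position bias, Swin transformer layer (STL), residual Swin transformer block (RSTB) |
| `swingan.generator`      | the translation generator: shallow conv → RSTB stack → long skip → sigmoid recovery head; attention-map extraction |
| `swingan.registration`   | U-shaped encoder–decoder flow network (Swin layers in the encoder), bilinear `spatial_resample`, gradient `smoothness_loss`, numerical field inversion |
| `swingan.adversarial`    | patch discriminator, logit-space adversarial losses, registration-corrected L1 `correction_loss`, weighted `total_loss` (κ, λ, μ defaults 1/20/10) |
| `swingan.synthetic_data` | multi-modal phantom generator (shared elliptical anatomy, contrast-inverted modalities, known smooth deformations; aligned / misaligned / unpaired modes), PNG/NIfTI I/O |
| `swingan.metrics`        | PSNR / MAE / SSIM (gaussian-weighted, 11×11, σ=1.5) and absolute-difference error maps |
| `swingan.train` + `swingan.cli` | alternating D and G+R training loop, checkpointing, inference, evaluation, 4-scenario ablation, greedy loss-weight sweep, `swingan` CLI |

## CLI

```bash
# synthesize a phantom dataset (PNG images + manifest.json)
swingan simulate --out data/ --n-samples 200 --mode misaligned --seed 0

# train (desk-scale defaults; YAML config + flag overrides)
swingan train --data data/manifest.json --out model.npz \
    --epochs 20 --seed 1 --scenario mmtrans --mode misaligned

# translate one image (PNG, or a NIfTI slice via --slice-axis/--slice-index)
swingan translate --checkpoint model.npz --input data/00000_x.png --out pred.png

# score against aligned ground truth (TSV table + per-image error maps)
swingan evaluate --checkpoint model.npz --data data/manifest.json --out eval/

# the four-scenario ablation (baseline_gan / swin_g / swin_g_plus_r / mmtrans)
swingan ablate --out ablation/ --epochs 10 --mode misaligned --seed 1

# greedy one-at-a-time loss-weight sweep
swingan sweep --out sweep/ --kappa-grid 0.01,1,100 --epochs 5
```

Training scenarios: `baseline_gan` (conv G + conv R), `swin_g` (Swin G, no
registration), `swin_g_plus_r` (Swin G + conv R), `mmtrans` (Swin G + Swin R).
The registration network is used only during training; inference applies the
generator alone (`--apply-registration` exposes the warped output).

## Library notes

- Images are `(batch, 1, H, W)` float arrays in [0, 1]; displacement fields
  are `(batch, 2, H, W)` in pixel units, (row, col) order.
- All randomness flows through seeded `numpy.random.Generator` streams;
  training is bitwise reproducible given the config, and checkpoints
  (`.npz` + JSON sidecar) round-trip losslessly.
- `TrainConfig()` carries the published-scale defaults (4 RSTBs × 6 STLs,
  80 epochs, lr 1e-4); `TrainConfig.desk_scale()` is the configuration used
  by the tests (minutes on one CPU core).
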