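"""Training loop, checkpointing, inference and the ablation / sweep drivers.

Each batch performs one discriminator update (on detached generator output)
followed by one joint generator + registration update on the weighted total
loss.  The four ablation scenarios swap Swin layers for plain convolutions
and/or disable the registration branch:

========================  ==========  ====================
scenario                  generator   registration
========================  ==========  ====================
baseline_gan              conv        conv
swin_g                    Swin        (disabled)
swin_g_plus_r             Swin        conv
mmtrans                   Swin        Swin
========================  ==========  ====================

The registration network is a training-time label-noise corrector only; by
default inference applies the generator alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from ._ops import AdamState, adam_step, tree_flatten
from .adversarial import (
    DiscriminatorConfig,
    LossWeights,
    adversarial_loss,
    correction_loss,
    discriminator_forward,
    init_discriminator_params,
    total_loss,
)
from .generator import GeneratorConfig, init_generator_params, stg_forward
from .metrics import MetricsRecord, compute_metrics, error_map
from .registration import (
    STRConfig,
    init_str_params,
    smoothness_loss,
    spatial_resample,
    str_forward,
)
from .swin_core import InvalidConfigError, SwinConfig
from .synthetic_data import PhantomSample, samples_to_arrays

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "train",
    "translate",
    "evaluate",
    "run_ablation",
    "run_sweep",
    "save_checkpoint",
    "load_checkpoint",
]

log = logging.getLogger(__name__)

SCENARIOS = ("baseline_gan", "swin_g", "swin_g_plus_r", "mmtrans")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 80
    batch_size: int = 4
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    scenario: str = "mmtrans"
    data_mode: str = "aligned"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    registration: STRConfig = field(default_factory=STRConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    holdout_fraction: float = 0.0
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    # whether the discriminator scores the registered (warped) output instead
    # of the raw generated image; off by default
    discriminate_registered: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be positive")
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")
        if self.scenario not in SCENARIOS:
            raise InvalidConfigError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise InvalidConfigError("holdout_fraction must be in [0, 1)")

    @property
    def has_registration(self) -> bool:
        return self.scenario != "swin_g"

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Small configuration that trains in minutes on one CPU core."""
        defaults = dict(
            learning_rate=1e-3,
            epochs=20,
            batch_size=8,
            generator=GeneratorConfig(
                n_rstb=2, n_stl_per_rstb=2,
                swin=SwinConfig(window_size=4, embed_dim=16, num_heads=2),
            ),
            registration=STRConfig(levels=3, base_channels=8, n_stl_encoder=1),
            discriminator=DiscriminatorConfig(n_layers=2, base_channels=16),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Checkpoint:
    g_params: dict
    d_params: dict
    r_params: dict | None
    opt_g: dict          # flattened Adam moments + step counters
    opt_d: dict
    epoch: int
    config: TrainConfig
    history: dict


def _scenario_configs(cfg: TrainConfig):
    gcfg = replace(cfg.generator, use_swin=cfg.scenario not in ("baseline_gan",))
    rcfg = replace(cfg.registration,
                   use_swin=cfg.scenario == "mmtrans")
    return gcfg, rcfg


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(cfg: TrainConfig, dataset: list[PhantomSample],
          progress: bool = False) -> Checkpoint:
    """Adversarial training on a phantom (or loaded) dataset.

    Deterministic given ``cfg`` (including ``cfg.seed``); returns the final
    checkpoint with a per-epoch and per-step loss history attached.
    """
    if len(dataset) == 0:
        raise InvalidConfigError("empty dataset")
    gcfg, rcfg = _scenario_configs(cfg)

    ss = np.random.SeedSequence(cfg.seed)
    init_ss, shuffle_ss = ss.spawn(2)
    init_rng = np.random.default_rng(init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)

    n_hold = int(round(cfg.holdout_fraction * len(dataset)))
    train_set = dataset[: len(dataset) - n_hold] if n_hold else dataset

    g_params = init_generator_params(init_rng, gcfg)
    d_params = init_discriminator_params(init_rng, cfg.discriminator)
    r_params = init_str_params(init_rng, rcfg) if cfg.has_registration else None

    joint = {"G": g_params}
    if r_params is not None:
        joint["R"] = r_params
    opt_g = AdamState(joint, lr=cfg.learning_rate,
                      beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_d = AdamState(d_params, lr=cfg.learning_rate,
                      beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    x_all, y_obs_all, _, _ = samples_to_arrays(train_set)
    w = cfg.weights

    def discriminator_fwd(img, dp):
        return discriminator_forward(img, cfg.discriminator, dp)

    def d_loss_fn(dp, xb, yb, fake_np):
        real_logits = discriminator_fwd(yb, dp)
        fake_logits = discriminator_fwd(fake_np, dp)
        return adversarial_loss(real_logits, fake_logits, "discriminator")

    def g_loss_fn(jp, xb, yb):
        fake = stg_forward(xb, gcfg, jp["G"])
        if cfg.has_registration:
            dvf = str_forward(fake, yb, rcfg, jp["R"])
            corr = correction_loss(yb, fake, dvf)
            smooth = smoothness_loss(dvf)
        else:
            dvf = None
            corr = anp.mean(anp.abs(yb - fake))
            smooth = 0.0
        disc_in = spatial_resample(fake, dvf) if (
            cfg.has_registration and cfg.discriminate_registered) else fake
        fake_logits = discriminator_fwd(disc_in, d_params)
        adv = adversarial_loss(None, fake_logits, "generator")
        return total_loss(adv, corr, smooth, w), (adv, corr, smooth)

    comp_cell: dict = {}

    def g_loss_scalar(jp, xb, yb):
        total, comps = g_loss_fn(jp, xb, yb)
        # stash raw component values from the traced forward (no extra pass)
        comp_cell["vals"] = tuple(
            float(np.asarray(getattr(v, "_value", v))) for v in comps
        )
        return total

    d_grad = value_and_grad(d_loss_fn)
    g_grad = value_and_grad(g_loss_scalar)

    history = {"epochs": [], "steps": []}
    step = 0
    epoch_iter = range(cfg.epochs)
    if progress:
        from tqdm import tqdm
        epoch_iter = tqdm(epoch_iter, desc=f"train[{cfg.scenario}]")
    for epoch in epoch_iter:
        comp_sums = np.zeros(5)  # d, adv, corr, smooth, total
        n_batches = 0
        for idx in _batches(len(train_set), cfg.batch_size, shuffle_rng):
            xb = x_all[idx]
            yb = y_obs_all[idx]

            fake_np = np.asarray(stg_forward(xb, gcfg, joint["G"]))
            d_val, d_g = d_grad(d_params, xb, yb, fake_np)
            d_params = adam_step(d_params, d_g, opt_d)

            g_val, g_gr = g_grad(joint, xb, yb)
            adv, corr, smooth = comp_cell["vals"]
            joint = adam_step(joint, g_gr, opt_g)

            if not (np.isfinite(d_val) and np.isfinite(g_val)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: "
                    f"d={d_val}, g={g_val}"
                )
            comps = (float(d_val), float(adv), float(corr), float(smooth),
                     float(g_val))
            history["steps"].append({
                "step": step, "epoch": epoch, "d_loss": comps[0],
                "adv": comps[1], "corr": comps[2], "smooth": comps[3],
                "total": comps[4],
            })
            comp_sums += comps
            n_batches += 1
            step += 1
        means = comp_sums / n_batches
        history["epochs"].append({
            "epoch": epoch, "d_loss": means[0], "adv": means[1],
            "corr": means[2], "smooth": means[3], "total": means[4],
        })
        log.info("epoch %d: d=%.4f adv=%.4f corr=%.4f smooth=%.5f total=%.4f",
                 epoch, *means)

    return Checkpoint(
        g_params=joint["G"], d_params=d_params, r_params=joint.get("R"),
        opt_g=_opt_to_dict(opt_g), opt_d=_opt_to_dict(opt_d),
        epoch=cfg.epochs, config=cfg, history=history,
    )


# ---------------------------------------------------------------------------
# inference / evaluation
# ---------------------------------------------------------------------------


def translate(ckpt: Checkpoint, images: np.ndarray,
              apply_registration: bool = False,
              reference: np.ndarray | None = None) -> np.ndarray:
    """Run the generator on a (B, 1, H, W) batch; output in [0, 1].

    Registration is a training-time correction and is not applied by
    default.  With ``apply_registration=True`` (and a reference batch) the
    translated-then-registered output is returned instead.
    """
    gcfg, rcfg = _scenario_configs(ckpt.config)
    out = np.asarray(stg_forward(images, gcfg, ckpt.g_params))
    if apply_registration:
        if ckpt.r_params is None:
            raise InvalidConfigError("checkpoint has no registration network")
        if reference is None:
            raise InvalidConfigError("apply_registration requires a reference batch")
        dvf = np.asarray(str_forward(out, reference, rcfg, ckpt.r_params))
        out = np.asarray(spatial_resample(out, dvf))
    return out


def evaluate(ckpt: Checkpoint, dataset: list[PhantomSample],
             outdir: str | Path | None = None, label: str = "model",
             batch_size: int = 32) -> MetricsRecord:
    """Translate and score against the aligned ground truth."""
    if len(dataset) == 0:
        raise InvalidConfigError("empty evaluation dataset")
    x, _, y_al, _ = samples_to_arrays(dataset)
    preds = np.concatenate([translate(ckpt, x[i : i + batch_size])
                            for i in range(0, len(x), batch_size)])
    rec = compute_metrics(preds, y_al)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metrics_table([(label, ckpt.config.data_mode, rec)],
                            outdir / "metrics.tsv")
        from .synthetic_data import _write_png16
        for i, (p, t) in enumerate(zip(preds[:, 0], y_al[:, 0])):
            _write_png16(outdir / f"{i:05d}_pred.png", p)
            _write_png16(outdir / f"{i:05d}_errmap.png", error_map(p, t))
    return rec


def write_metrics_table(rows, path: str | Path) -> None:
    """Tab-separated results; MAE and SSIM also shown on the x100 scale used
    in printed tables."""
    lines = ["method\tdataset\tpsnr_mean\tpsnr_sd\tmae_mean\tmae_sd\t"
             "ssim_mean\tssim_sd\tmae_x100\tssim_x100"]
    for label, ds, rec in rows:
        lines.append(
            f"{label}\t{ds}\t{rec.psnr_mean:.4f}\t{rec.psnr_sd:.4f}\t"
            f"{rec.mae_mean:.6f}\t{rec.mae_sd:.6f}\t"
            f"{rec.ssim_mean:.6f}\t{rec.ssim_sd:.6f}\t"
            f"{100 * rec.mae_mean:.2f}\t{100 * rec.ssim_mean:.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ablation / sweep drivers
# ---------------------------------------------------------------------------


def run_ablation(base_cfg: TrainConfig, dataset: list[PhantomSample],
                 eval_set: list[PhantomSample] | None = None,
                 scenarios=SCENARIOS, progress: bool = False):
    """Train every scenario with a shared seed and data; one result row each."""
    eval_set = eval_set if eval_set is not None else dataset
    rows = []
    for scenario in scenarios:
        cfg = replace(base_cfg, scenario=scenario)
        ckpt = train(cfg, dataset, progress=progress)
        rec = evaluate(ckpt, eval_set)
        rows.append({"scenario": scenario, "metrics": rec, "checkpoint": ckpt})
    return rows


def run_sweep(base_cfg: TrainConfig, dataset: list[PhantomSample],
              grids: dict[str, list[float]],
              eval_set: list[PhantomSample] | None = None,
              progress: bool = False):
    """Greedy one-at-a-time sweep over loss-weight grids.

    ``grids`` maps weight names ('kappa', 'lam', 'mu') to candidate lists;
    each weight is swept with the others fixed, then set to its best value
    (by held-out PSNR) before the next weight is swept.
    """
    eval_set = eval_set if eval_set is not None else dataset
    current = base_cfg.weights
    rows = []
    for name, values in grids.items():
        if name not in ("kappa", "lam", "mu"):
            raise InvalidConfigError(f"unknown weight {name!r}")
        best_value, best_psnr = None, -np.inf
        for v in values:
            weights = replace(current, **{name: float(v)})
            cfg = replace(base_cfg, weights=weights)
            ckpt = train(cfg, dataset, progress=progress)
            rec = evaluate(ckpt, eval_set)
            rows.append({"weight": name, "value": float(v), "metrics": rec})
            if rec.psnr_mean > best_psnr:
                best_value, best_psnr = float(v), rec.psnr_mean
        current = replace(current, **{name: best_value})
    return rows, current


# ---------------------------------------------------------------------------
# checkpoint serialization (npz arrays + JSON metadata sidecar)
# ---------------------------------------------------------------------------


def _opt_to_dict(state: AdamState) -> dict:
    return {"m": state.m, "v": state.v, "t": state.t, "lr": state.lr,
            "beta1": state.beta1, "beta2": state.beta2, "eps": state.eps}


def _config_to_json(cfg: TrainConfig) -> dict:
    return asdict(cfg)


def _config_from_json(d: dict) -> TrainConfig:
    d = dict(d)
    d["weights"] = LossWeights(**d["weights"])
    g = dict(d["generator"])
    g["swin"] = SwinConfig(**g["swin"])
    d["generator"] = GeneratorConfig(**g)
    d["registration"] = STRConfig(**d["registration"])
    d["discriminator"] = DiscriminatorConfig(**d["discriminator"])
    return TrainConfig(**d)


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    """Write ``<path>`` (npz arrays) and ``<path>.json`` (metadata)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    arrays = {}
    for group, tree in (("G", ckpt.g_params), ("D", ckpt.d_params),
                        ("R", ckpt.r_params),
                        ("optG", ckpt.opt_g["m"]), ("optGv", ckpt.opt_g["v"]),
                        ("optD", ckpt.opt_d["m"]), ("optDv", ckpt.opt_d["v"])):
        if tree is None:
            continue
        for key, arr in tree_flatten(tree):
            arrays[f"{group}/{key}"] = arr
    np.savez(path, **arrays)
    meta = {
        "epoch": ckpt.epoch,
        "config": _config_to_json(ckpt.config),
        "history": ckpt.history,
        "opt": {
            "g": {k: ckpt.opt_g[k] for k in ("t", "lr", "beta1", "beta2", "eps")},
            "d": {k: ckpt.opt_d[k] for k in ("t", "lr", "beta1", "beta2", "eps")},
        },
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))


def _unflatten_paths(flat: dict[str, np.ndarray]):
    """Rebuild nested dict/list pytrees from 'a/b/0/c'-style keys."""
    root: dict = {}
    for key, arr in flat.items():
        parts = key.split("/")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = arr

    def listify(node):
        if not isinstance(node, dict):
            return node
        keys = list(node.keys())
        if keys and all(k.isdigit() for k in keys):
            return [listify(node[k]) for k in sorted(keys, key=int)]
        return {k: listify(v) for k, v in node.items()}

    return listify(root)


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not path.exists() or not sidecar.exists():
        raise FileNotFoundError(f"checkpoint {path} (+.json sidecar) not found")
    try:
        meta = json.loads(sidecar.read_text())
        with np.load(path) as npz:
            flat = {k: npz[k] for k in npz.files}
    except Exception as exc:  # corrupt archive or sidecar
        raise IOError(f"failed to load checkpoint {path}: {exc}") from exc
    groups: dict[str, dict] = {}
    for key, arr in flat.items():
        group, rest = key.split("/", 1)
        groups.setdefault(group, {})[rest] = arr
    trees = {g: _unflatten_paths(d) for g, d in groups.items()}
    cfg = _config_from_json(meta["config"])
    opt_g = dict(meta["opt"]["g"])
    opt_g.update({"m": trees.get("optG"), "v": trees.get("optGv")})
    opt_d = dict(meta["opt"]["d"])
    opt_d.update({"m": trees.get("optD"), "v": trees.get("optDv")})
    return Checkpoint(
        g_params=trees["G"], d_params=trees["D"], r_params=trees.get("R"),
        opt_g=opt_g, opt_d=opt_d, epoch=meta["epoch"], config=cfg,
        history=meta["history"],
    )
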