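"""End-to-end experiment orchestration.

One config drives the whole protocol: generate phantoms, truncate the
lateral columns, train the completion network, complete every held-out
slice with each of the three methods (network-only, body-outline water
fill, hybrid), evaluate image metrics over both evaluation areas, and run
the gamma-index suite of arc-dose recalculations. All artifacts are
declared in a manifest with content hashes; per-stage seeds derive
deterministically from the master seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dosimetry import DEFAULT_CRITERIA_GRID, gamma_suite, summarize_pass_rates, toy_arc_dose, write_dose
from .image import CTSlice
from .metrics import SSIMConstants, evaluate_pair
from .network import NetworkSpec, complete
from .pbo import FillConstants, extract_outline, hybrid_fuse, pbo_fill, save_outline_png
from .phantom import PhantomSpec, generate_dataset
from .preprocess import apply_mask, make_truncation_mask
from .training import TrainConfig, train, write_loss_csv

__all__ = ["ExperimentConfig", "run_experiment", "stage_seed", "load_config"]

log = logging.getLogger("ctinpaint")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    h = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
    return int(np.random.SeedSequence([master, h]).generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    n_phantoms: int = 80
    n_test: int = 4
    grid_size: int = 64
    left_cols: int = 18
    right_cols: int = 18
    base_channels: float = 0.25
    epochs: int = 60
    seed: int = 0
    out_dir: str = "experiment_out"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    fill: FillConstants = field(default_factory=FillConstants)
    ssim: SSIMConstants = field(default_factory=SSIMConstants)
    gamma_grid: tuple = DEFAULT_CRITERIA_GRID
    n_beams: int = 36
    prescription_cGy: float = 200.0
    target_diameter_mm: float = 20.0

    def __post_init__(self):
        # keep the phantom and mask on the configured grid
        scale = self.grid_size / self.phantom.grid_size
        if scale != 1.0:
            self.phantom.grid_size = self.grid_size
            self.phantom.pixel_spacing = self.phantom.pixel_spacing / scale
        self.train_cfg.epochs = self.epochs
        self.train_cfg.seed = stage_seed(self.seed, "train")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, default=list, sort_keys=True, indent=1)


def load_config(path) -> ExperimentConfig:
    """Read a YAML (or JSON — YAML is a superset) experiment config."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    for key in ("phantom", "train_cfg", "fill", "ssim"):
        if key in raw:
            cls = {"phantom": PhantomSpec, "train_cfg": TrainConfig,
                   "fill": FillConstants, "ssim": SSIMConstants}[key]
            kw[key] = cls(**raw.pop(key))
    kw.update(raw)
    return ExperimentConfig(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full protocol; returns the manifest dict (also written to
    out_dir/manifest.json). On a stage failure a partial manifest naming
    the failed stage is still written."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
                      "seed": cfg.seed, "files": {}, "failed_stage": None}
    (out / "config.json").write_text(cfg.to_json())
    manifest["files"]["config.json"] = None

    def declare(relpath):
        manifest["files"][str(relpath)] = _sha256(out / relpath)

    def stage(name):
        log.info("stage=%s seed=%s config=%s", name, cfg.seed,
                 manifest["config_hash"][:12])
        return time.time()

    try:
        t0 = stage("phantoms")
        data = generate_dataset(cfg.phantom, cfg.n_phantoms,
                                stage_seed(cfg.seed, "phantoms"))
        mask = make_truncation_mask(cfg.grid_size, cfg.left_cols, cfg.right_cols)
        n_train = cfg.n_phantoms - cfg.n_test
        train_set = [(s.to_normalized01(), mask) for s, _ in data[:n_train]]
        test_set = data[n_train:]
        log.info("stage=phantoms done wall=%.1fs", time.time() - t0)

        t0 = stage("train")
        spec = NetworkSpec(base_channels=cfg.base_channels)
        state = train(train_set, spec, cfg.train_cfg,
                      checkpoint_path=str(out / "model.npz"))
        write_loss_csv(state, out / "loss_history.csv")
        declare("loss_history.csv")
        declare("model.npz")
        log.info("stage=train done wall=%.1fs", time.time() - t0)

        t0 = stage("complete")
        rows = []
        gamma_rows = []
        per_method_gammas = {"dl": [], "pbo": [], "hybrid": []}
        for i, (truth, _) in enumerate(test_set):
            truncated = apply_mask(truth, mask)
            outline = extract_outline(truth, cfg.fill)
            comp = complete(state.model, truncated.to_normalized01(), mask)
            dl_slice = CTSlice(np.round(comp.composited * 255).astype(np.uint8),
                               truth.spacing, "gray8")
            pbo_slice = pbo_fill(truncated, mask, outline, cfg.fill)
            hyb_slice = hybrid_fuse(comp, mask, outline, cfg.fill,
                                    spacing=truth.spacing)
            methods = {"zerofill": truncated, "dl": dl_slice,
                       "pbo": pbo_slice, "hybrid": hyb_slice}
            case = f"case{i:03d}"
            truth.save_png(out / f"{case}_truth.png")
            declare(f"{case}_truth.png")
            save_outline_png(out / f"{case}_outline.png", outline)
            declare(f"{case}_outline.png")
            for name, sl in methods.items():
                sl.save_png(out / f"{case}_{name}.png")
                declare(f"{case}_{name}.png")
                whole, gen = evaluate_pair(truth, sl, mask, cfg.ssim)
                for rep in (whole, gen):
                    rows.append([case, name, rep.region, rep.ssim, rep.rmse,
                                 rep.psnr, rep.n_pixels])

            center = (cfg.grid_size // 2, cfg.grid_size // 2)
            ref_dose = toy_arc_dose(truth, center, cfg.target_diameter_mm,
                                    cfg.prescription_cGy, cfg.n_beams,
                                    water_gray=cfg.fill.water_gray)
            write_dose(out / f"{case}_dose_truth.txt", ref_dose)
            declare(f"{case}_dose_truth.txt")
            for name in ("dl", "pbo", "hybrid"):
                # the reference plan (same monitor units) recomputed on the
                # completed image
                ev = toy_arc_dose(methods[name], center, cfg.target_diameter_mm,
                                  cfg.prescription_cGy, cfg.n_beams,
                                  water_gray=cfg.fill.water_gray,
                                  scale=ref_dose.meta["scale"])
                res = gamma_suite(ref_dose, ev, cfg.gamma_grid)
                per_method_gammas[name].append(res)
                for ((dd, dta), th), r in res.items():
                    gamma_rows.append([case, name, f"{dd:g}%/{dta:g}mm", th,
                                       r.pass_rate, r.n_evaluated])
        log.info("stage=complete done wall=%.1fs", time.time() - t0)

        with open(out / "metrics.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["case", "method", "region", "ssim", "rmse", "psnr",
                        "n_pixels"])
            w.writerows(rows)
        declare("metrics.csv")

        with open(out / "gamma.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["case", "method", "criterion", "threshold_percent",
                        "pass_rate", "n_evaluated"])
            w.writerows(gamma_rows)
        declare("gamma.csv")

        summary = {m: {f"{dd:g}%/{dta:g}mm@{th:g}%": v
                       for ((dd, dta), th), v in summarize_pass_rates(g).items()}
                   for m, g in per_method_gammas.items() if g}
        (out / "gamma_summary.json").write_text(json.dumps(summary, indent=1))
        declare("gamma_summary.json")
        manifest["gamma_summary"] = summary
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
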