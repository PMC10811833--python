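"""Adversarial training of the completion network.

Each joint iteration updates the discriminators first (to separate real
slices from completed ones) and then the completion network, whose total
loss is the pixel-wise L2 reconstruction loss over the missing region plus
an adversarial term weighted by alpha (default 4e-4). Training is phased:
an initial reconstruction-only phase (Tc), a discriminator-only phase (Td),
then joint alternation (Tjoint) — the pure-joint schedule (0, 0, epochs) is
also supported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import CTSlice
from .network import (
    CompletionModel,
    ContextDiscriminator,
    NetworkSpec,
    build_completion,
    build_discriminators,
    composite,
    extract_local_crops,
    local_patch_bounds,
)
from .nn import Adam
from .preprocess import TruncationMask

__all__ = ["TrainConfig", "TrainState", "reconstruction_loss",
           "adversarial_losses", "train", "write_loss_csv"]

_EPS = 1e-7  # clamp for log-loss at saturated discriminator scores


@dataclass
class TrainConfig:
    epochs: int = 60
    alpha: float = 0.0004
    batch_size: int = 2
    learning_rate: float = 1e-3
    seed: int = 0
    phase_schedule: tuple[int, int, int] | None = None  # (Tc, Td, Tjoint)

    def phases(self) -> tuple[int, int, int]:
        if self.phase_schedule is not None:
            tc, td, tj = self.phase_schedule
            if tc + td + tj != self.epochs:
                raise ValueError("phase_schedule must sum to epochs")
            return tc, td, tj
        tc = int(round(0.20 * self.epochs))
        td = int(round(0.05 * self.epochs))
        return tc, td, self.epochs - tc - td

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.phases()


@dataclass
class TrainState:
    epoch: int
    g_recon: list = field(default_factory=list)  # per-epoch mean
    g_adv: list = field(default_factory=list)  # nan outside joint phase
    d_loss: list = field(default_factory=list)  # nan outside Td/joint
    model: CompletionModel | None = None
    discriminator: ContextDiscriminator | None = None
    checkpoint: str | None = None


def reconstruction_loss(raw: np.ndarray, truth: np.ndarray, mask: TruncationMask) -> float:
    """Mean squared error over the missing region only (0 if nothing is
    missing). Accepts single images (H,W) or batches (B,H,W,1)."""
    missing = mask.missing
    if raw.ndim == 2:
        raw = raw[None, :, :, None]
        truth = truth[None, :, :, None]
    n_miss = int(missing.sum())
    if n_miss == 0:
        return 0.0
    diff = (raw - truth)[:, missing, :]
    return float(np.mean(diff.astype(np.float64) ** 2))


def adversarial_losses(disc_score_real, disc_score_fake) -> tuple[float, float]:
    """Min–max GAN losses, averaged over the batch.

    d_loss = -[log D(real) + log(1 - D(fake))],  g_loss = -log D(fake);
    scores are clamped to [eps, 1-eps] to avoid infinities.
    """
    sr = np.clip(np.asarray(disc_score_real, dtype=np.float64), _EPS, 1 - _EPS)
    sf = np.clip(np.asarray(disc_score_fake, dtype=np.float64), _EPS, 1 - _EPS)
    d_loss = float(np.mean(-(np.log(sr) + np.log(1.0 - sf))))
    g_loss = float(np.mean(-np.log(sf)))
    return d_loss, g_loss


def _as_batch(slices: list[CTSlice]) -> np.ndarray:
    return np.stack([s.pixels.astype(np.float32) for s in slices])[..., None]


def _scatter_crop_grad(dimages: np.ndarray, dcrops: np.ndarray, mask: TruncationMask):
    for (a, b), dc in zip(local_patch_bounds(mask), dcrops):
        dimages[:, :, a:b, :] += dc
    return dimages


def train(dataset, net_spec: NetworkSpec, cfg: TrainConfig,
          checkpoint_path: str | None = None) -> TrainState:
    """Train on a list of (truth CTSlice in normalized01, TruncationMask)
    pairs sharing one mask geometry. Deterministic for a fixed seed with a
    single-threaded BLAS backend."""
    cfg.validate()
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    for s, _ in dataset:
        if s.unit != "normalized01":
            raise ValueError("training slices must be normalized01")
    mask = dataset[0][1]
    for _, m in dataset:
        if (m.left_cols, m.right_cols, m.grid_size) != (mask.left_cols, mask.right_cols, mask.grid_size):
            raise ValueError("all training masks must share one geometry")

    rng = np.random.default_rng(cfg.seed)
    n = mask.grid_size
    gen = build_completion(net_spec, rng=rng)
    disc = build_discriminators(net_spec, (n, n), mask, rng=rng)
    opt_g = Adam(gen.params(), lr=cfg.learning_rate)
    opt_d = Adam(disc.params(), lr=cfg.learning_rate)

    truths = _as_batch([s for s, _ in dataset])
    missing = mask.missing.astype(np.float32)[None, :, :, None]
    tc, td, tj = cfg.phases()
    state = TrainState(epoch=0, model=gen, discriminator=disc)

    n_miss = float(mask.missing.sum())
    for epoch in range(cfg.epochs):
        phase = "c" if epoch < tc else ("d" if epoch < tc + td else "joint")
        order = rng.permutation(len(dataset))
        ep_recon, ep_adv, ep_d = [], [], []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            truth = truths[idx]
            B = truth.shape[0]
            masked = truth * (1.0 - missing)

            raw = comp = None
            if phase != "c":
                # ---- discriminator step (or pure-d phase) -------------
                raw = gen.forward(masked, np.broadcast_to(missing, truth.shape))
                comp = composite(raw, truth, missing)
                disc.zero_grad()
                s_real = disc.forward(truth, extract_local_crops(truth, mask))
                sr = np.clip(s_real, _EPS, 1 - _EPS)
                disc.backward((-1.0 / sr / B).astype(np.float32))
                s_fake = disc.forward(comp, extract_local_crops(comp, mask))
                sf = np.clip(s_fake, _EPS, 1 - _EPS)
                disc.backward((1.0 / (1.0 - sf) / B).astype(np.float32))
                d_loss, _ = adversarial_losses(s_real, s_fake)
                ep_d.append(d_loss)
                if np.isfinite(d_loss):
                    opt_d.step()
                else:
                    raise RuntimeError(
                        f"non-finite discriminator loss at epoch {epoch}; "
                        f"history={state.d_loss}"
                    )

            if phase == "d":
                continue

            # ---- generator step ----------------------------------------
            raw = gen.forward(masked, np.broadcast_to(missing, truth.shape))
            recon = reconstruction_loss(raw, truth, mask)
            ep_recon.append(recon)
            d_raw = (2.0 * (raw - truth) * missing / (n_miss * B)).astype(np.float32)

            if phase == "joint":
                comp = composite(raw, truth, missing)
                disc.zero_grad()
                s_fake = disc.forward(comp, extract_local_crops(comp, mask))
                sf = np.clip(s_fake, _EPS, 1 - _EPS)
                _, g_adv = adversarial_losses(np.ones_like(sf), s_fake)
                ep_adv.append(g_adv)
                dscore = (-cfg.alpha / sf / B).astype(np.float32)
                dimg, dcrops = disc.backward(dscore)
                dcomp = _scatter_crop_grad(dimg, dcrops, mask)
                d_raw = d_raw + dcomp * missing
                disc.zero_grad()  # adversarial grads must not leak into opt_d

            total = recon + (cfg.alpha * ep_adv[-1] if phase == "joint" else 0.0)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite generator loss at epoch {epoch}; "
                    f"history={state.g_recon}"
                )
            gen.zero_grad()
            gen.backward(d_raw)
            opt_g.step()

        state.epoch = epoch + 1
        state.g_recon.append(float(np.mean(ep_recon)) if ep_recon else float("nan"))
        state.g_adv.append(float(np.mean(ep_adv)) if ep_adv else float("nan"))
        state.d_loss.append(float(np.mean(ep_d)) if ep_d else float("nan"))

    if checkpoint_path is not None:
        from .network import save_checkpoint

        save_checkpoint(checkpoint_path, gen, disc)
        state.checkpoint = str(checkpoint_path)
    return state


def write_loss_csv(state: TrainState, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "g_recon", "g_adv", "d_loss"])
        for i, (r, a, d) in enumerate(zip(state.g_recon, state.g_adv, state.d_loss), 1):
            w.writerow([i, r, a, d])
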