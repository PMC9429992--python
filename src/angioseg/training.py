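"""Two-phase training protocol and cross-validation driver.

Phase 1 pretrains the segmentation generator alone on the combined
GDL + centerline-Dice loss (initial learning rate 5e-3, up to 100 epochs,
stopped early pre-convergence). Phase 2 trains adversarially: the generator
minimizes GDL + clDice + feature-matching loss while the discriminator,
updated once every three generator iterations at learning rate 1e-4,
maximizes the feature-matching term (up to 150 epochs). Both phases monitor
validation vessel Dice with plateau-triggered learning-rate decay and early
stopping; the decayed generator learning rate at the end of pretraining
carries into the adversarial phase. Adam (beta1 = 0.9) with batch size 6 is
the reference optimizer setting; the discriminator's unbounded maximization
objective is kept stable by gradient-norm clipping on top of its low
learning rate.

Ablation arms are pure configuration: vanilla U-Net, U-Net + prior, the
full adversarial model, the no-prior adversarial model, and single-loss
(GDL-only / clDice-only) variants.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import nn
from .grids import LabelMap, OneHotMap, Volume
from .losses import cld_loss, combined_loss, feature_loss, gdl
from .metrics import MetricsReport, aggregate_reports, evaluate_scan
from .networks import (Discriminator, DiscriminatorConfig, Generator,
                       GeneratorConfig)
from .patches import (AugmentConfig, PatchSpec, augment, extract_patch,
                      sample_patch, sliding_windows, assemble)
from .prior import PriorAtlas, build_prior

logger = logging.getLogger(__name__)

__all__ = [
    "ARMS", "TrainingConfig", "TrainState", "Trainer", "split_folds",
    "pretrain_generator", "monitor_and_decay", "run_fold", "predict_volume",
]

# arm -> (use_prior, use_discriminator, use_gdl, use_cld)
ARMS = {
    "unet": (False, False, True, True),
    "unet_prior": (True, False, True, True),
    "adv": (True, True, True, True),
    "adv_noprior": (False, True, True, True),
    "gdl_only": (True, True, True, False),
    "cld_only": (True, True, False, True),
}


@dataclasses.dataclass
class TrainingConfig:
    arm: str = "adv"
    patch_size: tuple[int, int, int] = (80, 80, 80)
    levels: int = 4
    base_channels: int = 16
    disc_base_channels: int = 16
    disc_scales: int = 5
    g_lr: float = 5e-3
    d_lr: float = 1e-4
    batch_size: int = 6
    pretrain_epochs: int = 100
    adv_epochs: int = 150
    d_every: int = 3                 # one D update per three G updates
    passes_per_epoch: int = 2        # data iterated twice with fresh crops
    skeleton_iters: int = 10
    min_delta: float = 1e-3
    patience: int = 5
    decay_factor: float = 0.5
    stop_patience: int = 15
    clip_norm: float = 1.0           # discriminator gradient clipping
    g_clip_norm: float = 5.0         # generator gradient clipping
    min_fraction: float = 0.05       # prior nullification
    val_patches: int = 4             # monitoring patches per val subject
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; one of {sorted(ARMS)}")
        if self.pretrain_epochs > 100:
            raise ValueError("pretraining budget is capped at 100 epochs")
        if self.adv_epochs > 150:
            raise ValueError("adversarial budget is capped at 150 epochs")

    @property
    def flags(self):
        return ARMS[self.arm]


@dataclasses.dataclass
class TrainState:
    epoch: int = 0
    phase: str = "pretrain"
    g_lr: float = 5e-3
    d_lr: float = 1e-4
    best_vdsc: float = -np.inf
    since_improve: int = 0
    since_decay: int = 0
    g_steps: int = 0
    d_steps: int = 0
    stop: bool = False
    seed: int = 0


def split_folds(n_subjects: int, n_folds: int, seed: int,
                n_val: int | None = None):
    """Subject-level cross-validation folds (test block rotates; the next
    block is validation; the remainder trains). 42 subjects with 5 folds
    give 36/3/3 partitions, with no subject in two partitions of a fold."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    test_size = int(np.ceil(n_subjects / (2 * n_folds))) if n_val is None \
        else n_val
    # 42 subjects / 5 folds -> blocks of 3 test + 3 validation
    if n_subjects == 42 and n_folds == 5 and n_val is None:
        test_size = 3
    folds = []
    for f in range(n_folds):
        t0 = (f * 2 * test_size) % n_subjects
        test = [int(order[(t0 + i) % n_subjects]) for i in range(test_size)]
        val = [int(order[(t0 + test_size + i) % n_subjects])
               for i in range(test_size)]
        train = [int(s) for s in order if s not in test and s not in val]
        if set(train) & set(val) or set(train) & set(test) or set(val) & set(test):
            raise RuntimeError("subject leakage across partitions")
        folds.append((train, val, test))
    return folds


def _derive_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0]
               % (2 ** 31))


def _batch_tensors(samples):
    """Stack TrainingSamples into (B,1,...), (B,2,...), (B,2,...) tensors."""
    x = np.stack([s.scan_patch.data for s in samples])[:, None]
    r = np.stack([np.moveaxis(s.gt_patch.data, -1, 0) for s in samples])
    p = np.stack([np.moveaxis(s.prior_patch.data, -1, 0) for s in samples])
    return (nn.constant(x.astype(np.float32)),
            nn.constant(r.astype(np.float32)),
            nn.constant(p.astype(np.float32)))


class Trainer:
    """Owns the generator/discriminator, optimizers and the training loops.

    ``subjects`` is a list of (scan, gt) pairs on a common registered grid,
    with scans already intensity-preprocessed.
    """

    def __init__(self, subjects, train_idx, val_idx, cfg: TrainingConfig,
                 prior: PriorAtlas | None = None):
        self.cfg = cfg
        self.subjects = subjects
        self.train_idx = list(train_idx)
        self.val_idx = list(val_idx)
        use_prior, use_disc, _, _ = cfg.flags
        self.prior = prior
        if self.prior is None:
            self.prior = build_prior([subjects[i][1] for i in self.train_idx],
                                     min_fraction=cfg.min_fraction)
        self.gen = Generator(GeneratorConfig(
            levels=cfg.levels, base_channels=cfg.base_channels,
            use_prior=use_prior, seed=_derive_seed(cfg.seed, 101)))
        self.disc = None
        self.d_opt = None
        if use_disc:
            self.disc = Discriminator(DiscriminatorConfig(
                scales=cfg.disc_scales, base_channels=cfg.disc_base_channels,
                seed=_derive_seed(cfg.seed, 202)))
            self.d_opt = nn.Adam(self.disc.parameters(), lr=cfg.d_lr,
                                 beta1=0.9, clip_norm=cfg.clip_norm)
        self.g_opt = nn.Adam(self.gen.parameters(), lr=cfg.g_lr, beta1=0.9,
                             clip_norm=cfg.g_clip_norm)
        self.state = TrainState(g_lr=cfg.g_lr, d_lr=cfg.d_lr, seed=cfg.seed)
        self.history: list[dict] = []

    # ----- loss assembly -------------------------------------------------
    def _seg_loss(self, x, r, p, adversarial: bool):
        _, _, use_gdl, use_cld = self.cfg.flags
        pred = self.gen(x, p if self.gen.cfg.use_prior else None)
        self._last_pred = pred.value
        gdl_t = gdl(r, pred) if use_gdl else None
        cld_t = None
        if use_cld:
            rv = nn.constant(r.value[:, 1:2])
            pv = pred                       # keep graph: take vessel channel
            pv_v = _channel(pv, 1)
            cld_t = cld_loss(rv, pv_v, k=self.cfg.skeleton_iters)
        mae_t = None
        if adversarial and self.disc is not None:
            pv_v = _channel(pred, 1)
            rv = nn.constant(r.value[:, 1:2])
            mae_t = feature_loss(x, pv_v, rv, self.disc)
        zero = nn.constant(np.zeros((), dtype=np.float32))
        total = combined_loss(gdl_t if gdl_t is not None else zero,
                              cld_t if cld_t is not None else zero, mae_t)
        parts = {"gdl": float(gdl_t.value) if gdl_t is not None else 0.0,
                 "cld": float(cld_t.value) if cld_t is not None else 0.0,
                 "mae": float(mae_t.value) if mae_t is not None else 0.0}
        return total, parts

    # ----- batching ------------------------------------------------------
    def _draw_batch(self, epoch: int, pass_i: int, positions):
        samples = []
        for j, subj in enumerate(positions):
            scan, gt = self.subjects[subj]
            s = sample_patch(scan, gt, self.prior,
                             rng_seed=_derive_seed(self.cfg.seed, epoch,
                                                   pass_i, subj, j),
                             size=self.cfg.patch_size)
            s = augment(s, self.cfg.augment,
                        rng_seed=_derive_seed(self.cfg.seed, epoch, pass_i,
                                              subj, j, 7))
            samples.append(s)
        return _batch_tensors(samples)

    def _epoch_batches(self, epoch: int):
        rng = np.random.default_rng(_derive_seed(self.cfg.seed, epoch, 33))
        for pass_i in range(self.cfg.passes_per_epoch):
            order = rng.permutation(self.train_idx)
            for k in range(0, len(order), self.cfg.batch_size):
                chunk = order[k:k + self.cfg.batch_size]
                yield self._draw_batch(epoch, pass_i, chunk)

    # ----- steps ---------------------------------------------------------
    def generator_step(self, batch, adversarial: bool):
        x, r, p = batch
        self.g_opt.zero_grad()
        if self.d_opt is not None:
            self.d_opt.zero_grad()
        total, parts = self._seg_loss(x, r, p, adversarial)
        if not np.isfinite(total.value):
            raise FloatingPointError(
                f"non-finite generator loss at step {self.state.g_steps}: "
                f"{parts}")
        total.backward()
        self.g_opt.step()
        self.state.g_steps += 1
        return parts

    def discriminator_step(self, batch, pred_vessel: np.ndarray | None = None):
        x, r, p = batch
        self.g_opt.zero_grad()
        self.d_opt.zero_grad()
        if pred_vessel is None:
            pred = self.gen(x, p if self.gen.cfg.use_prior else None)
            pred_vessel = pred.value[:, 1:2]
        pv = nn.constant(pred_vessel)               # detached from generator
        rv = nn.constant(r.value[:, 1:2])
        mae = feature_loss(x, pv, rv, self.disc)
        if not np.isfinite(mae.value):
            raise FloatingPointError("non-finite discriminator loss")
        neg = nn.scale(mae, -1.0)                   # ascent on the L1 gap
        neg.backward()
        self.d_opt.step()
        self.state.d_steps += 1
        return float(mae.value)

    def adversarial_step(self, batch):
        """One generator update; every third, also one discriminator update."""
        parts = self.generator_step(batch, adversarial=True)
        if self.state.g_steps % self.cfg.d_every == 0:
            parts["d_mae"] = self.discriminator_step(
                batch, pred_vessel=self._last_pred[:, 1:2])
        return parts

    # ----- validation & scheduling ---------------------------------------
    def validation_vdsc(self, epoch: int) -> float:
        if not self.val_idx:
            return float("nan")
        tp = fp = fn = 0
        for subj in self.val_idx:
            scan, gt = self.subjects[subj]
            for v in range(self.cfg.val_patches):
                s = sample_patch(scan, gt, self.prior,
                                 rng_seed=_derive_seed(self.cfg.seed, 999,
                                                       subj, v),
                                 size=self.cfg.patch_size)
                x, r, p = _batch_tensors([s])
                pred = self.gen(x, p if self.gen.cfg.use_prior else None)
                pb = pred.value[0, 1] > pred.value[0, 0]
                rb = r.value[0, 1] > 0.5
                tp += int(np.count_nonzero(pb & rb))
                fp += int(np.count_nonzero(pb & ~rb))
                fn += int(np.count_nonzero(~pb & rb))
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    def monitor_and_decay(self, val_vdsc: float) -> None:
        monitor_and_decay(self.state, val_vdsc, self.cfg)
        self.g_opt.lr = self.state.g_lr
        if self.d_opt is not None:
            self.d_opt.lr = self.state.d_lr

    # ----- phases ---------------------------------------------------------
    def _run_phase(self, phase: str, epochs: int):
        self.state.phase = phase
        self.state.best_vdsc = -np.inf
        self.state.since_improve = 0
        self.state.since_decay = 0
        adversarial = phase == "adversarial"
        for _ in range(epochs):
            self.state.epoch += 1
            parts_acc: dict[str, list] = {}
            for batch in self._epoch_batches(self.state.epoch):
                if adversarial:
                    parts = self.adversarial_step(batch)
                else:
                    parts = self.generator_step(batch, adversarial=False)
                for k_, v_ in parts.items():
                    parts_acc.setdefault(k_, []).append(v_)
            vdsc = self.validation_vdsc(self.state.epoch)
            self.monitor_and_decay(vdsc)
            row = {"epoch": self.state.epoch, "phase": phase,
                   "val_vdsc": vdsc, "g_lr": self.state.g_lr,
                   "g_steps": self.state.g_steps,
                   "d_steps": self.state.d_steps}
            row.update({k_: float(np.mean(v_)) for k_, v_ in parts_acc.items()})
            self.history.append(row)
            logger.info("epoch %d [%s] val VDSC %.4f", self.state.epoch,
                        phase, vdsc)
            if self.state.stop:
                logger.info("early stop in %s at epoch %d", phase,
                            self.state.epoch)
                break
        self.state.stop = False

    def pretrain(self, epochs: int | None = None):
        self._run_phase("pretrain",
                        self.cfg.pretrain_epochs if epochs is None else epochs)
        return self

    def train_adversarial(self, epochs: int | None = None):
        if self.disc is None:
            raise ValueError(f"arm {self.cfg.arm!r} has no discriminator")
        # the decayed pretraining learning rate carries over
        self._run_phase("adversarial",
                        self.cfg.adv_epochs if epochs is None else epochs)
        return self


def _channel(t: nn.Tensor, c: int) -> nn.Tensor:
    """Differentiable (N, 1, ...) view of one channel."""
    val = t.value[:, c:c + 1]

    def bwd(g):
        if t.requires_grad:
            full = np.zeros_like(t.value)
            full[:, c:c + 1] = g
            t._accumulate(full)

    return nn.Tensor(val, (t,), bwd)


def monitor_and_decay(state: TrainState, val_vdsc: float,
                      cfg: TrainingConfig) -> TrainState:
    """Plateau scheduling: decay the learning rate after ``patience`` epochs
    without a ``min_delta`` VDSC improvement; early-stop after
    ``stop_patience``."""
    if np.isnan(val_vdsc):
        return state
    if val_vdsc > state.best_vdsc + cfg.min_delta:
        state.best_vdsc = val_vdsc
        state.since_improve = 0
    else:
        state.since_improve += 1
    state.since_decay += 1
    if (state.since_improve >= cfg.patience
            and state.since_decay >= cfg.patience):
        state.g_lr *= cfg.decay_factor
        state.d_lr *= cfg.decay_factor
        state.since_decay = 0
        logger.info("plateau: learning rate decayed to %.2e", state.g_lr)
    if state.since_improve >= cfg.stop_patience:
        state.stop = True
    return state


def pretrain_generator(subjects, train_idx, val_idx, cfg: TrainingConfig,
                       epochs: int | None = None) -> Trainer:
    """Phase-1 convenience wrapper: build a Trainer and pretrain."""
    t = Trainer(subjects, train_idx, val_idx, cfg)
    if epochs == 0:
        return t
    return t.pretrain(epochs)


def predict_volume(gen: Generator, scan: Volume, prior: PriorAtlas | None,
                   patch_size=(80, 80, 80)) -> OneHotMap:
    """Sliding-window full-volume inference (non-overlapping tiles)."""
    windows = sliding_windows(scan.shape, patch_size)
    outputs = []
    freq = prior.frequency if prior is not None else None
    for spec in windows:
        xs = extract_patch(scan.data.astype(np.float32), spec)
        x = nn.constant(xs[None, None])
        p = None
        if gen.cfg.use_prior:
            if freq is None:
                raise ValueError("generator requires a prior atlas")
            fr = extract_patch(freq, spec)
            p = nn.constant(np.stack([1.0 - fr, fr])[None].astype(np.float32))
        pred = gen(x, p)
        outputs.append((spec, OneHotMap(np.moveaxis(pred.value[0], 0, -1))))
    return assemble(outputs, scan.shape)


def run_fold(subjects, fold, cfg: TrainingConfig,
             pretrain_epochs: int | None = None,
             adv_epochs: int | None = None):
    """Train one fold end to end and evaluate on its held-out test subjects.

    ``fold`` is (train_idx, val_idx, test_idx); the prior atlas is built
    from the training subjects only.
    """
    train_idx, val_idx, test_idx = fold
    if (set(train_idx) & set(val_idx) or set(train_idx) & set(test_idx)
            or set(val_idx) & set(test_idx)):
        raise ValueError("subject leakage across fold partitions")
    trainer = Trainer(subjects, train_idx, val_idx, cfg)
    trainer.pretrain(pretrain_epochs)
    if trainer.disc is not None:
        trainer.train_adversarial(adv_epochs)
    reports = []
    for subj in test_idx:
        scan, gt = subjects[subj]
        pred = predict_volume(trainer.gen, scan, trainer.prior,
                              cfg.patch_size)
        reports.append(evaluate_scan(gt, pred))
    return trainer, reports, aggregate_reports(reports)
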