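"""Training protocol: folds, plateau scheduling, update ratio, descent."""

import numpy as np
import pytest

from angioseg.grids import preprocess_intensity
from angioseg.phantom import PhantomSpec, generate_cohort
from angioseg.prior import build_prior
from angioseg.training import (ARMS, Trainer, TrainingConfig, TrainState,
                               monitor_and_decay, predict_volume, run_fold,
                               split_folds)

TINY = dict(patch_size=(16, 16, 16), levels=3, base_channels=2,
            disc_base_channels=2, disc_scales=3, batch_size=2,
            skeleton_iters=2, val_patches=1)


@pytest.fixture(scope="module")
def tiny_subjects():
    spec = PhantomSpec(shape=(32, 32, 32), n_trees=2,
                       radius_range=(1.2, 2.5), seed=21)
    cohort = generate_cohort(6, spec, shared_geometry=0.5)
    return [(preprocess_intensity(s), g) for s, g, _ in cohort]


class TestSplitFolds:
    def test_cross_validation_partition_sizes(self):
        folds = split_folds(42, 5, seed=0)
        assert len(folds) == 5
        for train, val, test in folds:
            assert (len(train), len(val), len(test)) == (36, 3, 3)
            assert not set(train) & set(val)
            assert not set(train) & set(test)
            assert not set(val) & set(test)

    def test_deterministic(self):
        assert split_folds(42, 5, seed=7) == split_folds(42, 5, seed=7)
        assert split_folds(42, 5, seed=7) != split_folds(42, 5, seed=8)


class TestMonitorAndDecay:
    def _cfg(self):
        return TrainingConfig(patience=3, stop_patience=6, min_delta=1e-3,
                              decay_factor=0.5)

    def test_improving_sequence_never_decays(self):
        cfg = self._cfg()
        state = TrainState(g_lr=5e-3, d_lr=1e-4)
        for v in np.linspace(0.1, 0.9, 10):
            monitor_and_decay(state, float(v), cfg)
        assert state.g_lr == 5e-3 and not state.stop

    def test_flat_sequence_single_decay(self):
        cfg = self._cfg()
        state = TrainState(g_lr=5e-3, d_lr=1e-4)
        monitor_and_decay(state, 0.5, cfg)
        for _ in range(cfg.patience + 1):
            monitor_and_decay(state, 0.5, cfg)
        assert state.g_lr == pytest.approx(2.5e-3)  # exactly one decay

    def test_persistent_plateau_early_stops(self):
        cfg = self._cfg()
        state = TrainState(g_lr=5e-3, d_lr=1e-4)
        epochs = 0
        monitor_and_decay(state, 0.5, cfg)
        while not state.stop and epochs < 150:
            monitor_and_decay(state, 0.5, cfg)
            epochs += 1
        assert state.stop and epochs < 150

    def test_epoch_budgets_enforced(self):
        with pytest.raises(ValueError, match="100"):
            TrainingConfig(pretrain_epochs=101)
        with pytest.raises(ValueError, match="150"):
            TrainingConfig(adv_epochs=151)


class TestSchedule:
    def test_three_to_one_update_ratio(self, tiny_subjects):
        cfg = TrainingConfig(arm="adv", seed=0, **TINY)
        tr = Trainer(tiny_subjects, [0, 1, 2, 3], [4], cfg)
        batches = tr._epoch_batches(1)
        batch = next(batches)
        for _ in range(9):
            tr.adversarial_step(batch)
        assert tr.state.g_steps == 9
        assert tr.state.d_steps == 3

    def test_arm_without_discriminator_rejects_adversarial(self,
                                                           tiny_subjects):
        cfg = TrainingConfig(arm="unet", seed=0, **TINY)
        tr = Trainer(tiny_subjects, [0, 1], [2], cfg)
        with pytest.raises(ValueError, match="discriminator"):
            tr.train_adversarial(1)

    def test_reference_hyperparameters(self):
        cfg = TrainingConfig()
        assert cfg.g_lr == 5e-3
        assert cfg.d_lr == 1e-4
        assert cfg.batch_size == 6
        assert cfg.d_every == 3
        assert set(ARMS) == {"unet", "unet_prior", "adv", "adv_noprior",
                             "gdl_only", "cld_only"}


class TestTrainingRuns:
    def test_zero_epoch_budget_leaves_weights_untouched(self, tiny_subjects):
        cfg = TrainingConfig(arm="unet", seed=1, **TINY)
        tr = Trainer(tiny_subjects, [0, 1], [2], cfg)
        before = [p.value.copy() for p in tr.gen.parameters()]
        tr.pretrain(0)
        for b, p in zip(before, tr.gen.parameters()):
            np.testing.assert_array_equal(b, p.value)

    def test_loss_descends_over_epochs(self, tiny_subjects):
        # descent measured on a fixed probe batch, before vs after training
        cfg = TrainingConfig(arm="unet", seed=2, patch_size=(32, 32, 32),
                             levels=3, base_channels=2, batch_size=2,
                             skeleton_iters=3, val_patches=1)
        tr = Trainer(tiny_subjects, [0, 1, 2, 3], [4], cfg)
        probe = next(tr._epoch_batches(777))
        before, _ = tr._seg_loss(*probe, adversarial=False)
        tr.pretrain(5)
        after, _ = tr._seg_loss(*probe, adversarial=False)
        assert float(after.value) < float(before.value)
        assert tr.history[4]["cld"] < tr.history[0]["cld"]

    def test_seeded_runs_reproduce_epoch_losses(self, tiny_subjects):
        cfg = TrainingConfig(arm="unet_prior", seed=11, **TINY)
        a = Trainer(tiny_subjects, [0, 1, 2], [3], cfg).pretrain(1)
        b = Trainer(tiny_subjects, [0, 1, 2], [3], cfg).pretrain(1)
        assert a.history[0]["gdl"] == b.history[0]["gdl"]
        assert a.history[0]["cld"] == b.history[0]["cld"]
        assert a.history[0]["val_vdsc"] == b.history[0]["val_vdsc"]

    def test_prior_built_from_training_subjects_only(self, tiny_subjects):
        cfg = TrainingConfig(arm="unet_prior", seed=0, **TINY)
        tr = Trainer(tiny_subjects, [0, 2, 4], [1], cfg)
        expect = build_prior([tiny_subjects[i][1] for i in (0, 2, 4)],
                             min_fraction=cfg.min_fraction)
        np.testing.assert_array_equal(tr.prior.counts, expect.counts)

    def test_run_fold_rejects_subject_leakage(self, tiny_subjects):
        cfg = TrainingConfig(arm="unet", seed=0, **TINY)
        with pytest.raises(ValueError, match="leakage"):
            run_fold(tiny_subjects, ([0, 1], [1], [2]), cfg,
                     pretrain_epochs=0)

    def test_trained_gates_attend_to_vessel_regions(self):
        # after brief training, gate weight maps should be higher near
        # vessels than far from them (soft spatial attention at work)
        from scipy import ndimage
        from angioseg import nn
        spec = PhantomSpec(shape=(32, 32, 32), n_trees=3,
                           radius_range=(1.5, 2.5), seed=104)
        cohort = generate_cohort(8, spec, shared_geometry=0.7)
        subjects = [(preprocess_intensity(s), g) for s, g, _ in cohort]
        cfg = TrainingConfig(arm="unet_prior", seed=0,
                             patch_size=(32, 32, 32), base_channels=4,
                             batch_size=4, skeleton_iters=3, val_patches=1)
        tr = Trainer(subjects, list(range(6)), [6], cfg)
        tr.pretrain(6)
        scan, gt = subjects[7]
        x = nn.constant(scan.data[None, None].astype(np.float32))
        fr = tr.prior.frequency
        p = nn.constant(np.stack([1 - fr, fr])[None].astype(np.float32))
        tr.gen(x, p)
        near_full = ndimage.binary_dilation(gt.data, iterations=2)
        concentrated = 0
        for wmap in tr.gen.gate_weight_maps():
            w = wmap[0]
            factor = gt.shape[0] // w.shape[0]
            near = ndimage.zoom(near_full.astype(float), 1 / factor,
                                order=0) > 0 if factor > 1 else near_full
            if w[near].mean() > w[~near].mean():
                concentrated += 1
        assert concentrated >= 4  # of the 5 gates

    def test_predict_volume_visits_every_window_once(self, tiny_subjects):
        cfg = TrainingConfig(arm="unet", seed=0, **TINY)
        tr = Trainer(tiny_subjects, [0, 1], [2], cfg)
        scan, gt = tiny_subjects[5]
        out = predict_volume(tr.gen, scan, None, (16, 16, 16))
        assert out.shape == (32, 32, 32, 2)
        np.testing.assert_allclose(out.data.sum(axis=-1), 1.0, atol=1e-5)
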