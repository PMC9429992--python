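"""Patch sampling, joint augmentation and sliding-window tiling."""

import numpy as np
import pytest
from scipy import stats

from angioseg.grids import LabelMap, OneHotMap, Volume, to_one_hot
from angioseg.patches import (AugmentConfig, PatchSpec, assemble, augment,
                              brain_bbox, extract_patch, sample_patch,
                              sliding_windows)
from angioseg.prior import PriorAtlas


def _subject(shape, rng, spacing=(1, 1, 1)):
    scan = Volume(data=rng.uniform(0.1, 1.0, shape), spacing=spacing)
    gt = LabelMap(data=rng.integers(0, 2, shape).astype(np.uint8),
                  spacing=spacing)
    prior = PriorAtlas(counts=rng.integers(0, 4, shape).astype(np.int32),
                       n_subjects=3, min_fraction=0.05)
    return scan, gt, prior


class TestSamplePatch:
    def test_exact_fit_has_unique_origin(self, rng):
        scan, gt, prior = _subject((16, 16, 16), rng)
        for seed in range(5):
            s = sample_patch(scan, gt, prior, rng_seed=seed,
                             size=(16, 16, 16))
            assert s.spec.origin == (0, 0, 0)

    def test_seed_determinism(self, rng):
        scan, gt, prior = _subject((32, 32, 32), rng)
        a = sample_patch(scan, gt, prior, rng_seed=42, size=(16, 16, 16))
        b = sample_patch(scan, gt, prior, rng_seed=42, size=(16, 16, 16))
        assert a.spec == b.spec
        np.testing.assert_array_equal(a.scan_patch.data, b.scan_patch.data)

    def test_origin_distribution_uniform(self, rng):
        # bbox 24^3, patch 16^3 -> 9 valid origins per axis
        scan, gt, prior = _subject((24, 24, 24), rng)
        counts = np.zeros((3, 9))
        n = 3000
        for seed in range(n):
            s = sample_patch(scan, gt, prior, rng_seed=seed,
                             size=(16, 16, 16))
            for ax in range(3):
                counts[ax, s.spec.origin[ax]] += 1
        for ax in range(3):
            chi2 = ((counts[ax] - n / 9) ** 2 / (n / 9)).sum()
            assert chi2 < stats.chi2.ppf(0.999, df=8)

    def test_small_bbox_padded_with_warning(self, rng, caplog):
        scan, gt, prior = _subject((12, 16, 16), rng)
        with caplog.at_level("WARNING"):
            s = sample_patch(scan, gt, prior, rng_seed=0, size=(16, 16, 16))
        assert s.scan_patch.shape == (16, 16, 16)
        assert "padding" in caplog.text

    def test_patches_are_congruent(self, rng):
        scan, gt, prior = _subject((32, 32, 32), rng)
        s = sample_patch(scan, gt, prior, rng_seed=7, size=(16, 16, 16))
        sl = s.spec.slices
        np.testing.assert_array_equal(s.gt_patch.vessel, gt.data[sl])
        np.testing.assert_allclose(s.prior_patch.vessel,
                                   prior.frequency[sl], atol=1e-7)

    def test_brain_bbox_tight(self):
        data = np.zeros((20, 20, 20))
        data[3:9, 4:12, 5:6] = 1.0
        lo, hi = brain_bbox(Volume(data=data, spacing=(1, 1, 1)))
        assert tuple(lo) == (3, 4, 5) and tuple(hi) == (9, 12, 6)


class TestAugment:
    def _sample(self, rng, shape=(16, 16, 16)):
        scan, gt, prior = _subject(shape, rng)
        return sample_patch(scan, gt, prior, rng_seed=1, size=shape)

    def test_zero_probabilities_identity(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(p_flip=0, p_rotate=0, p_zoom=0, p_gamma=0)
        out = augment(s, cfg, rng_seed=5)
        np.testing.assert_array_equal(out.scan_patch.data, s.scan_patch.data)
        np.testing.assert_array_equal(out.gt_patch.data, s.gt_patch.data)

    def test_flip_is_involution(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(p_flip=1.0, p_rotate=0, p_zoom=0, p_gamma=0)
        twice = augment(augment(s, cfg, rng_seed=3), cfg, rng_seed=4)
        np.testing.assert_array_equal(twice.scan_patch.data,
                                      s.scan_patch.data)
        np.testing.assert_array_equal(twice.gt_patch.data, s.gt_patch.data)

    def test_zoom_scales_vessel_volume(self, rng):
        # centered sphere: zoom 1.1 multiplies its volume by ~1.1^3
        shape = (24, 24, 24)
        idx = np.indices(shape)
        sphere = ((idx - 11.5) ** 2).sum(axis=0) <= 36.0
        scan = Volume(data=sphere * 1.0, spacing=(1, 1, 1))
        gt = LabelMap(data=sphere.astype(np.uint8), spacing=(1, 1, 1))
        prior = PriorAtlas(counts=sphere.astype(np.int32), n_subjects=1,
                           min_fraction=0.0)
        s = sample_patch(scan, gt, prior, rng_seed=0, size=shape)
        cfg = AugmentConfig(p_flip=0, p_rotate=0, p_zoom=1.0,
                            zoom_range=(1.1, 1.1), p_gamma=0)
        out = augment(s, cfg, rng_seed=11)
        ratio = out.gt_patch.vessel.sum() / gt.data.sum()
        assert ratio == pytest.approx(1.1 ** 3, rel=0.10)

    def test_morphology_applied_jointly_intensity_scan_only(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(p_flip=1.0, p_rotate=0, p_zoom=0, p_gamma=1.0)
        out = augment(s, cfg, rng_seed=9)
        # GT and prior flipped exactly; scan flipped then noised
        np.testing.assert_array_equal(out.gt_patch.vessel,
                                      s.gt_patch.vessel[::-1])
        np.testing.assert_allclose(out.prior_patch.vessel,
                                   s.prior_patch.vessel[::-1], atol=1e-6)
        assert not np.allclose(out.scan_patch.data, s.scan_patch.data[::-1])

    def test_gt_stays_binary_after_rotation(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(p_flip=0, p_rotate=1.0, p_zoom=0, p_gamma=0)
        out = augment(s, cfg, rng_seed=21)
        assert set(np.unique(out.gt_patch.vessel)) <= {0.0, 1.0}
        np.testing.assert_allclose(out.gt_patch.data.sum(axis=-1), 1.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            AugmentConfig(p_flip=1.5)


class TestTiling:
    @pytest.mark.parametrize("shape,expected", [
        ((160, 160, 80), 4),
        ((80, 80, 80), 1),
        ((100, 100, 100), 8),   # ceil(100/80)^3 over the 160^3 padded grid
    ])
    def test_window_counts(self, shape, expected):
        assert len(sliding_windows(shape)) == expected

    def test_windows_disjoint_and_cover(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(1, 200, 3))
            size = tuple(rng.integers(1, 64, 3))
            specs = sliding_windows(shape, size)
            padded = tuple(int(np.ceil(s / w)) * w
                           for s, w in zip(shape, size))
            hits = np.zeros(padded, dtype=np.int16)
            for spec in specs:
                hits[spec.slices] += 1
            assert (hits == 1).all()

    def test_roundtrip_bit_exact(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(4, 64, 3))
            size = tuple(rng.integers(3, 24, 3))
            vessel = rng.random(shape).astype(np.float32)
            full = OneHotMap(np.stack([1 - vessel, vessel], axis=-1))
            outs = [(spec, OneHotMap(extract_patch(full.data, spec,
                                                   fill=0.0)))
                    for spec in sliding_windows(shape, size)]
            back = assemble(outs, shape)
            np.testing.assert_array_equal(back.data, full.data)

    def test_duplicate_window_rejected(self):
        full = to_one_hot(np.zeros((8, 8, 8), dtype=np.uint8))
        spec = sliding_windows((8, 8, 8), (8, 8, 8))[0]
        with pytest.raises(ValueError, match="duplicate"):
            assemble([(spec, full), (spec, full)], (8, 8, 8))

    def test_missing_window_rejected(self):
        specs = sliding_windows((16, 8, 8), (8, 8, 8))
        patch = to_one_hot(np.zeros((8, 8, 8), dtype=np.uint8))
        with pytest.raises(ValueError, match="missing"):
            assemble([(specs[0], patch)], (16, 8, 8))
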