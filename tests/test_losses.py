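"""GDL, soft-skeleton centerline Dice, masking and feature-matching losses."""

import numpy as np
import pytest

from angioseg import nn
from angioseg.losses import (cld_loss, cld_loss_value, combined_loss,
                             feature_loss, gdl, gdl_value, masked_input,
                             soft_skeleton_array, soft_skeletonize)


def _one_hot(vessel):
    vessel = np.asarray(vessel, dtype=np.float64)
    return np.stack([1.0 - vessel, vessel], axis=-1)


def _line(length=20, shape=(28, 28, 28)):
    m = np.zeros(shape)
    m[4:4 + length, 14, 14] = 1
    return m


class TestGeneralizedDice:
    def test_hand_evaluated_2x2x2_case(self):
        R = np.zeros((2, 2, 2))
        R[0, 0, 0] = R[1, 1, 1] = 1
        P = np.zeros((2, 2, 2))
        P[0, 0, 0] = 1
        # w_v = 1/4, w_b = 1/36; num = 2(1/4 + 6/36); den = 3/4 + 13/36
        assert gdl_value(_one_hot(R), _one_hot(P)) == pytest.approx(
            0.25, abs=1e-9)

    def test_perfect_and_inverse(self, rng):
        for _ in range(10):
            R = rng.integers(0, 2, (5, 5, 5)).astype(float)
            if R.sum() in (0, R.size):
                continue
            assert gdl_value(_one_hot(R), _one_hot(R)) == pytest.approx(
                0.0, abs=1e-12)
            assert gdl_value(_one_hot(R), _one_hot(1 - R)) == pytest.approx(
                1.0, abs=1e-12)

    def test_monotone_along_interpolation(self, rng):
        R = rng.integers(0, 2, (6, 6, 6)).astype(float)
        worst = _one_hot(1 - R)
        best = _one_hot(R)
        vals = [gdl_value(_one_hot(R), (1 - t) * worst + t * best)
                for t in np.linspace(0, 1, 11)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_permutation_invariant(self, rng):
        R = rng.integers(0, 2, (4, 4, 4)).astype(float)
        P = rng.uniform(0, 1, (4, 4, 4))
        perm = rng.permutation(64)
        Rp = R.ravel()[perm].reshape(4, 4, 4)
        Pp = P.ravel()[perm].reshape(4, 4, 4)
        assert gdl_value(_one_hot(R), _one_hot(P)) == pytest.approx(
            gdl_value(_one_hot(Rp), _one_hot(Pp)), abs=1e-12)

    def test_empty_class_guard_finite(self):
        R = np.zeros((3, 3, 3))          # vessel class empty
        P = np.full((3, 3, 3), 0.3)
        v = gdl_value(_one_hot(R), _one_hot(P))
        assert np.isfinite(v) and 0.0 <= v <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            gdl(nn.constant(np.zeros((1, 2, 3, 3, 3))),
                nn.constant(np.zeros((1, 2, 4, 3, 3))))


class TestSoftSkeleton:
    def test_single_voxel_is_its_own_skeleton(self):
        m = np.zeros((9, 9, 9))
        m[4, 4, 4] = 1
        out = soft_skeleton_array(m, k=3)
        np.testing.assert_array_equal(out.data, m)

    def test_thin_line_is_fixed_point(self):
        m = _line()
        for k in (1, 5, 10):
            np.testing.assert_array_equal(soft_skeleton_array(m, k).data, m)

    def test_skeleton_below_source(self, rng):
        m = rng.uniform(0, 1, (12, 12, 12))
        out = soft_skeleton_array(m, k=4)
        assert (out.data <= m + 1e-6).all()

    def test_cylinder_skeleton_near_medial_axis(self):
        from skimage.morphology import skeletonize
        shape = (20, 20, 40)
        idx = np.indices(shape)
        cyl = (((idx[0] - 10) ** 2 + (idx[1] - 10) ** 2) <= 9).astype(float)
        ours = soft_skeleton_array(cyl, k=5).data > 0.5
        ref = skeletonize(cyl.astype(bool))
        # both skeletons must lie on the same medial structure: ours within
        # one voxel of the reference axis for >= 90% of its mass
        from scipy import ndimage
        near_ref = ndimage.binary_dilation(ref, iterations=1)
        assert (ours & near_ref).sum() / max(ours.sum(), 1) >= 0.9

    def test_k_validation(self):
        with pytest.raises(ValueError, match="iterations"):
            soft_skeletonize(nn.constant(np.zeros((1, 1, 4, 4, 4))), k=0)


class TestCenterlineDice:
    def test_perfect_match_zero_loss(self):
        m = _line()
        assert cld_loss_value(m, m, k=5) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_maps_loss_one(self):
        a = np.zeros((20, 20, 20))
        b = np.zeros((20, 20, 20))
        a[2:8, 5, 5] = 1
        b[12:18, 14, 14] = 1
        assert cld_loss_value(a, b, k=5) == pytest.approx(1.0, abs=1e-12)

    def test_empty_prediction_loss_one(self):
        assert cld_loss_value(_line(), np.zeros((28, 28, 28)), k=3) == 1.0

    def test_truncated_tube_loss_one_third(self):
        # R: line of 40; P: same line truncated to 20. Skeleton = line, so
        # Tprec = 1, Tsens = 0.5, clDice = 2/3, loss = 1/3.
        R = np.zeros((48, 12, 12))
        R[4:44, 6, 6] = 1
        P = np.zeros((48, 12, 12))
        P[4:24, 6, 6] = 1
        assert cld_loss_value(R, P, k=5) == pytest.approx(1 / 3, abs=1e-6)

    def test_isometry_invariance(self, rng, small_phantom):
        _, gt, _ = small_phantom
        R = gt.data.astype(float)
        P = np.clip(R + rng.uniform(-0.3, 0.3, R.shape), 0, 1)
        base = cld_loss_value(R, P, k=4)
        flipped = cld_loss_value(R[::-1], P[::-1], k=4)
        transposed = cld_loss_value(R.transpose(2, 0, 1),
                                    P.transpose(2, 0, 1), k=4)
        assert base == pytest.approx(flipped, abs=1e-9)
        assert base == pytest.approx(transposed, abs=1e-9)


class TestMaskingAndFeatureLoss:
    def test_masked_input_support(self, rng):
        x = nn.constant(rng.standard_normal((1, 1, 6, 6, 6)))
        M = rng.integers(0, 2, (1, 1, 6, 6, 6)).astype(float)
        out = masked_input(x, nn.constant(M))
        np.testing.assert_array_equal(out.value != 0,
                                      (M != 0) & (x.value != 0))
        ones = masked_input(x, nn.constant(np.ones_like(M)))
        np.testing.assert_array_equal(ones.value, x.value)
        zeros = masked_input(x, nn.constant(np.zeros_like(M)))
        assert (zeros.value == 0).all()

    def test_identical_masks_zero_for_any_discriminator(self, rng):
        from angioseg.networks import Discriminator, DiscriminatorConfig
        disc = Discriminator(DiscriminatorConfig(scales=3, base_channels=2,
                                                 seed=0))
        x = nn.constant(rng.uniform(0, 1, (1, 1, 8, 8, 8)).astype(np.float32))
        M = nn.constant(rng.uniform(0, 1, (1, 1, 8, 8, 8)).astype(np.float32))
        assert float(feature_loss(x, M, M, disc).value) == 0.0

    def test_identity_discriminator_closed_form(self):
        # single-layer identity "discriminator": loss = mean |x∘Pv - x∘Rv|
        x = nn.constant(np.full((1, 1, 4, 4, 4), 2.0))
        Pv = nn.constant(np.full((1, 1, 4, 4, 4), 0.75))
        Rv = nn.constant(np.full((1, 1, 4, 4, 4), 0.25))
        ident = lambda t: [t]
        assert float(feature_loss(x, Pv, Rv, ident).value) == pytest.approx(
            1.0)  # |2*0.75 - 2*0.25| = 1
        doubled = lambda t: [t, t]
        assert float(feature_loss(x, Pv, Rv, doubled).value) == \
            pytest.approx(1.0)  # duplicating layers leaves the mean intact

    def test_positive_for_differing_masks(self, rng):
        from angioseg.networks import Discriminator, DiscriminatorConfig
        disc = Discriminator(DiscriminatorConfig(scales=2, base_channels=2,
                                                 seed=1))
        x = nn.constant(rng.uniform(0.5, 1, (1, 1, 8, 8, 8))
                        .astype(np.float32))
        Rv = rng.integers(0, 2, (1, 1, 8, 8, 8)).astype(np.float32)
        Pv = 1.0 - Rv
        v = float(feature_loss(x, nn.constant(Pv), nn.constant(Rv),
                               disc).value)
        assert v > 0


class TestCombinedLoss:
    def test_addition(self):
        parts = [nn.constant(v) for v in (0.25, 1 / 3, 0.1)]
        assert float(combined_loss(*parts).value) == pytest.approx(
            0.25 + 1 / 3 + 0.1)
        assert float(combined_loss(parts[0], parts[1]).value) == \
            pytest.approx(0.25 + 1 / 3)  # segmentation-only variant
        zero = [nn.constant(0.0)] * 3
        assert float(combined_loss(*zero).value) == 0.0

    def test_gradients_finite_on_open_interval(self, rng):
        R = rng.integers(0, 2, (1, 2, 8, 8, 8)).astype(np.float64)
        R[0, 0] = 1 - R[0, 1]
        logits = nn.Tensor(rng.standard_normal((1, 2, 8, 8, 8)),
                           requires_grad=True)
        P = nn.softmax_channel(logits)
        g = gdl(nn.constant(R), P)
        c = cld_loss(nn.constant(R[:, 1:2]), _channel_vessel(P), k=3)
        total = combined_loss(g, c)
        total.backward()
        assert np.isfinite(logits.grad).all()


def _channel_vessel(t):
    val = t.value[:, 1:2]

    def bwd(g):
        full = np.zeros_like(t.value)
        full[:, 1:2] = g
        t._accumulate(full)

    return nn.Tensor(val, (t,), bwd)
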