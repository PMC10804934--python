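"""Task recipes: normalization, augmentation, model builders, bag handling."""

import numpy as np
import pytest

from shefl.tasks import (
    AugmentConfig,
    MLPConfig,
    UNetConfig,
    augment_volume,
    balance_by_undersampling,
    build_mlp,
    build_unet,
    dice_loss,
    mlp_parameter_count,
    normalize_volume,
    patient_score,
)


class TestNormalizeVolume:
    def test_constant_volume_maps_to_zeros(self):
        out = normalize_volume(np.full((4, 4, 4), 7.3))
        assert np.array_equal(out, np.zeros((4, 4, 4)))

    def test_uniform_ramp_clips_at_99th_percentile(self):
        vals = np.arange(100.0).reshape(4, 5, 5)
        out = normalize_volume(vals)
        hi = np.percentile(vals, 99)
        expect = np.minimum(vals, hi)
        expect = (expect - expect.min()) / (expect.max() - expect.min())
        assert np.allclose(out, expect)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_output_range_property(self, rng):
        for _ in range(10):
            v = rng.normal(size=(3, 4, 4, 4)) * rng.uniform(0.1, 100)
            out = normalize_volume(v)
            assert out.min() == 0.0
            assert out.max() == pytest.approx(1.0) or out.max() == 0.0

    def test_4d_normalizes_each_channel(self, rng):
        v = np.stack([rng.normal(size=(4, 4, 4)), 100 + rng.normal(size=(4, 4, 4))])
        out = normalize_volume(v)
        for c in range(2):
            assert out[c].min() == 0.0
            assert out[c].max() == pytest.approx(1.0)


class TestAugmentVolume:
    def _identity_config(self):
        return AugmentConfig(
            flip_probability=0.0, gain_range=(1.0, 1.0),
            gamma_range=(1.0, 1.0), noise_sigma=0.0, crop=None,
        )

    def test_degenerate_config_is_identity(self, rng):
        vol = rng.uniform(0, 1, size=(2, 6, 6, 6))
        mask = rng.integers(0, 3, size=(6, 6, 6))
        out_v, out_m = augment_volume(vol, mask, self._identity_config(), seed=0)
        assert np.allclose(out_v, vol)
        assert np.array_equal(out_m, mask)

    def test_flips_keep_volume_and_mask_aligned(self, rng):
        cfg = AugmentConfig(flip_probability=1.0, gain_range=(1.0, 1.0),
                            gamma_range=(1.0, 1.0), noise_sigma=0.0)
        vol = rng.uniform(0, 1, size=(1, 6, 6, 6))
        mask = (vol[0] > 0.8).astype(np.int64)
        # encode the mask into the volume: alignment must survive flipping
        out_v, out_m = augment_volume(vol, mask, cfg, seed=3)
        assert np.array_equal((out_v[0] > 0.8).astype(np.int64), out_m)

    def test_empirical_flip_rate(self):
        cfg = AugmentConfig(gain_range=(1.0, 1.0), gamma_range=(1.0, 1.0),
                            noise_sigma=0.0)
        vol = np.zeros((1, 2, 2, 2))
        vol[0, 0, 0, 0] = 1.0
        mask = np.zeros((2, 2, 2), dtype=np.int64)
        flips_a = flips_b = 0
        n = 10000
        for i in range(n):
            out_v, _ = augment_volume(vol, mask, cfg, seed=i)
            marker = tuple(np.argwhere(out_v[0] == 1.0)[0])
            flips_a += marker[1] == 1  # first flipped axis
            flips_b += marker[2] == 1  # second flipped axis
        assert abs(flips_a / n - 0.4) < 0.02
        assert abs(flips_b / n - 0.4) < 0.02

    def test_crop_too_large_rejected(self, rng):
        cfg = AugmentConfig(crop=(8, 8, 8))
        with pytest.raises(ValueError):
            augment_volume(
                rng.normal(size=(1, 4, 4, 4)),
                np.zeros((4, 4, 4), dtype=int),
                cfg,
                seed=0,
            )

    def test_deterministic_given_seed(self, rng):
        vol = rng.uniform(0, 1, size=(2, 6, 6, 6))
        mask = rng.integers(0, 3, size=(6, 6, 6))
        a = augment_volume(vol, mask, seed=9)
        b = augment_volume(vol, mask, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestBuilders:
    def test_unet_parameter_count_hand_summed(self):
        cfg = UNetConfig(levels=2, base_channels=4, in_channels=1,
                         out_classes=2, spatial=(8, 8, 8))
        model = build_unet(cfg)

        def conv(cin, cout, k):
            return cin * cout * k**3 + cout

        def block(cin, cout):  # two convs, each with an affine norm
            return conv(cin, cout, 3) + 2 * cout + conv(cout, cout, 3) + 2 * cout

        expect = (
            block(1, 4)          # contraction level 1
            + block(4, 8)        # bottleneck
            + block(4 + 8, 4)    # expansion (concat skip)
            + conv(4, 2, 1)      # 1x1x1 head
        )
        assert model.n_parameters == expect

    def test_doubling_base_channels_quadruples_conv_params(self):
        def conv_params(model):
            return sum(
                v.size for k, v in model.parameters().items()
                if "conv" in k and k.endswith("weight")
            )

        small = build_unet(UNetConfig(levels=2, base_channels=4, spatial=(8, 8, 8)))
        big = build_unet(UNetConfig(levels=2, base_channels=8, spatial=(8, 8, 8)))
        ratio = conv_params(big) / conv_params(small)
        assert 3.0 < ratio < 4.5

    def test_mlp_counts(self):
        assert mlp_parameter_count((512, 256, 256, 128, 2)) == 230274
        assert mlp_parameter_count((2, 2)) == 6
        assert build_mlp(MLPConfig(widths=(2, 2))).n_parameters == 6
        # removing biases reduces the count by the sum of output widths
        from shefl.nn import MLPClassifier

        widths = (16, 8, 4)
        with_bias = MLPClassifier(widths, seed=0).n_parameters
        without = MLPClassifier(widths, seed=0, bias=False).n_parameters
        assert with_bias - without == 8 + 4

    def test_reference_scale_configs_recorded(self):
        # reference topology: 4 levels, 48 base channels, 4 -> 3 channels
        cfg = UNetConfig(levels=4, base_channels=48, in_channels=4,
                         out_classes=3, spatial=(128, 128, 128))
        assert cfg.levels == 4 and cfg.base_channels == 48
        assert MLPConfig().widths == (512, 256, 256, 128, 2)


class TestDiceLoss:
    def test_half_overlap_binary_toy(self):
        # |A| = |B| = 4, |A n B| = 2 -> Dice 0.5, loss 0.5
        p = np.zeros((1, 2, 8))
        t = np.zeros((1, 2, 8))
        p[0, 1, 0:4] = 1.0
        t[0, 1, 2:6] = 1.0
        p[0, 0] = 1.0 - p[0, 1]
        t[0, 0] = 1.0 - t[0, 1]
        assert dice_loss(p, t) == pytest.approx(0.5, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((1, 2, 4)), np.zeros((1, 2, 5)))


class TestBags:
    def test_undersampling_to_minority_count(self, rng):
        x = rng.normal(size=(140, 4))
        y = np.array([0] * 100 + [1] * 40)
        xb, yb = balance_by_undersampling(x, y, seed=0)
        assert (yb == 0).sum() == 40 and (yb == 1).sum() == 40

    def test_balanced_input_unchanged_sizes(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.array([0] * 10 + [1] * 10)
        xb, yb = balance_by_undersampling(x, y, seed=0)
        assert len(yb) == 20

    def test_output_rows_are_subset_of_input(self, rng):
        x = rng.normal(size=(30, 2))
        y = np.array([0] * 20 + [1] * 10)
        xb, _ = balance_by_undersampling(x, y, seed=1)
        rows = {tuple(r) for r in x}
        assert all(tuple(r) in rows for r in xb)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            balance_by_undersampling(rng.normal(size=(5, 2)), np.zeros(5), seed=0)

    def test_patient_score(self):
        assert patient_score([0.8, 0.8, 0.8]) == pytest.approx(0.8)
        assert patient_score([0.0, 1.0]) == pytest.approx(0.5)
        perm = [0.1, 0.5, 0.9]
        assert patient_score(perm) == patient_score(perm[::-1])
        with pytest.raises(ValueError):
            patient_score([])
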