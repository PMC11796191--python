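import numpy as np
import pytest

from cd31quant.model import (
    AugmentConfig,
    ClassWeights,
    NetConfig,
    TrainConfig,
    augment,
    build_unet,
    color_jitter,
    rotate_mirror,
    train,
    weighted_soft_dice_loss,
    weighted_soft_dice_loss_grad,
)
from cd31quant.model.loss import DEFAULT_CLASS_WEIGHTS
from cd31quant.imageio import TissueClass, one_hot


def reference_mean_soft_dice_complement(p, g):
    """Independent plain-loop implementation of the unweighted mean soft
    Dice complement, used as an oracle for the equal-weights case."""
    p = np.asarray(p, float).reshape(-1, p.shape[-1])
    g = np.asarray(g, float).reshape(-1, g.shape[-1])
    dices = []
    for j in range(p.shape[1]):
        num = 0.0
        den = 0.0
        for i in range(p.shape[0]):
            num += 2 * p[i, j] * g[i, j]
            den += p[i, j] + g[i, j]
        dices.append(num / den if den > 0 else 1.0)
    return 1.0 - sum(dices) / len(dices)


class TestLoss:
    def test_perfect_agreement_zero(self):
        rng = np.random.default_rng(0)
        g = one_hot(rng.integers(0, 10, (16, 16)).astype(np.uint8))
        assert weighted_soft_dice_loss(g, g, ClassWeights()) == pytest.approx(0.0, abs=1e-12)

    def test_total_disagreement_one(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 10, (16, 16)).astype(np.uint8)
        g = one_hot(codes)
        p = one_hot(((codes + 1) % 10).astype(np.uint8))
        assert weighted_soft_dice_loss(p, g, ClassWeights()) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_toy(self):
        # two pixels, one class: 1 - 2*1 / ((1+1) + 1) = 1/3
        loss = weighted_soft_dice_loss(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        assert loss == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_equal_weights_match_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = int(rng.integers(2, 6))
            n = int(rng.integers(2, 30))
            p = rng.random((n, c))
            p /= p.sum(axis=1, keepdims=True)
            g = np.eye(c)[rng.integers(0, c, n)]
            ours = weighted_soft_dice_loss(p, g)
            ref = reference_mean_soft_dice_complement(p, g)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_bounded_and_monotone_in_overlap(self):
        rng = np.random.default_rng(7)
        g = np.eye(2)[rng.integers(0, 2, 64)]
        # interpolate from anti-aligned to aligned predictions; loss must fall
        losses = []
        for alpha in np.linspace(0, 1, 9):
            p = alpha * g + (1 - alpha) * (1 - g)
            loss = weighted_soft_dice_loss(p, g)
            assert 0.0 <= loss <= 1.0
            losses.append(loss)
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_smoothing_keeps_empty_class_neutral(self):
        # class 2 absent from p and g: contributes Dice 1 either way
        g = np.eye(3)[np.zeros(8, dtype=int)]
        p = g.copy()
        assert weighted_soft_dice_loss(p, g, smooth=0.0) == pytest.approx(0.0, abs=1e-12)
        assert weighted_soft_dice_loss(p, g, smooth=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_ignore_mask_excludes_pixels(self):
        rng = np.random.default_rng(3)
        g = one_hot(rng.integers(0, 4, (8, 8)).astype(np.uint8), n_classes=4)
        p = rng.random((8, 8, 4))
        p /= p.sum(axis=-1, keepdims=True)
        ignore = np.zeros((8, 8), bool)
        ignore[:2] = True
        base = weighted_soft_dice_loss(p, g, ignore=ignore)
        p2 = p.copy()
        p2[:2] = rng.random((2, 8, 4))  # corrupt only ignored pixels
        assert weighted_soft_dice_loss(p2, g, ignore=ignore) == pytest.approx(base, abs=1e-12)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(5)
        p = rng.random((6, 3))
        g = np.eye(3)[rng.integers(0, 3, 6)]
        w = np.array([1.0, 2.0, 5.0])
        loss, grad = weighted_soft_dice_loss_grad(p, g, w, smooth=1.0)
        eps = 1e-6
        for i in range(6):
            for j in range(3):
                pp = p.copy()
                pp[i, j] += eps
                fd = (weighted_soft_dice_loss(pp, g, w, smooth=1.0) - loss) / eps
                assert grad[i, j] == pytest.approx(fd, abs=1e-4)

    def test_default_weights(self):
        w = ClassWeights().as_array()
        assert w[int(TissueClass.VESSEL)] == 10
        assert w.sum() == 31
        assert all(v > 0 for v in DEFAULT_CLASS_WEIGHTS.values())

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            ClassWeights({TissueClass.VESSEL: 0.0})


class TestUNet:
    def test_output_contract(self):
        net = build_unet(NetConfig(depth=2, base_channels=4, tile_px=32), seed=0)
        x = np.random.default_rng(0).random((1, 3, 32, 32)).astype(np.float32)
        probs = net.forward(x)
        assert probs.shape == (1, 10, 32, 32)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_constant_input_finite(self):
        net = build_unet(NetConfig(depth=2, base_channels=4, tile_px=32), seed=1)
        probs = net.predict(np.full((32, 32, 3), 128, dtype=np.uint8))
        assert np.isfinite(probs).all()
        assert probs.shape == (32, 32, 10)

    def test_indivisible_tile_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(depth=5, tile_px=100)

    def test_save_load_round_trip(self, tmp_path):
        net = build_unet(NetConfig(depth=2, base_channels=4, tile_px=16), seed=2)
        rgb = np.random.default_rng(2).integers(0, 255, (16, 16, 3), dtype=np.uint8)
        before = net.predict(rgb)
        net.save(tmp_path / "m.npz")
        from cd31quant.model import UNet

        loaded = UNet.load(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.predict(rgb), before, atol=1e-6)
        assert loaded.class_order[0] == "VESSEL"

    def test_backward_matches_finite_difference(self):
        net = build_unet(NetConfig(depth=2, base_channels=2, tile_px=8), seed=0)
        rng = np.random.default_rng(1)
        x = rng.random((1, 3, 8, 8))
        g = np.eye(10)[rng.integers(0, 10, (1, 8, 8))]
        w = ClassWeights().as_array()

        def loss_of():
            p = net.forward(x, train=True)
            loss, _ = weighted_soft_dice_loss_grad(p.transpose(0, 2, 3, 1), g, w, smooth=1.0)
            return loss

        p = net.forward(x, train=True)
        loss, dp = weighted_soft_dice_loss_grad(p.transpose(0, 2, 3, 1), g, w, smooth=1.0)
        net.backward(dp.transpose(0, 3, 1, 2))
        layers = [l for l in net.layers() if l.params]
        errs = []
        for layer in (layers[0], layers[len(layers) // 2], layers[-1]):
            for key in layer.params:
                flat = layer.params[key].ravel()
                gflat = layer.grads[key].ravel()
                for idx in rng.integers(0, flat.size, 2):
                    eps = 1e-4
                    old = flat[idx]
                    flat[idx] = old + eps
                    lp = loss_of()
                    flat[idx] = old - eps
                    lm = loss_of()
                    flat[idx] = old
                    fd = (lp - lm) / (2 * eps)
                    errs.append(abs(fd - gflat[idx]) / max(1e-8, abs(fd) + abs(gflat[idx])))
        assert max(errs) < 1e-2


class TestAugment:
    def test_double_half_turn_is_identity(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        mask = one_hot(rng.integers(0, 10, (32, 32)).astype(np.uint8))
        r1, m1 = rotate_mirror(rgb, mask, 180)
        r2, m2 = rotate_mirror(r1, m1, 180)
        np.testing.assert_array_equal(r2, rgb)
        np.testing.assert_array_equal(m2, mask)

    def test_flip_preserves_class_counts(self):
        rng = np.random.default_rng(1)
        mask = one_hot(rng.integers(0, 10, (32, 32)).astype(np.uint8))
        np.testing.assert_array_equal(mask[::-1].sum(axis=(0, 1)), mask.sum(axis=(0, 1)))

    def test_free_rotation_mask_stays_one_hot(self):
        rng = np.random.default_rng(2)
        rgb = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        mask = one_hot(rng.integers(0, 10, (32, 32)).astype(np.uint8))
        _, m45 = rotate_mirror(rgb, mask, 45)
        np.testing.assert_allclose(m45.sum(axis=-1), 1.0)
        assert set(np.unique(m45)) <= {0.0, 1.0}

    def test_color_jitter_leaves_geometry(self):
        rng = np.random.default_rng(3)
        rgb = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        out = color_jitter(rgb, rng, AugmentConfig())
        assert out.shape == rgb.shape and out.dtype == np.uint8

    def test_augment_end_to_end_one_hot(self):
        rng = np.random.default_rng(4)
        rgb = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        mask = one_hot(rng.integers(0, 10, (32, 32)).astype(np.uint8))
        for _ in range(5):
            rgb2, mask2 = augment(rgb, mask, rng)
            assert rgb2.shape == rgb.shape
            np.testing.assert_allclose(mask2.sum(axis=-1), 1.0)


class TestTrain:
    def test_empty_dataset_rejected(self):
        net = build_unet(NetConfig(depth=2, base_channels=2, tile_px=16))
        with pytest.raises(ValueError, match="empty"):
            train([], net)

    def test_same_seed_same_history(self):
        rng = np.random.default_rng(0)
        data = []
        for _ in range(4):
            rgb = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
            mask = one_hot(rng.integers(0, 10, (16, 16)).astype(np.uint8))
            data.append((rgb, mask))
        cfg = TrainConfig(epochs=2, batch_size=2, seed=9, augment=False)
        h1 = train(data, build_unet(NetConfig(depth=2, base_channels=2, tile_px=16), seed=3), cfg)
        h2 = train(data, build_unet(NetConfig(depth=2, base_channels=2, tile_px=16), seed=3), cfg)
        np.testing.assert_allclose(h1["step_loss"], h2["step_loss"], rtol=1e-10)

    def test_lr_schedule_decays_with_restarts(self):
        cfg = TrainConfig(lr=1e-3, lr_decay=0.9, warm_restart_epochs=5)
        lrs = [cfg.lr_at(e) for e in range(10)]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[4] < lrs[0]  # cosine decay within the period
        assert lrs[5] > lrs[4]  # warm restart
        assert lrs[5] < lrs[0]  # exponential envelope still decays
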