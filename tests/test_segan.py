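import numpy as np
import pytest

from ivusffr.segan import (
    Critic,
    CriticConfig,
    Segmentor,
    SegmentorConfig,
    TrainSchedule,
    TrainState,
    masked_image,
    multiscale_l1_loss,
    segment_pullback,
    train_segan,
)
from ivusffr.segan.nn import Tensor


class TestMaskedImage:
    def test_identity_and_null_mask(self):
        rng = np.random.default_rng(0)
        x = rng.random((8, 8)).astype(np.float32)
        assert np.array_equal(masked_image(x, np.ones_like(x)), x)
        assert not masked_image(x, np.zeros_like(x)).any()

    def test_disk_mask_zeroes_outside(self):
        x = np.ones((16, 16), np.float32)
        yy, xx = np.mgrid[0:16, 0:16]
        m = (np.hypot(xx - 7.5, yy - 7.5) < 5).astype(np.float32)
        out = masked_image(x, m)
        assert np.array_equal(out, m)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            masked_image(np.ones((4, 4)), np.ones((5, 5)))

    def test_mask_range_checked(self):
        with pytest.raises(ValueError):
            masked_image(np.ones((4, 4)), np.full((4, 4), 2.0))


def _critic(channels=(4, 8), in_channels=1, seed=0):
    return Critic(CriticConfig(in_channels=in_channels, channels=channels), np.random.default_rng(seed))


class TestMultiscaleL1:
    def test_zero_on_identical_inputs(self):
        x = np.random.default_rng(1).random((2, 1, 16, 16)).astype(np.float32)
        loss = multiscale_l1_loss(_critic(), x, x.copy())
        assert loss.item() == 0.0

    def test_identity_critic_reduces_to_mae(self):
        rng = np.random.default_rng(2)
        a = rng.random((2, 1, 16, 16)).astype(np.float32)
        b = rng.random((2, 1, 16, 16)).astype(np.float32)
        identity = _critic(channels=())
        loss = multiscale_l1_loss(identity, a, b)
        assert loss.item() == pytest.approx(np.abs(a - b).mean(), abs=1e-7)

    def test_matches_brute_force_feature_oracle(self):
        """Independent oracle: direct nested-loop convolution + leaky ReLU in
        float64, layer features compared by per-element mean absolute
        difference averaged over layers."""
        rng = np.random.default_rng(3)
        critic = _critic(channels=(3, 5))
        a = rng.random((1, 1, 8, 8)).astype(np.float32)
        b = rng.random((1, 1, 8, 8)).astype(np.float32)

        def conv_direct(x, w, bias, stride=2, pad=1):
            f, c, kh, kw = w.shape
            n, _, h, wid = x.shape
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            hp = (h + 2 * pad - kh) // stride + 1
            wp = (wid + 2 * pad - kw) // stride + 1
            out = np.zeros((n, f, hp, wp))
            for ni in range(n):
                for fi in range(f):
                    for i in range(hp):
                        for j in range(wp):
                            patch = xp[ni, :, i * stride : i * stride + kh, j * stride : j * stride + kw]
                            out[ni, fi, i, j] = (patch * w[fi]).sum() + bias[fi]
            return out

        def features_direct(x):
            feats = [x.astype(np.float64)]
            h = x.astype(np.float64)
            for layer in critic.layers:
                h = conv_direct(h, layer.w.data.astype(np.float64), layer.b.data.astype(np.float64))
                h = np.where(h > 0, h, 0.2 * h)
                feats.append(h)
            return feats

        fa, fb = features_direct(a), features_direct(b)
        expected = np.mean([np.abs(p - q).mean() for p, q in zip(fa, fb)])
        loss = multiscale_l1_loss(critic, a, b)
        assert loss.item() == pytest.approx(expected, abs=1e-6)

    def test_nonnegative_for_random_critics(self):
        rng = np.random.default_rng(4)
        for seed in range(4):
            a = rng.random((1, 1, 16, 16)).astype(np.float32)
            b = rng.random((1, 1, 16, 16)).astype(np.float32)
            assert multiscale_l1_loss(_critic(seed=seed), a, b).item() >= 0.0


class TestMinMaxSteps:
    def _setup(self):
        rng = np.random.default_rng(5)
        x = rng.random((4, 1, 16, 16)).astype(np.float32)
        y = (rng.random((4, 2, 16, 16)) > 0.5).astype(np.float32)
        seg = Segmentor(SegmentorConfig(input_size=16, channels=(4, 8)), np.random.default_rng(0))
        critic = Critic(CriticConfig(in_channels=2, channels=(4, 8)), np.random.default_rng(1))
        gt = Tensor(x * y)
        return x, seg, critic, gt

    def _loss(self, x, seg, critic, gt):
        pred = Tensor(x) * seg(Tensor(x))
        return multiscale_l1_loss(critic, pred, gt)

    def test_critic_ascent_does_not_decrease_loss(self):
        x, seg, critic, gt = self._setup()
        before = self._loss(x, seg, critic, gt)
        before.backward()
        lr = 1e-5  # plain gradient step, clipping disabled
        for p in critic.params:
            p.data += lr * p.grad
        after = self._loss(x, seg, critic, gt)
        assert after.item() >= before.item()

    def test_segmentor_descent_does_not_increase_loss(self):
        x, seg, critic, gt = self._setup()
        before = self._loss(x, seg, critic, gt)
        before.backward()
        lr = 1e-5
        for p in seg.params:
            p.data -= lr * p.grad
        after = self._loss(x, seg, critic, gt)
        assert after.item() <= before.item()


class TestTraining:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_segan(np.empty((0, 16, 16)), np.empty((0, 2, 16, 16)))

    def test_same_seed_same_trajectory(self, overfit_frames):
        _, frames, masks = overfit_frames
        runs = [
            train_segan(frames, masks, schedule=TrainSchedule(steps=12, log_every=4), seed=7)
            for _ in range(2)
        ]
        assert runs[0].loss_history == runs[1].loss_history

    def test_mismatched_masks_rejected(self, overfit_frames):
        _, frames, masks = overfit_frames
        with pytest.raises(ValueError):
            train_segan(frames, masks[:, :, :32, :32])


class TestSegmentPullback:
    class _DiskSegmentor:
        """Stand-in network emitting a fixed probability map."""

        def __init__(self, prob_map):
            self.prob = prob_map

        def __call__(self, x):
            n = x.data.shape[0]
            return Tensor(np.repeat(self.prob[None, None], n, axis=0))

    def test_disk_probability_map_contour_radius(self):
        size, px = 64, 0.05
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        prob = (np.hypot(xx - c, yy - c) <= 20).astype(np.float32)
        state = TrainState(segmentor=self._DiskSegmentor(prob), critic=None, seed=0)
        (res,) = segment_pullback(state, np.zeros((1, size, size), np.float32), px)
        assert not res.flagged
        radii = np.hypot(res.contour[:, 0], res.contour[:, 1])
        assert np.allclose(radii, 20 * px, atol=0.5 * px)

    def test_empty_probability_map_flagged(self):
        prob = np.zeros((64, 64), np.float32)
        state = TrainState(segmentor=self._DiskSegmentor(prob), critic=None, seed=0)
        (res,) = segment_pullback(state, np.zeros((1, 64, 64), np.float32), 0.05)
        assert res.flagged and res.contour is None
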