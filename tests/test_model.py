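"""Multitask CNN: layers, embedding, paste synthesis, training contracts."""

import numpy as np
import pytest

from graymap import _nn
from graymap.maps import GrayValueMap
from graymap.model import (
    MultitaskCNN,
    SlideSample,
    TrainConfig,
    canvas_embed,
    desk_config,
    paste_synthesize,
)
from graymap.simulate import synth_cohort


def _tiny_cfg(**kw):
    base = dict(canvas=24, crop=16, base_width=4, stage_blocks=(1,), epochs=5,
                batch_size=4, paste_prob=0.0, rotation_deg=0.0)
    base.update(kw)
    return TrainConfig(**base)


def _map(grid):
    return GrayValueMap(np.asarray(grid, dtype=np.float32))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients of the full layer stack vs central differences."""
        net = _nn.Sequential(
            _nn.Conv2d(2, 3, 3, rng=rng),
            _nn.BatchNorm2d(3),
            _nn.PReLU(3),
            _nn.ResidualBlock(3, 4, stride=2, rng=rng),
            _nn.GlobalAvgPool(),
            _nn.Linear(4, 2, rng=rng),
        )
        x = rng.normal(size=(3, 2, 8, 8))
        t = rng.random((3, 2))
        z = net.forward(x, train=True)
        _, dz = _nn.bce_with_logits(z, t)
        for p in net.params():
            p.grad[...] = 0
        net.backward(dz)
        eps = 1e-6
        for p in net.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _nn.bce_with_logits(net.forward(x, train=True), t)
                flat[i] = orig - eps
                lm, _ = _nn.bce_with_logits(net.forward(x, train=True), t)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_masked_bce(self):
        z = np.array([[2.0, -1.0], [0.5, 3.0]])
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = np.array([[1.0, 0.0], [1.0, 1.0]])
        loss, grad = _nn.bce_with_logits(z, t, m)
        assert grad[0, 1] == 0.0
        full, _ = _nn.bce_with_logits(z, t)
        assert loss != pytest.approx(full)


class TestCosineSchedule:
    def test_endpoints(self):
        assert _nn.cosine_lr(0, 100, 0.001, 1e-8) == pytest.approx(0.001)
        assert _nn.cosine_lr(99, 100, 0.001, 1e-8) <= 1e-7

    def test_monotone_decay(self):
        lrs = [_nn.cosine_lr(e, 50, 0.001, 1e-8) for e in range(50)]
        assert np.all(np.diff(lrs) < 0)


class TestCanvasEmbed:
    def test_centered_placement(self):
        cfg = _tiny_cfg()
        grid = np.ones((10, 12, 3), dtype=np.float32)
        canvas = canvas_embed(_map(grid), cfg)
        assert canvas.shape == (24, 24, 3)
        nz = np.any(canvas != 0, axis=2)
        rows = np.flatnonzero(nz.any(axis=1))
        cols = np.flatnonzero(nz.any(axis=0))
        assert rows[0] == (24 - 10) // 2 and len(rows) == 10
        assert cols[0] == (24 - 12) // 2 and len(cols) == 12

    def test_oversized_map_downscaled_preserving_aspect(self):
        cfg = _tiny_cfg()
        canvas = canvas_embed(_map(np.ones((48, 24, 3))), cfg)
        nz = np.any(canvas != 0, axis=2)
        rows = np.flatnonzero(nz.any(axis=1))
        cols = np.flatnonzero(nz.any(axis=0))
        assert len(rows) <= 24 and len(cols) <= 12 + 1

    def test_f_channel_sum_preserved_without_resize(self):
        cfg = _tiny_cfg()
        grid = np.zeros((8, 8, 3), dtype=np.float32)
        grid[..., 1] = np.random.default_rng(0).random((8, 8)).astype(np.float32)
        canvas = canvas_embed(_map(grid), cfg)
        assert canvas[..., 1].sum() == pytest.approx(grid[..., 1].sum(), rel=1e-6)

    def test_normalization_divides_a_and_l(self):
        cfg = _tiny_cfg(a_p99=2.0, l_p99=100.0)
        grid = np.zeros((2, 2, 3), dtype=np.float32)
        grid[0, 0] = (1.0, 0.5, 50.0)
        canvas = canvas_embed(_map(grid), cfg)
        center = canvas[11, 11]
        assert tuple(center) == pytest.approx((0.5, 0.5, 0.5))


class TestPasteSynthesize:
    def _sample(self, block, ihc, fish, canvas=24, offset=(0, 0)):
        c = np.zeros((canvas, canvas, 3), dtype=np.float32)
        r, co = offset
        c[r : r + block.shape[0], co : co + block.shape[1]] = block
        return SlideSample(canvas=c, ihc_label=ihc, fish_label=fish, fold_id=0)

    def test_disjoint_cell_arithmetic(self):
        target = self._sample(np.ones((6, 6, 3)), ihc=2, fish=1, offset=(0, 0))
        donor = self._sample(np.ones((5, 5, 3)) * 2, ihc=0, fish=1, offset=(10, 10))
        out = paste_synthesize(target, donor, seed=3)
        assert out.pasted
        n_target = 36
        n_donor = 25
        assert int(np.any(out.canvas != 0, axis=2).sum()) == n_target + n_donor

    def test_no_space_returns_target_unchanged(self):
        target = self._sample(np.ones((24, 24, 3)), ihc=2, fish=0)
        donor = self._sample(np.ones((10, 10, 3)), ihc=1, fish=0, offset=(5, 5))
        out = paste_synthesize(target, donor, seed=1)
        assert not out.pasted
        np.testing.assert_array_equal(out.canvas, target.canvas)

    def test_labels_are_targets(self):
        target = self._sample(np.ones((4, 4, 3)), ihc=2, fish=1)
        donor = self._sample(np.ones((4, 4, 3)), ihc=1, fish=1, offset=(12, 12))
        out = paste_synthesize(target, donor, seed=2)
        assert out.ihc_label == 2 and out.fish_label == 1

    def test_preconditions_enforced(self):
        a = self._sample(np.ones((4, 4, 3)), ihc=2, fish=1)
        wrong_fish = self._sample(np.ones((4, 4, 3)), ihc=1, fish=0)
        with pytest.raises(ValueError, match="FISH"):
            paste_synthesize(a, wrong_fish, seed=0)
        higher = self._sample(np.ones((4, 4, 3)), ihc=2, fish=1)
        with pytest.raises(ValueError, match="strictly below"):
            paste_synthesize(a, higher, seed=0)


class TestTraining:
    @pytest.fixture(scope="class")
    def eight_sample_fit(self):
        cfg = _tiny_cfg(epochs=300, seed=1, dropout_p=0.1, base_width=8,
                        stage_blocks=(1, 1), batch_size=8)
        slides = synth_cohort(n_per_class=4, seed=5, grid=(8, 8))
        # pick 8 samples covering all IHC classes and both FISH labels
        chosen = [s for s in slides if s.ihc_class in (0, 2)][:5]
        chosen += [s for s in slides if s.ihc_class == 1][:3]
        samples = [
            SlideSample(
                canvas=canvas_embed(s.gmap, cfg),
                ihc_label=s.ihc_class,
                fish_label=s.fish_label,
                fold_id=0,
            )
            for s in chosen
        ]
        assert len({s.fish_label for s in samples}) == 2
        net = MultitaskCNN(cfg).fit(samples)
        return net, samples

    def test_overfits_eight_samples(self, eight_sample_fit):
        net, samples = eight_sample_fit
        ihc_ok = fish_ok = 0
        for s in samples:
            pred = net.predict_sample(s)
            ihc_ok += pred.ihc_class == s.ihc_label
            fish_ok += pred.fish_class == s.fish_label
        assert ihc_ok == len(samples)
        assert fish_ok == len(samples)

    def test_loss_decreases_early(self, eight_sample_fit):
        net, _ = eight_sample_fit
        losses = [h["loss"] for h in net.history]
        first = np.mean(losses[:3])
        later = np.mean(losses[7:10])
        assert later <= first

    def test_history_lr_follows_cosine(self, eight_sample_fit):
        net, _ = eight_sample_fit
        assert net.history[0]["lr"] == pytest.approx(0.001)
        assert net.history[-1]["lr"] <= 1e-7

    def test_loss_is_sum_of_heads(self, eight_sample_fit):
        net, _ = eight_sample_fit
        for h in net.history:
            assert h["loss"] == pytest.approx(h["loss_ihc"] + h["loss_fish"], abs=1e-12)

    def test_prediction_deterministic(self, eight_sample_fit):
        net, samples = eight_sample_fit
        p1 = net.predict_sample(samples[0])
        p2 = net.predict_sample(samples[0])
        np.testing.assert_array_equal(p1.ihc_scores, p2.ihc_scores)
        assert p1.fish_score == p2.fish_score

    def test_all_zero_map_valid_prediction(self, eight_sample_fit):
        net, _ = eight_sample_fit
        zero = SlideSample(canvas=np.zeros((24, 24, 3), np.float32), ihc_label=None, fish_label=None)
        pred = net.predict_sample(zero)
        assert np.all((pred.ihc_scores > 0) & (pred.ihc_scores < 1))
        assert 0 < pred.fish_score < 1

    def test_checkpoint_round_trip(self, eight_sample_fit, tmp_path):
        """Saved and reloaded models give bit-identical predictions."""
        net, samples = eight_sample_fit
        net.save(tmp_path / "model.npz")
        back = MultitaskCNN.load(tmp_path / "model.npz")
        for s in samples[:3]:
            p1, p2 = net.predict_sample(s), back.predict_sample(s)
            np.testing.assert_array_equal(p1.ihc_scores, p2.ihc_scores)
            assert p1.fish_score == p2.fish_score

    def test_untrained_model_rejects_predict(self):
        net = MultitaskCNN(_tiny_cfg())
        with pytest.raises(RuntimeError):
            net.predict_sample(SlideSample(np.zeros((24, 24, 3), np.float32), None, None))

    def test_degenerate_labels_rejected(self):
        cfg = _tiny_cfg()
        samples = [
            SlideSample(np.zeros((24, 24, 3), np.float32), ihc_label=1, fish_label=1)
            for _ in range(4)
        ]
        with pytest.raises(ValueError):
            MultitaskCNN(cfg).fit(samples)


class TestConfig:
    def test_reference_defaults(self):
        cfg = TrainConfig()
        assert cfg.base_lr == 0.001 and cfg.min_lr == 1e-8
        assert cfg.canvas == 680 and cfg.crop == 512
        assert cfg.base_width == 64 and cfg.stage_blocks == (2, 2, 2, 2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(base_lr=1e-9)  # min_lr not below base_lr
        with pytest.raises(ValueError):
            TrainConfig(canvas=100, crop=200)

    def test_desk_config_keeps_crop_ratio(self):
        ref, desk = TrainConfig(), desk_config()
        assert desk.crop / desk.canvas == pytest.approx(ref.crop / ref.canvas, abs=0.01)
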