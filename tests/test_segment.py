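"""Segmentation: baseline threshold, feature stacks, boosted classifier."""

import numpy as np
import pytest

from slitmosaic.segment import (
    SCENARIO_PLANES,
    BoostingConfig,
    SlitSegmenter,
    extract_features,
    load_model,
    predict_mask,
    richa_baseline_mask,
    save_model,
    train_classifier,
)


def _rgb(r, g, b, shape=(8, 8)):
    img = np.empty((*shape, 3))
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img


class TestRichaBaseline:
    @pytest.mark.parametrize(
        "r,g,expected",
        [
            (1.0, 0.0, True),  # pure red: clearly foreground
            (0.0, 1.0, False),  # pure green: negative score
            (0.70, 1.00, False),  # exactly on the r = 0.7 g boundary: strict
        ],
    )
    def test_threshold_rule(self, r, g, expected):
        mask = richa_baseline_mask(_rgb(r, g, 0.5))
        assert bool(mask.binary.all()) is expected

    def test_matches_direct_evaluation_on_random_images(self, rng):
        img = rng.random((32, 40, 3))
        mask = richa_baseline_mask(img)
        expected = img[..., 0] - 0.7 * img[..., 1] > 0
        np.testing.assert_array_equal(mask.binary, expected)
        np.testing.assert_array_equal(mask.votes, expected.astype(float))


class TestFeatureStacks:
    @pytest.mark.parametrize("scenario,planes", sorted(SCENARIO_PLANES.items()))
    def test_plane_counts(self, scenario, planes, short_loop):
        stack = extract_features(short_loop.frames[0], scenario)
        assert stack.shape[-1] == planes

    def test_downscaled_resolution(self, short_loop):
        h, w = short_loop.frames[0].shape
        stack = extract_features(short_loop.frames[0], "A")
        assert stack.shape[:2] == (-(-h // 4), -(-w // 4))  # ceil division

    def test_xy_planes_normalized(self):
        img = _rgb(0.5, 0.5, 0.5, shape=(16, 24))
        stack = extract_features(img, "B", downscale_factor=1)
        x_plane, y_plane = stack[..., 9], stack[..., 10]
        assert np.all(x_plane[:, 0] == 0.0) and np.all(x_plane[:, -1] == 1.0)
        assert np.all(y_plane[0, :] == 0.0) and np.all(y_plane[-1, :] == 1.0)
        # constant down each column / along each row
        assert np.ptp(x_plane, axis=0).max() == 0.0
        assert np.ptp(y_plane, axis=1).max() == 0.0

    def test_unknown_scenario(self, short_loop):
        with pytest.raises(ValueError, match="scenario"):
            extract_features(short_loop.frames[0], "D")

    def test_planes_bounded(self, short_loop):
        stack = extract_features(short_loop.frames[0], "C")
        assert stack.min() >= 0.0 and stack.max() <= 1.0


class TestBoostingConfig:
    def test_defaults(self):
        cfg = BoostingConfig()
        assert (cfg.rounds, cfg.shrinkage, cfg.subsample, cfg.max_depth,
                cfg.downscale_factor) == (200, 0.1, 0.5, 3, 4)

    def test_validation(self):
        with pytest.raises(ValueError):
            BoostingConfig(rounds=0)
        with pytest.raises(ValueError):
            BoostingConfig(subsample=1.5)


class TestTraining:
    def test_separable_in_red_gives_perfect_training_auc(self, fast_boost, rng):
        from slitmosaic.evaluate import roc_auc

        frames, masks = [], []
        for _ in range(2):
            # 4x4-blocky labels so the 4x downscale keeps classes pure
            m = np.kron(rng.random((4, 4)) > 0.5, np.ones((4, 4), bool))
            img = np.where(m[..., None], [0.9, 0.1, 0.1], [0.1, 0.9, 0.1])
            img += rng.normal(0, 0.01, img.shape)
            frames.append(np.clip(img, 0, 1))
            masks.append(m)
        seg = train_classifier(frames, masks, "A", fast_boost)
        votes = np.concatenate([seg.predict_votes(f).ravel() for f in frames])
        labels = np.concatenate([m[::4, ::4].ravel() for m in masks])  # blocky
        assert roc_auc(votes, labels).auc == 1.0

    def test_single_class_rejected(self, fast_boost):
        frames = [np.full((16, 16, 3), 0.5)] * 2
        masks = [np.zeros((16, 16), bool)] * 2
        with pytest.raises(ValueError, match="single class"):
            train_classifier(frames, masks, "A", fast_boost)

    def test_too_few_frames_rejected(self, fast_boost):
        with pytest.raises(ValueError, match="2"):
            train_classifier([np.full((8, 8, 3), 0.5)], [np.ones((8, 8), bool)], "A", fast_boost)

    def test_deterministic_votes_under_seed(self, short_sweep, fast_boost):
        frames = short_sweep.frames[:4]
        masks = short_sweep.true_masks[:4]
        v1 = train_classifier(frames, masks, "B", fast_boost).predict_votes(frames[0])
        v2 = train_classifier(frames, masks, "B", fast_boost).predict_votes(frames[0])
        np.testing.assert_array_equal(v1, v2)

    def test_votes_within_unit_interval(self, short_sweep, fast_boost):
        seg = train_classifier(short_sweep.frames[:4], short_sweep.true_masks[:4],
                               "B", fast_boost)
        v = seg.predict_votes(short_sweep.frames[4])
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_untrained_predict_raises(self):
        with pytest.raises(RuntimeError, match="train"):
            SlitSegmenter("A").predict_votes(np.full((8, 8, 3), 0.5))

    def test_model_round_trip(self, tmp_path, short_sweep, fast_boost):
        seg = train_classifier(short_sweep.frames[:4], short_sweep.true_masks[:4],
                               "B", fast_boost)
        save_model(seg, tmp_path / "model.joblib")
        loaded = load_model(tmp_path / "model.joblib")
        np.testing.assert_array_equal(
            seg.predict_votes(short_sweep.frames[4]),
            loaded.predict_votes(short_sweep.frames[4]),
        )


class _StubSegmenter(SlitSegmenter):
    """Returns a fixed vote map; lets mask post-processing be tested in
    isolation from training."""

    def __init__(self, votes):
        super().__init__("A", BoostingConfig())
        self._votes = votes

    def predict_votes(self, frame):
        return self._votes


class TestPredictMask:
    def test_all_one_votes_full_mask(self):
        votes = np.ones((8, 8))
        frame = np.full((32, 32, 3), 0.5)
        for thr in (0.1, 0.5, 0.9):
            m = predict_mask(_StubSegmenter(votes), frame, threshold=thr)
            assert m.binary.all()
            assert m.binary.shape == (32, 32)

    def test_all_zero_votes_empty_mask(self):
        m = predict_mask(_StubSegmenter(np.zeros((8, 8))), np.full((32, 32, 3), 0.5))
        assert not m.binary.any()

    def test_isolated_spike_suppressed_by_smoothing(self):
        votes = np.zeros((9, 9))
        votes[4, 4] = 1.0
        frame = np.full((36, 36, 3), 0.5)
        m = predict_mask(_StubSegmenter(votes), frame, threshold=0.5, smoothing_scale=1.0)
        # a Gaussian of scale >= 1 spreads the unit spike below the threshold
        assert not m.binary.any()

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            predict_mask(_StubSegmenter(np.zeros((4, 4))), np.full((16, 16, 3), 0.5),
                         threshold=1.0)

    def test_binary_idempotent_under_rethreshold(self, rng):
        frame = np.full((32, 32, 3), 0.5)
        votes = rng.random((8, 8))
        m1 = predict_mask(_StubSegmenter(votes), frame, smoothing_scale=0.0)
        # feeding the binarized votes back through the chain changes nothing
        m2 = predict_mask(_StubSegmenter(m1.votes >= 0.5), frame, smoothing_scale=0.0)
        np.testing.assert_array_equal(m1.binary, m2.binary)
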