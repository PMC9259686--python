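"""ScoreCAM mechanics with stubbed models, thresholding contracts, and a
reference training run on a separable toy problem."""

import numpy as np
import pytest

from artseg import nn, weak_supervision as ws
from artseg.metrics import pixel_metrics
from _stubs import StubCAMModel
from artseg.weak_supervision import (ActivationStack, ClassifierConfig,
                                     SaliencyMap, binarize_map,
                                     combine_scorecam, make_pseudolabels,
                                     scorecam_map, select_threshold,
                                     upscale_normalize)


class TestScoreCAM:
    def test_zero_activation_stack_gives_zero_map(self):
        model = StubCAMModel(np.zeros((3, 4, 4)), [0.9], input_size=8)
        sal = scorecam_map(model, np.random.default_rng(0).random((8, 8)))
        assert not sal.values.any()

    def test_weighted_relu_sum_matches_per_pixel_oracle(self):
        """K=2 known 4x4 maps at input size 4 with scripted weights 0.8 and
        0.1: output must equal the hand-computed normalised ReLU sum."""
        rng = np.random.default_rng(1)
        maps = rng.random((2, 4, 4))
        w = np.array([0.8, 0.1])
        model = StubCAMModel(maps, [0.8, 0.1], input_size=4)
        image = rng.random((4, 4))
        sal = scorecam_map(model, image)

        # independent per-pixel oracle (no upscaling needed at equal size)
        oracle = np.zeros((4, 4))
        for k in range(2):
            m = maps[k]
            norm = (m - m.min()) / (m.max() - m.min())
            oracle += w[k] * norm
        oracle = np.maximum(oracle, 0)
        oracle = (oracle - oracle.min()) / (oracle.max() - oracle.min())
        np.testing.assert_allclose(sal.values, oracle, atol=1e-6)

    def test_output_shape_equals_input_shape(self):
        model = StubCAMModel(np.random.default_rng(2).random((3, 4, 4)), [0.5],
                             input_size=16)
        img = np.random.default_rng(3).random((24, 24))
        sal = scorecam_map(model, img)
        assert sal.values.shape == img.shape

    def test_map_order_invariance(self):
        rng = np.random.default_rng(4)
        maps = rng.random((3, 4, 4))
        probs = [0.7, 0.2, 0.5]
        a = scorecam_map(StubCAMModel(maps, probs, 4), np.ones((4, 4)))
        perm = [2, 0, 1]
        b = scorecam_map(StubCAMModel(maps[perm], [probs[i] for i in perm], 4),
                         np.ones((4, 4)))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_constant_map_normalises_to_zero(self):
        stack = ActivationStack(maps=np.full((1, 4, 4), 3.3), source_layer_id="x")
        out = upscale_normalize(stack, (8, 8))
        assert not out.any()

    def test_saliency_bounds(self):
        rng = np.random.default_rng(5)
        out = combine_scorecam(rng.random((4, 8, 8)).astype(np.float32),
                               rng.random(4))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestBinarize:
    def test_zero_map_at_default_threshold(self):
        sal = SaliencyMap(values=np.zeros((5, 5), dtype=np.float32))
        assert not binarize_map(sal, 0.05).any()

    def test_default_pseudolabel_threshold_is_in_default_grid(self):
        assert ws.DEFAULT_PSEUDOLABEL_THRESHOLD == 0.05
        assert 0.05 in ws.DEFAULT_THRESHOLD_GRID

    def test_strict_inequality_enumeration(self):
        vals = np.array([[0.0, 0.04, 0.05], [0.06, 0.2, 1.0], [0.05, 0.049, 0.51]],
                        dtype=np.float32)
        mask = binarize_map(SaliencyMap(values=vals), 0.05)
        oracle = sum(1 for v in vals.ravel() if v > 0.05)
        assert int(mask.sum()) == oracle
        assert not mask[0, 2]       # exactly at threshold stays negative

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_map(np.zeros((2, 2)), 1.5)


class TestSelectThreshold:
    def test_tie_break_returns_smallest(self):
        gt = np.zeros((6, 6), dtype=bool)
        gt[1:4, 1:4] = True
        perfect = gt.astype(np.float32)
        best, table = select_threshold([perfect], [gt], grid=[0.25, 0.5, 0.75])
        assert best == 0.25
        assert all(row["mean_iou"] == 1.0 for row in table)

    def test_matches_exhaustive_sweep_oracle(self, rng):
        for _ in range(20):
            maps = [rng.random((8, 8)).astype(np.float32) for _ in range(4)]
            gts = [rng.random((8, 8)) > 0.5 for _ in range(4)]
            grid = sorted(rng.random(5).tolist())
            best, table = select_threshold(maps, gts, grid=grid)
            # oracle: recompute every mean IoU from scratch
            oracle_best, oracle_iou = None, -np.inf
            for t in grid:
                ious = []
                for m, g in zip(maps, gts):
                    r = pixel_metrics(m > t, g)
                    if r.iou is not None:
                        ious.append(r.iou)
                mi = np.mean(ious) if ious else -np.inf
                if mi > oracle_iou:
                    oracle_iou, oracle_best = mi, t
            assert best == oracle_best
            for row, t in zip(table, grid):
                assert row["threshold"] == pytest.approx(t)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([], [], grid=[0.5])


class TestPseudoLabels:
    def test_clean_images_get_zero_masks_and_counts_match(self):
        maps = np.random.default_rng(6).random((2, 8, 8))
        model = StubCAMModel(maps, [0.9, 0.4], input_size=8)
        images = [np.random.default_rng(i).random((8, 8)) for i in range(3)]
        labels = ["clean", "artifact", "clean"]
        masks = make_pseudolabels(model, images, labels, threshold=0.5)
        assert masks.shape == (3, 8, 8)
        assert not masks[0].any() and not masks[2].any()

    def test_artifact_mask_equals_binarized_scorecam(self):
        maps = np.random.default_rng(7).random((2, 8, 8))
        img = np.random.default_rng(8).random((8, 8))
        m1 = StubCAMModel(maps, [0.9, 0.4], input_size=8)
        masks = make_pseudolabels(m1, [img], ["artifact"], threshold=0.3)
        m2 = StubCAMModel(maps, [0.9, 0.4], input_size=8)
        expected = binarize_map(scorecam_map(m2, img), 0.3)
        np.testing.assert_array_equal(masks[0], expected)

    def test_unlabeled_image_rejected(self):
        model = StubCAMModel(np.zeros((1, 4, 4)), [0.5], input_size=4)
        with pytest.raises(ValueError):
            make_pseudolabels(model, [np.zeros((4, 4))], ["unknown"], 0.05)


class TestClassifierTraining:
    def test_single_class_training_rejected(self):
        imgs = [np.random.default_rng(i).random((16, 16)) for i in range(4)]
        with pytest.raises(ValueError):
            ws.train_classifier(imgs, ["clean"] * 4, imgs[:2], ["clean", "artifact"],
                                ClassifierConfig(input_size=16),
                                nn.TrainConfig(epochs=2, lr_patience_epochs=1))

    def test_probabilities_normalised_and_deterministic(self):
        cfg = ClassifierConfig(input_size=16, seed=0)
        model = ws.build_classifier(cfg)
        img = np.random.default_rng(9).random((16, 16))
        p1 = ws.classify(model, img)
        p2 = ws.classify(model, img)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_array_equal(p1, p2)
        batch = ws.classify_batch(model, [img, img])
        np.testing.assert_allclose(batch[0], batch[1], atol=1e-7)

    def test_separable_toy_dataset_learned(self):
        """Bright textured disk vs blank background: a reference run on 60
        training images must reach >= 0.95 training accuracy and >= 0.9
        held-out image-level F1."""
        rng = np.random.default_rng(10)
        size = 32

        def sample(with_disk: bool):
            img = rng.normal(0.2, 0.02, (size, size))
            if with_disk:
                cy, cx = rng.integers(10, 22, 2)
                yy, xx = np.mgrid[0:size, 0:size]
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= 36
                img[disk] += 0.6 + rng.normal(0, 0.1, int(disk.sum()))
            return img

        train = [sample(i % 2 == 0) for i in range(60)]
        train_labels = ["artifact" if i % 2 == 0 else "clean" for i in range(60)]
        val = [sample(i % 2 == 0) for i in range(16)]
        val_labels = ["artifact" if i % 2 == 0 else "clean" for i in range(16)]
        test = [sample(i % 2 == 0) for i in range(20)]
        test_labels = ["artifact" if i % 2 == 0 else "clean" for i in range(20)]

        model, hist = ws.train_classifier(
            train, train_labels, val, val_labels,
            ClassifierConfig(input_size=size, seed=0),
            nn.TrainConfig(epochs=12, lr_patience_epochs=4, batch_size=8, seed=0))
        assert len(hist.train_loss) <= 12

        probs = ws.classify_batch(model, train)
        acc = np.mean((probs[:, 1] > 0.5) == (np.array(train_labels) == "artifact"))
        assert acc >= 0.95

        probs = ws.classify_batch(model, test)
        pred = ["artifact" if p > 0.5 else "clean" for p in probs[:, 1]]
        from artseg.metrics import image_level_f1
        assert image_level_f1(pred, test_labels).f1 >= 0.9


def test_classifier_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(backbone_preset="resnet")
    with pytest.raises(ValueError):
        ClassifierConfig(input_size=30)     # not divisible by 8
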