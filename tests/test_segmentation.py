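"""Losses, ensemble averaging, stitching, training, slide inference."""

import numpy as np
import pytest

from wsikit.wsi_core import LevelPoint
from wsikit.patches import PatchGrid, build_inference_grid
from wsikit.segmentation import (
    ConstantPredictor,
    GroundTruthPredictor,
    LossWeights,
    MiniFCN,
    TrainingSchedule,
    cross_entropy_loss,
    dice_loss,
    ensemble_predict,
    hybrid_loss,
    run_slide_inference,
    stitch_heatmap,
    train_segmentation_model,
)


class TestLosses:
    def test_perfect_prediction_has_zero_dice_loss(self):
        g = np.zeros((8, 8))
        g[2:5, 2:5] = 1
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_complement_prediction_has_unit_dice_loss(self):
        g = np.zeros((8, 8))
        g[:4] = 1
        assert dice_loss(1 - g, g) == pytest.approx(1.0, abs=1e-6)

    def test_dice_loss_closed_form(self):
        # p=[0.5,0.5], g=[1,0]: 1 - (2*0.5)/(0.25+0.25+1) = 1/3
        val = dice_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert val == pytest.approx(1 / 3, abs=1e-5)

    def test_cross_entropy_at_half_is_ln2(self):
        p = np.full((16, 16), 0.5)
        g = np.zeros((16, 16))
        assert cross_entropy_loss(p, g) == pytest.approx(np.log(2), abs=1e-9)

    def test_cross_entropy_closed_form(self):
        val = cross_entropy_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
        assert val == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_cross_entropy_zero_for_perfect_binary(self):
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(g, g) == pytest.approx(0.0, abs=1e-5)

    def test_hybrid_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, (6, 6))
        g = (rng.uniform(size=(6, 6)) > 0.5).astype(float)
        w = LossWeights(alpha=1.0, beta=0.0, gamma=0.0)
        assert hybrid_loss(p, g, w) == pytest.approx(cross_entropy_loss(p, g))

    def test_hybrid_default_weights_and_zero_at_perfect(self):
        w = LossWeights()
        assert (w.alpha, w.beta, w.gamma) == (0.5, 0.25, 0.25)
        g = np.zeros((8, 8))
        g[3:6, 3:6] = 1
        assert hybrid_loss(g, g, w) == pytest.approx(0.0, abs=1e-5)

    def test_hybrid_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0, 1, (5, 5))
            g = (rng.uniform(size=(5, 5)) > 0.5).astype(float)
            assert hybrid_loss(p, g) >= 0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestEnsemblePredict:
    def test_single_model_identity(self, rng):
        patch = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        m = ConstantPredictor(0.3)
        assert np.array_equal(ensemble_predict([m], patch), m.predict(patch))

    def test_mean_of_constants(self, rng):
        patch = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        out = ensemble_predict([ConstantPredictor(0.2), ConstantPredictor(0.8)], patch)
        assert np.allclose(out, 0.5)

    def test_identical_members_equal_single(self, rng):
        patch = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        m = ConstantPredictor(0.7)
        assert np.allclose(ensemble_predict([m, m, m], patch), m.predict(patch))

    def test_no_models_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], np.zeros((4, 4, 3), np.uint8))


def _grid_of(centers, patch_size, stride=None):
    return PatchGrid([LevelPoint(x, y, 0) for x, y in centers],
                     patch_size, stride or patch_size, 0)


class TestStitchHeatmap:
    def test_constant_maps_give_constant_heatmap(self):
        grid = _grid_of([(8, 8), (24, 8)], 16)
        maps = [np.full((16, 16), 0.4)] * 2
        hm = stitch_heatmap(grid, maps, (32, 16))
        assert np.allclose(hm.prob[hm.count > 0], 0.4)
        assert (hm.count[:, :32] > 0).all()

    def test_half_overlap_averages_two_constants(self):
        grid = _grid_of([(8, 8), (16, 8)], 16, stride=8)
        maps = [np.full((16, 16), 0.2), np.full((16, 16), 0.8)]
        hm = stitch_heatmap(grid, maps, (24, 16))
        # overlap strip x in [8, 16): mean of the two constants
        assert np.allclose(hm.prob[:, 8:16], 0.5)
        assert np.allclose(hm.prob[:, :8], 0.2)
        assert np.allclose(hm.prob[:, 16:24], 0.8)

    def test_matches_brute_force_pixel_mean_oracle(self, rng):
        """Random maps on a random grid: every pixel equals the mean of all
        patch predictions covering it (20 instances, tol 1e-12)."""
        for trial in range(20):
            trng = np.random.default_rng(trial)
            w = h = int(trng.integers(64, 160))
            ps = int(trng.choice([16, 32]))
            stride = ps // 2
            n = int(trng.integers(3, 12))
            centers = [
                (int(trng.integers(0, w)), int(trng.integers(0, h)))
                for _ in range(n)
            ]
            maps = [trng.uniform(size=(ps, ps)) for _ in range(n)]
            hm = stitch_heatmap(_grid_of(centers, ps, stride), maps, (w, h))

            acc = np.zeros((h, w))
            cnt = np.zeros((h, w))
            for (cx, cy), pm in zip(centers, maps):
                for py in range(ps):
                    for px in range(ps):
                        x, y = cx - ps // 2 + px, cy - ps // 2 + py
                        if 0 <= x < w and 0 <= y < h:
                            acc[y, x] += pm[py, px]
                            cnt[y, x] += 1
            expected = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
            assert np.abs(hm.prob - expected).max() < 1e-12
            assert np.array_equal(hm.count, cnt.astype(np.int64))

    def test_count_mismatch_rejected(self):
        grid = _grid_of([(8, 8)], 16)
        with pytest.raises(ValueError):
            stitch_heatmap(grid, [], (32, 32))

    def test_range_invariant(self, rng):
        centers = [(int(rng.integers(0, 64)), int(rng.integers(0, 64))) for _ in range(6)]
        maps = [rng.uniform(size=(16, 16)) for _ in range(6)]
        hm = stitch_heatmap(_grid_of(centers, 16), maps, (64, 64))
        assert hm.prob.min() >= 0.0 and hm.prob.max() <= 1.0

    def test_stitching_is_linear(self, rng):
        centers = [(20, 20), (28, 20), (20, 28)]
        A = [rng.uniform(size=(16, 16)) for _ in range(3)]
        B = [rng.uniform(size=(16, 16)) for _ in range(3)]
        grid = _grid_of(centers, 16)
        lhs = stitch_heatmap(grid, [0.3 * a + 0.7 * b for a, b in zip(A, B)], (48, 48))
        sa = stitch_heatmap(grid, A, (48, 48))
        sb = stitch_heatmap(grid, B, (48, 48))
        assert np.allclose(lhs.prob, 0.3 * sa.prob + 0.7 * sb.prob, atol=1e-6)


class TestSlideInference:
    def test_constant_predictor_covers_tissue_only(self, small_slide):
        hm = run_slide_inference(
            small_slide.image, [ConstantPredictor(0.7)],
            patch_size=128, stride=64, mask_level=1, out_level=1,
        )
        tissue = small_slide.tissue_mask_at(1)[: hm.prob.shape[0], : hm.prob.shape[1]]
        covered = hm.count > 0
        assert np.allclose(hm.prob[covered], 0.7, atol=1e-6)
        # tissue is covered; far-from-tissue glass is not
        assert covered[tissue].mean() > 0.99
        assert hm.prob[~covered].max() == 0.0

    def test_oracle_predictor_recovers_tumor_mask(self, small_slide):
        hm = run_slide_inference(
            small_slide.image, [GroundTruthPredictor(small_slide.tumor_mask)],
            patch_size=128, stride=64, mask_level=0, out_level=0,
        )
        pred = hm.prob > 0.5
        gt = small_slide.tumor_mask
        iou = (pred & gt).sum() / (pred | gt).sum()
        assert iou >= 0.95

    def test_grid_order_invariance(self, small_slide, small_tissue_l0):
        """Stitching a permuted patch order gives the identical heatmap."""
        from wsikit.segmentation import ensemble_predict, stitch_heatmap

        img = small_slide.image
        grid = build_inference_grid(small_tissue_l0, 128, 64)
        models = [GroundTruthPredictor(small_slide.tumor_mask)]
        probs = [ensemble_predict(models, img.read_region(c, 128, 0), c) for c in grid.centers]
        fwd = stitch_heatmap(grid, probs, (img.width0, img.height0))
        perm = np.random.default_rng(0).permutation(len(grid.centers))
        pgrid = PatchGrid([grid.centers[i] for i in perm], 128, 64, 0)
        rev = stitch_heatmap(pgrid, [probs[i] for i in perm], (img.width0, img.height0))
        assert np.allclose(fwd.prob, rev.prob, atol=1e-6)


def _training_pairs(slide, n_per_class, patch_size, seed):
    from wsikit.patches import extract_training_coordinates
    from wsikit.tissue import compute_tissue_mask

    tissue = compute_tissue_mask(slide.image.levels[1], level=1)
    coords, _ = extract_training_coordinates(
        tissue, slide.tumor_mask, n_per_class, patch_size=patch_size,
        seed=seed, mask_downsample=4,
    )
    oracle = GroundTruthPredictor(slide.tumor_mask)
    pairs = []
    for c in coords:
        patch = slide.image.read_region(c.center, patch_size, 0)
        pairs.append((patch, oracle.predict(patch, c.center)))
    order = np.random.default_rng(seed).permutation(len(pairs))
    return [pairs[i] for i in order]


class TestTraining:
    SCHEDULE = TrainingSchedule(max_epochs=4, learning_rate=3e-3, patience=2, seed=0)

    def test_loss_decreases(self, small_slide):
        pairs = _training_pairs(small_slide, 12, 64, seed=2)
        model = MiniFCN(channels=6, seed=0)
        _, hist = train_segmentation_model(model, pairs[:18], pairs[18:], schedule=self.SCHEDULE)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_training_is_deterministic(self, small_slide):
        pairs = _training_pairs(small_slide, 8, 64, seed=2)
        hists = []
        for _ in range(2):
            model = MiniFCN(channels=4, seed=1)
            _, hist = train_segmentation_model(
                model, pairs[:12], pairs[12:], schedule=self.SCHEDULE
            )
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_segmentation_model(MiniFCN(channels=4), [], [])

    def test_encoder_frozen_during_warmup(self, small_slide):
        pairs = _training_pairs(small_slide, 4, 64, seed=3)
        model = MiniFCN(channels=4, seed=0)
        model.pretrained_encoder = True
        enc_before = model.enc1.W.copy()
        schedule = TrainingSchedule(max_epochs=1, learning_rate=1e-2,
                                    freeze_encoder_epochs=2, patience=5, seed=0)
        train_segmentation_model(model, pairs, [], schedule=schedule)
        assert np.array_equal(model.enc1.W, enc_before)  # epoch 1: frozen
        model2 = MiniFCN(channels=4, seed=0)
        model2.pretrained_encoder = False
        train_segmentation_model(model2, pairs, [], schedule=schedule)
        assert not np.array_equal(model2.enc1.W, enc_before)


class TestBundleIO:
    def test_save_load_round_trip(self, tmp_path, rng):
        from wsikit.segmentation import load_model_bundle, save_model_bundle

        models = [MiniFCN(channels=4, seed=s) for s in (0, 1)]
        save_model_bundle(tmp_path / "bundle", models, patch_size=64)
        loaded, meta = load_model_bundle(tmp_path / "bundle")
        assert meta["patch_size"] == 64 and len(loaded) == 2
        patch = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        for a, b in zip(models, loaded):
            assert np.allclose(a.predict(patch), b.predict(patch))
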