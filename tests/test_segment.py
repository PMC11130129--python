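"""Fat segmenters: k-means color clustering and the encoder-decoder net."""

import numpy as np
import pytest

import imfquant as q
from imfquant.errors import (ConfigurationError, DegenerateClusteringError,
                             EmptyMaskError, ModelStateError)
from imfquant.nn import SegNetLite, bce_with_logits
from imfquant.segment import _tile_grid, extract_tiles


class TestKMeans:
    def test_three_flat_colors_exact_partition(self):
        img = np.zeros((30, 30, 3), dtype=np.uint8)
        img[:10] = (250, 250, 250)   # fat-like white
        img[10:20] = (225, 150, 170)  # eosin pink
        img[20:] = (60, 40, 90)      # dark
        hull = np.ones((30, 30), dtype=bool)
        pred = q.kmeans_fat(img, hull, q.KMeansConfig(seed=0))
        assert pred.fat[:10].all()
        assert not pred.fat[10:].any()

    def test_clean_section_dice(self, clean_section):
        _, hull = q.tissue_pipeline(clean_section.image)
        pred = q.kmeans_fat(clean_section.image, hull, q.KMeansConfig(seed=0))
        assert q.dice(pred.fat, clean_section.truth_fat) >= 0.7

    def test_crack_causes_overdetection(self, crack_sections):
        sec = crack_sections[0]
        tissue, hull = q.tissue_pipeline(sec.image)
        pred = q.kmeans_fat(sec.image, hull, q.KMeansConfig(seed=0))
        cross = q.cross_section_mask(tissue, pred.fat, hull)
        assert q.fat_fraction(pred.fat, cross, hull) > q.realized_fat_fraction(sec)

    def test_seed_invariant_fat_selection(self, clean_section):
        """The fat cluster is picked by centroid lightness, not label index."""
        _, hull = q.tissue_pipeline(clean_section.image)
        a = q.kmeans_fat(clean_section.image, hull, q.KMeansConfig(seed=0))
        b = q.kmeans_fat(clean_section.image, hull, q.KMeansConfig(seed=99))
        assert q.dice(a.fat, b.fat) > 0.99

    def test_prediction_subset_of_hull(self, clean_section):
        _, hull = q.tissue_pipeline(clean_section.image)
        pred = q.kmeans_fat(clean_section.image, hull)
        assert not (pred.fat & ~hull).any()

    def test_degenerate_colors_raise(self):
        img = np.full((20, 20, 3), 128, dtype=np.uint8)
        with pytest.raises(DegenerateClusteringError):
            q.kmeans_fat(img, np.ones((20, 20), bool), q.KMeansConfig(seed=0))

    def test_empty_hull_raises(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        with pytest.raises(EmptyMaskError):
            q.kmeans_fat(img, np.zeros((20, 20), bool))


class TestArchitecture:
    def test_bottleneck_spatial_size(self):
        m = SegNetLite(depth=3, channels=(4, 4, 4), seed=0)
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        _, cache = m.forward(x, want_cache=True)
        assert cache["pool2_idx"].shape[-2:] == (64 // 8, 64 // 8)

    def test_depth_one_has_single_pool_pair(self):
        m = SegNetLite(depth=1, channels=(8,), seed=0)
        pools = [k for k in m.params if k.startswith("e")]
        assert sorted(pools) == ["e0a_W", "e0a_b", "e0b_W", "e0b_b"]
        x = np.random.default_rng(0).random((1, 3, 16, 16))
        _, cache = m.forward(x, want_cache=True)
        assert [k for k in cache if k.endswith("_idx")] == ["pool0_idx"]

    def test_forward_shape_and_probability_range(self):
        m = SegNetLite(depth=2, channels=(4, 8), seed=1)
        x = np.random.default_rng(1).random((2, 3, 32, 48))
        probs = m.predict_proba(x)
        assert probs.shape == (2, 32, 48)
        assert ((probs > 0) & (probs < 1)).all()

    def test_incompatible_tile_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            q.SegnetConfig(depth=3, channels=(4, 4, 4), tile=100, downsample=1)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = SegNetLite(depth=2, channels=(3, 4), seed=1)
        # move biases off zero: freshly initialized decoder levels see
        # all-zero unpool windows whose pre-activations sit exactly on the
        # ReLU kink, where the one-sided finite difference disagrees with
        # the subgradient convention relu'(0) = 0
        for k, p in m.params.items():
            if k.endswith("_b"):
                m.params[k] = rng.normal(0, 0.05, p.shape)
        x = rng.random((2, 3, 8, 8))
        y = (rng.random((2, 8, 8)) > 0.7).astype(float)
        logits, cache = m.forward(x, want_cache=True)
        _, dlog = bce_with_logits(logits, y, 3.0)
        grads = m.backward(cache, dlog)
        eps = 1e-6
        for name in sorted(m.params):
            p = m.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                l1, _ = bce_with_logits(m.forward(x), y, 3.0)
                p[idx] = orig - eps
                l2, _ = bce_with_logits(m.forward(x), y, 3.0)
                p[idx] = orig
                assert (l1 - l2) / (2 * eps) == pytest.approx(
                    grads[name][idx], abs=1e-7)


class TestTraining:
    def test_same_seed_identical_loss_traces(self, training_sections):
        cfg = q.SegnetConfig(depth=2, channels=(4, 8), tile=48, epochs=2,
                             seed=3, downsample=1)
        tiles = extract_tiles(training_sections[:3], 16, 48, seed=5)
        h1 = q.train_segnet(q.build_segnet(cfg), tiles, cfg).history
        h2 = q.train_segnet(q.build_segnet(cfg), tiles, cfg).history
        assert h1 == h2

    def test_loss_decreases_over_training(self, trained_model):
        h = np.array(trained_model.members[0].history)
        assert h[-1] < 0.2 * h[0]
        # non-increasing within tolerance: Adam shows transient spikes, so
        # compare epoch means over thirds of the schedule
        third = len(h) // 3
        assert h[2 * third:].mean() < h[third:2 * third].mean() < h[:third].mean()

    def test_background_only_input_predicts_no_fat(self, trained_model):
        bg = np.full((1, 3, 48, 48), 247 / 255.0)
        thr = getattr(trained_model, "threshold", 0.5)
        assert (trained_model.predict_proba(bg) >= thr).mean() < 0.01

    def test_empty_tile_set_raises(self, segnet_cfg):
        with pytest.raises(q.DataError):
            q.train_segnet(q.build_segnet(segnet_cfg),
                           (np.empty((0, 3, 48, 48)), np.empty((0, 48, 48))),
                           segnet_cfg)


class TestInference:
    def test_tile_grid_geometry(self):
        assert _tile_grid(512, 256, 256) == [0, 256]
        assert _tile_grid(512, 256, 128) == [0, 128, 256]
        assert _tile_grid(200, 256, 128) == [0]
        assert _tile_grid(300, 256, 128) == [0, 44]

    def test_untrained_model_rejected(self, segnet_cfg, clean_section):
        model = q.build_segnet(segnet_cfg)
        _, hull = q.tissue_pipeline(clean_section.image)
        with pytest.raises(ModelStateError):
            q.segnet_fat(model, clean_section.image, hull, segnet_cfg)

    def test_empty_hull_gives_empty_mask(self, trained_model, segnet_cfg):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        pred = q.segnet_fat(trained_model, img, np.zeros((64, 64), bool),
                            segnet_cfg)
        assert not pred.fat.any()

    def test_mask_clipped_to_hull_and_full_shape(self, trained_model,
                                                 segnet_cfg, clean_section):
        _, hull = q.tissue_pipeline(clean_section.image)
        pred = q.segnet_fat(trained_model, clean_section.image, hull, segnet_cfg)
        assert pred.fat.shape == clean_section.image.shape[:2]
        assert pred.score.shape == pred.fat.shape
        assert not (pred.fat & ~hull).any()

    def test_checkpoint_roundtrip(self, trained_model, segnet_cfg,
                                  clean_section, tmp_path):
        member = trained_model.members[0]
        path = tmp_path / "model.npz"
        member.save(path)
        loaded = SegNetLite.load(path)
        _, hull = q.tissue_pipeline(clean_section.image)
        a = q.segnet_fat(member, clean_section.image, hull, segnet_cfg)
        b = q.segnet_fat(loaded, clean_section.image, hull, segnet_cfg)
        assert np.array_equal(a.fat, b.fat)
        assert loaded.threshold == member.threshold
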