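import dataclasses

import numpy as np
import pytest

from richfuse.image_backbone import (
    FULL_SCALE,
    REDUCED,
    BackboneSpec,
    StageFeatureMap,
    TrainConfig,
    build_backbone,
    global_average_pool,
    multilevel_features,
    multilevel_features_batch,
    stage_outputs,
    train_backbone_classifier,
)
from richfuse.synthetic import TEST_PRESET, generate_image


@pytest.fixture(scope="module")
def tiny_backbone(tiny_backbone_spec):
    return build_backbone(tiny_backbone_spec, seed=0)


class TestSpec:
    def test_full_scale_widths(self):
        assert FULL_SCALE.stage_channels == (64, 128, 256, 512, 512)
        assert FULL_SCALE.convs_per_stage == (2, 2, 3, 3, 3)
        assert FULL_SCALE.multilevel_dim() == 1280

    def test_reduced_multilevel_dim(self):
        spec = BackboneSpec(stage_channels=(8, 16, 16, 32, 32),
                            convs_per_stage=(1, 1, 1, 1, 1), input_side=64)
        assert spec.multilevel_dim() == 16 + 32 + 32 == 80

    def test_input_side_must_be_multiple_of_32(self):
        with pytest.raises(ValueError):
            BackboneSpec(input_side=100)

    def test_wrong_stage_count_errors(self):
        with pytest.raises(ValueError):
            BackboneSpec(stage_channels=(8, 16, 32), convs_per_stage=(1, 1, 1))


class TestBuild:
    def test_same_seed_identical_parameters(self, tiny_backbone_spec):
        a = build_backbone(tiny_backbone_spec, seed=7)
        b = build_backbone(tiny_backbone_spec, seed=7)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_different_seed_differs(self, tiny_backbone_spec):
        a = build_backbone(tiny_backbone_spec, seed=7)
        b = build_backbone(tiny_backbone_spec, seed=8)
        assert not np.array_equal(a.conv_W[0], b.conv_W[0])


class TestStageOutputs:
    @pytest.mark.parametrize("side", [32, 64])
    def test_shape_law(self, side, rng):
        spec = BackboneSpec(stage_channels=(4, 4, 8, 8, 8),
                            convs_per_stage=(1, 1, 1, 1, 1), input_side=side)
        bb = build_backbone(spec, seed=0)
        maps = stage_outputs(bb, rng.random((side, side, 3)))
        for k, m in enumerate(maps, start=1):
            assert m.height == m.width == side // 2 ** (k - 1)
            assert m.channels == spec.stage_channels[k - 1]

    def test_reduced_spec_stage3_side_16_at_64(self, rng):
        spec = BackboneSpec(stage_channels=(8, 16, 16, 32, 32),
                            convs_per_stage=(1, 1, 1, 1, 1), input_side=64)
        bb = build_backbone(spec, seed=0)
        maps = stage_outputs(bb, rng.random((64, 64, 3)))
        assert maps[2].height == 16

    def test_wrong_image_size_errors(self, tiny_backbone, rng):
        with pytest.raises(ValueError):
            stage_outputs(tiny_backbone, rng.random((48, 48, 3)))

    def test_zero_image_zero_biases_gives_zero_maps(self, tiny_backbone_spec):
        bb = build_backbone(tiny_backbone_spec, seed=0)
        for b in bb.conv_b:
            b[:] = 0.0
        maps = stage_outputs(bb, np.zeros((32, 32, 3)))
        for m in maps:
            assert np.all(m.values == 0.0)


class TestGlobalAveragePool:
    def test_constant_map(self):
        m = StageFeatureMap(1, np.full((4, 6, 3), 2.5))
        assert np.allclose(global_average_pool(m), 2.5)

    def test_small_known_case(self):
        m = StageFeatureMap(1, np.array([1.0, 2.0, 3.0, 4.0]).reshape(2, 2, 1))
        assert global_average_pool(m) == pytest.approx([2.5])

    def test_matches_brute_force(self, rng):
        values = rng.random((5, 7, 3))
        pooled = global_average_pool(StageFeatureMap(1, values))
        for c in range(3):
            total = 0.0
            for i in range(5):
                for j in range(7):
                    total += values[i, j, c]
            assert pooled[c] == pytest.approx(total / 35)

    def test_spatial_permutation_invariance(self, rng):
        values = rng.random((4, 4, 2))
        pooled = global_average_pool(StageFeatureMap(1, values))
        flat = values.reshape(16, 2)
        perm = flat[rng.permutation(16)].reshape(4, 4, 2)
        assert np.allclose(global_average_pool(StageFeatureMap(1, perm)), pooled)

    def test_empty_map_errors(self):
        with pytest.raises(ValueError):
            global_average_pool(np.zeros((0, 3, 2)))


class TestMultilevelFeatures:
    def test_reduced_length_80(self, rng):
        spec = BackboneSpec(stage_channels=(8, 16, 16, 32, 32),
                            convs_per_stage=(1, 1, 1, 1, 1), input_side=64)
        bb = build_backbone(spec, seed=0)
        f = multilevel_features(bb, rng.random((64, 64, 3)))
        assert len(f) == 80

    def test_single_stage_width(self, tiny_backbone, rng):
        f = multilevel_features(tiny_backbone, rng.random((32, 32, 3)), {5})
        assert len(f) == tiny_backbone.spec.stage_channels[4]

    def test_length_additivity_over_stage_sets(self, tiny_backbone, rng):
        img = rng.random((32, 32, 3))
        for stages in [(3,), (4, 5), (3, 4, 5), (1, 2, 3, 4, 5)]:
            f = multilevel_features(tiny_backbone, img, stages)
            assert len(f) == tiny_backbone.spec.multilevel_dim(stages)

    def test_concatenation_order_is_ascending(self, tiny_backbone, rng):
        img = rng.random((32, 32, 3))
        f345 = multilevel_features(tiny_backbone, img, (3, 4, 5)).values
        maps = stage_outputs(tiny_backbone, img)
        manual = np.concatenate([global_average_pool(maps[s - 1]) for s in (3, 4, 5)])
        assert np.allclose(f345, manual)

    def test_empty_stage_set_errors(self, tiny_backbone, rng):
        with pytest.raises(ValueError):
            multilevel_features(tiny_backbone, rng.random((32, 32, 3)), ())

    def test_batch_agrees_with_single(self, tiny_backbone, rng):
        imgs = rng.random((3, 32, 32, 3))
        batch = multilevel_features_batch(tiny_backbone, imgs)
        for i in range(3):
            single = multilevel_features(tiny_backbone, imgs[i]).values
            assert np.allclose(batch[i], single, atol=1e-5)


@pytest.fixture(scope="module")
def strong_signal_images():
    params = dataclasses.replace(TEST_PRESET, image_side=64, image_signal=3.0)
    gen = np.random.default_rng(21)
    labels = np.array([i % 2 for i in range(200)])
    imgs = np.stack([
        generate_image("malignant" if lab else "benign", params, gen)
        for lab in labels
    ])
    return imgs, labels


class TestTraining:
    def test_strong_signal_beats_080(self, strong_signal_images):
        imgs, labels = strong_signal_images
        model = train_backbone_classifier(
            imgs[:150], labels[:150], REDUCED,
            TrainConfig(epochs=10, learning_rate=1e-3, batch_size=16), seed=3,
        )
        proba = model.predict_proba(imgs[150:])
        acc = np.mean((proba[:, 1] > 0.5) == labels[150:])
        assert acc > 0.8

    def test_shuffled_labels_near_chance(self, strong_signal_images):
        imgs, labels = strong_signal_images
        shuffled = np.random.default_rng(4).permutation(labels[:150])
        model = train_backbone_classifier(
            imgs[:150], shuffled, REDUCED,
            TrainConfig(epochs=3, learning_rate=1e-3, batch_size=16), seed=3,
        )
        proba = model.predict_proba(imgs[150:])
        acc = np.mean((proba[:, 1] > 0.5) == labels[150:])
        # binomial 3-sigma band around 0.5 at n=50
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 50)

    def test_same_seed_reproducible(self, strong_signal_images, tiny_backbone_spec):
        imgs, labels = strong_signal_images
        imgs32 = imgs[:60, ::2, ::2, :].copy()
        cfg = TrainConfig(epochs=2, learning_rate=1e-3, batch_size=16)
        a = train_backbone_classifier(imgs32, labels[:60], tiny_backbone_spec, cfg, seed=5)
        b = train_backbone_classifier(imgs32, labels[:60], tiny_backbone_spec, cfg, seed=5)
        assert a.history == b.history
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_single_class_errors(self, strong_signal_images, tiny_backbone_spec):
        imgs, _ = strong_signal_images
        imgs32 = imgs[:10, ::2, ::2, :].copy()
        with pytest.raises(ValueError):
            train_backbone_classifier(imgs32, np.zeros(10, dtype=int),
                                      tiny_backbone_spec, TrainConfig(epochs=1), seed=0)
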