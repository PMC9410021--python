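import numpy as np
import pytest

from spine_uda.core_io import BinaryMask, Volume
from spine_uda.detection import (
    DetectionPatchSpec,
    DetectionTrainConfig,
    assemble_prediction,
    extract_detection_patches,
    postprocess_largest_component,
    train_detector,
    weighted_bce,
)

SPEC = DetectionPatchSpec(patch_shape=(16, 16, 24))


class TestExtractPatches:
    def test_test_mode_tiles_reassemble_exactly(self):
        vol = Volume(np.zeros((32, 32, 48)))
        tiles = extract_detection_patches(vol, None, SPEC, mode="test")
        assert len(tiles) == 8  # 2 x 2 x 2
        origins = {t[2] for t in tiles}
        assert origins == {
            (a, b, c) for a in (0, 16) for b in (0, 16) for c in (0, 24)
        }

    def test_train_mode_is_seeded(self, phantom_sample):
        a = extract_detection_patches(phantom_sample.volume, phantom_sample.dense,
                                      SPEC, "train", seed=11)
        b = extract_detection_patches(phantom_sample.volume, phantom_sample.dense,
                                      SPEC, "train", seed=11)
        assert [t[2] for t in a] == [t[2] for t in b]

    def test_train_mode_spine_quota(self, phantom_sample):
        patches = extract_detection_patches(phantom_sample.volume,
                                            phantom_sample.dense, SPEC, "train",
                                            seed=0)
        assert len(patches) == SPEC.patches_per_scan_train
        n_spine = sum(1 for _, lab, _ in patches if lab.any())
        assert n_spine >= SPEC.min_spine_patches

    def test_train_mode_requires_labels(self, phantom_sample):
        with pytest.raises(ValueError, match="source"):
            extract_detection_patches(phantom_sample.volume, None, SPEC, "train")


class TestWeightedBCE:
    def test_perfect_prediction_is_near_zero(self):
        t = np.array([1.0, 0.0, 1.0])
        assert weighted_bce(t, t) < 1e-5

    def test_hand_computed_two_voxel_value(self):
        # pred 0.5 on both voxels, targets {1, 0}, weights (1.0, 0.1)
        val = weighted_bce(np.array([0.5, 0.5]), np.array([1.0, 0.0]), 1.0, 0.1)
        assert val == pytest.approx((1.0 * np.log(2) + 0.1 * np.log(2)) / 2)
        assert val == pytest.approx(0.38123, abs=1e-5)

    def test_unit_weights_reduce_to_plain_bce(self, rng):
        pred = rng.uniform(0.05, 0.95, 200)
        target = (rng.random(200) > 0.5).astype(float)
        plain = float(np.mean(-target * np.log(pred)
                              - (1 - target) * np.log(1 - pred)))
        assert weighted_bce(pred, target, 1.0, 1.0) == pytest.approx(plain)

    def test_permutation_invariance_and_weight_linearity(self, rng):
        pred = rng.uniform(0.05, 0.95, 100)
        target = (rng.random(100) > 0.5).astype(float)
        perm = rng.permutation(100)
        assert weighted_bce(pred[perm], target[perm]) == pytest.approx(
            weighted_bce(pred, target)
        )
        # loss is affine in each class weight
        a = weighted_bce(pred, target, 2.0, 0.1)
        b = weighted_bce(pred, target, 1.0, 0.1)
        z = weighted_bce(pred, target, 1e-12, 0.1)
        assert a - b == pytest.approx(b - z, rel=1e-6)

    def test_out_of_range_predictions_are_clamped(self):
        val = weighted_bce(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isfinite(val)


class TestAssemblePrediction:
    def test_constant_tiles_give_all_ones(self):
        tiles = [(np.ones((4, 4, 4)), (a, b, c))
                 for a in (0, 4) for b in (0, 4) for c in (0, 4)]
        mask = assemble_prediction(tiles, (8, 8, 8))
        assert mask.data.all()

    def test_disjoint_tiles_concatenate(self):
        left = np.zeros((4, 4, 4))
        right = np.ones((4, 4, 4))
        mask = assemble_prediction([(left, (0, 0, 0)), (right, (0, 0, 4))],
                                   (4, 4, 8))
        assert not mask.data[:, :, :4].any()
        assert mask.data[:, :, 4:].all()

    def test_half_probability_labeled_spine(self):
        mask = assemble_prediction([(np.full((2, 2, 2), 0.5), (0, 0, 0))],
                                   (2, 2, 2))
        assert mask.data.all()

    def test_missing_tile_named(self):
        with pytest.raises(ValueError, match=r"\(0, 0, 4\)"):
            assemble_prediction([(np.ones((4, 4, 4)), (0, 0, 0))], (4, 4, 8))


class TestPostprocess:
    def test_single_component_unchanged(self):
        grid = np.zeros((10, 10, 10), dtype=np.uint8)
        grid[2:5, 2:5, 2:5] = 1
        out = postprocess_largest_component(BinaryMask(grid))
        np.testing.assert_array_equal(out.data, grid)

    def test_bed_artefact_discarded(self):
        grid = np.zeros((20, 20, 20), dtype=np.uint8)
        grid[2:12, 2:12, 2:12] = 1  # 1000-voxel spine blob
        grid[15:18, 15:19, 5:15] = 1  # 120-voxel bed-like artefact
        out = postprocess_largest_component(BinaryMask(grid))
        assert out.data.sum() == 1000
        assert not out.data[15:, 15:, 15:].any()

    def test_equal_size_tie_keeps_earlier_component(self):
        grid = np.zeros((4, 8, 8), dtype=np.uint8)
        grid[0, 0:2, 0:2] = 1
        grid[3, 6:8, 6:8] = 1
        out = postprocess_largest_component(BinaryMask(grid))
        assert out.data[0, 0, 0] == 1
        assert not out.data[3].any()

    def test_empty_mask_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="empty"):
            out = postprocess_largest_component(BinaryMask(np.zeros((3, 3, 3), np.uint8)))
        assert not out.data.any()

    def test_output_is_subset_and_connected(self, rng):
        from scipy import ndimage

        grid = (rng.random((12, 12, 12)) > 0.7).astype(np.uint8)
        out = postprocess_largest_component(BinaryMask(grid))
        assert not (out.data & ~grid).any()
        _, n = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
        assert n <= 1

    def test_artefact_removal_never_decreases_vertebra_iou(self):
        """The predicted spine+bed mask loses only artefact voxels, so IoU
        against the true spine can only improve — the direction the
        post-processing step is designed to push."""
        from conftest import small_phantom_config
        from spine_uda.phantom import generate_phantom

        for seed in range(5):
            s = generate_phantom(small_phantom_config(seed=seed, domain="target"))
            pred = BinaryMask(
                (s.spine_mask.data | s.bed_mask.data).astype(np.uint8),
                s.spine_mask.spacing,
            )
            out = postprocess_largest_component(pred)
            truth = s.spine_mask.data.astype(bool)
            assert not out.data[s.bed_mask.data.astype(bool)].any()
            assert (out.data.astype(bool) & truth).sum() == truth.sum()


@pytest.fixture(scope="module")
def train_samples(phantom_sample):
    return extract_detection_patches(phantom_sample.volume,
                                     phantom_sample.dense, SPEC, "train",
                                     seed=3)


class TestTrainDetector:

    def test_loss_decreases(self, train_samples):
        cfg = DetectionTrainConfig(learning_rate=1e-2, batch_size=8, epochs=5,
                                   seed=0)
        model = train_detector(train_samples, cfg)
        assert model.history[-1] < model.history[0]

    def test_training_is_bit_reproducible(self, train_samples):
        cfg = DetectionTrainConfig(learning_rate=1e-2, batch_size=8, epochs=3,
                                   seed=4)
        a = train_detector(train_samples, cfg)
        b = train_detector(train_samples, cfg)
        assert a.history == b.history
        for k in a.mlp.params:
            np.testing.assert_array_equal(a.mlp.params[k], b.mlp.params[k])

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_detector([], DetectionTrainConfig())
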