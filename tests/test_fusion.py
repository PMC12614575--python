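"""Channel combinatorics, pseudo-color fusion, cropping, counts and splits."""

import itertools

import numpy as np
import pytest

from mdfa.fusion import (
    AcquisitionPlan,
    ChannelAssignment,
    channel_assignments,
    crop_by_mask,
    dataset_counts,
    fuse_pseudocolor,
    split_dataset,
)

WL4 = ("B435", "G546", "R700", "NIR860")


class TestChannelAssignments:
    def test_four_wavelengths_give_24_distinct_orderings(self):
        combos = channel_assignments(WL4)
        assert len(combos) == 24
        assert len({c.labels for c in combos}) == 24

    def test_three_wavelengths_give_six(self):
        # brute-force enumeration oracle
        labels = ("a", "b", "c")
        combos = channel_assignments(labels)
        oracle = set(itertools.permutations(labels, 3))
        assert {c.labels for c in combos} == oracle
        assert len(combos) == 6

    def test_too_few_or_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            channel_assignments(("a", "b"))
        with pytest.raises(ValueError):
            channel_assignments(("a", "b", "b", "c"))

    def test_enumeration_is_order_deterministic(self):
        assert channel_assignments(WL4) == channel_assignments(WL4)
        assert channel_assignments(WL4)[0].labels == ("B435", "G546", "R700")


class TestFusePseudocolor:
    def _frames(self, values):
        return {wl: np.full((4, 4), v, dtype=float) for wl, v in values.items()}

    def test_bitdepth_normalization_of_constants(self):
        frames = self._frames({"r": 10, "g": 20, "b": 30})
        out = fuse_pseudocolor(frames, ChannelAssignment("r", "g", "b"), "bitdepth", 255)
        np.testing.assert_allclose(out[..., 0], 10 / 255)
        np.testing.assert_allclose(out[..., 1], 20 / 255)
        np.testing.assert_allclose(out[..., 2], 30 / 255)

    def test_swapping_labels_swaps_channels(self):
        frames = self._frames({"r": 10, "g": 20, "b": 30})
        a = fuse_pseudocolor(frames, ChannelAssignment("r", "g", "b"))
        b = fuse_pseudocolor(frames, ChannelAssignment("g", "r", "b"))
        np.testing.assert_array_equal(a[..., 0], b[..., 1])
        np.testing.assert_array_equal(a[..., 1], b[..., 0])
        np.testing.assert_array_equal(a[..., 2], b[..., 2])

    def test_per_channel_minmax_spans_unit_interval(self):
        rng = np.random.default_rng(1)
        frames = {wl: rng.uniform(5, 50, (6, 6)) for wl in ("r", "g", "b")}
        out = fuse_pseudocolor(
            frames, ChannelAssignment("r", "g", "b"), "per_channel_minmax"
        )
        for c in range(3):
            assert out[..., c].min() == pytest.approx(0.0)
            assert out[..., c].max() == pytest.approx(1.0)

    def test_missing_wavelength_and_shape_mismatch(self):
        frames = self._frames({"r": 1, "g": 2})
        with pytest.raises(ValueError, match="missing"):
            fuse_pseudocolor(frames, ChannelAssignment("r", "g", "b"))
        frames["b"] = np.zeros((3, 3))
        with pytest.raises(ValueError, match="shape"):
            fuse_pseudocolor(frames, ChannelAssignment("r", "g", "b"))


class TestCropByMask:
    def test_six_labels_give_six_patches(self):
        mask = np.zeros((12, 12), dtype=int)
        for k in range(6):
            mask[2 * k : 2 * k + 2, :2] = k + 1
        image = np.ones((12, 12, 3))
        patches = crop_by_mask(image, mask)
        assert [label for label, _ in patches] == [1, 2, 3, 4, 5, 6]

    def test_full_image_label_with_zero_pad(self):
        image = np.random.default_rng(0).uniform(size=(5, 5, 3))
        mask = np.ones((5, 5), dtype=int)
        [(label, patch)] = crop_by_mask(image, mask, pad_px=0)
        assert label == 1
        np.testing.assert_array_equal(patch, image)

    def test_oversized_pad_clips_to_bounds(self):
        image = np.ones((6, 6, 3))
        mask = np.zeros((6, 6), dtype=int)
        mask[2:4, 2:4] = 1
        [(_, patch)] = crop_by_mask(image, mask, pad_px=100)
        assert patch.shape == (6, 6, 3)

    def test_outside_label_pixels_zeroed(self):
        image = np.ones((6, 6, 3))
        mask = np.zeros((6, 6), dtype=int)
        mask[1:3, 1:3] = 1
        mask[3:5, 3:5] = 2
        patches = dict(crop_by_mask(image, mask, pad_px=1))
        # label-1 patch covers rows/cols 0..3 and must zero the label-2 corner
        assert patches[1][3, 3].sum() == 0
        assert patches[1][1, 1].sum() == 3

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty mask"):
            assert crop_by_mask(np.ones((4, 4, 3)), np.zeros((4, 4), int)) == []


class TestDatasetCounts:
    def test_full_campaign_totals(self):
        counts = dataset_counts(AcquisitionPlan()).as_dict()
        assert counts == {
            "total_raw_frames": 72000,
            "fa_frames": 2000,
            "md_frames": 48000,
            "mdfa_frames": 4000,
            "pseudo_original": 144000,
            "pseudo_fa": 12000,
            "pseudo_md": 288000,
            "pseudo_mdfa": 24000,
        }

    def test_single_set_plan(self):
        plan = AcquisitionPlan(
            n_wavelengths=1, n_configs=1, conditions=("unmodulated",),
            frames_per_set=12, fa_window=12,
        )
        counts = dataset_counts(plan)
        assert counts.total_raw_frames == 12
        assert counts.fa_frames == 1
        assert counts.md_frames == 0
        assert counts.mdfa_frames == 0

    @pytest.mark.parametrize("n_configs", [1, 2, 5])
    @pytest.mark.parametrize("frames", [12, 120, 1200])
    def test_accumulation_identity_on_divisible_plans(self, n_configs, frames):
        plan = AcquisitionPlan(n_configs=n_configs, frames_per_set=frames)
        counts = dataset_counts(plan)
        assert counts.mdfa_frames * plan.fa_window == counts.md_frames

    def test_pseudo_round_trip_identity(self):
        plan = AcquisitionPlan()
        counts = dataset_counts(plan)
        n_assign = 24
        for pseudo, branch in [
            (counts.pseudo_fa, counts.fa_frames),
            (counts.pseudo_md, counts.md_frames),
            (counts.pseudo_mdfa, counts.mdfa_frames),
        ]:
            assert pseudo // n_assign * plan.n_wavelengths == branch


class TestSplitDataset:
    def test_single_class_hundred_items(self):
        train, val, test = split_dataset([0] * 100, seed=1)
        assert (len(train), len(val), len(test)) == (60, 10, 30)

    def test_ten_items(self):
        train, val, test = split_dataset([0] * 10, seed=1)
        assert (len(train), len(val), len(test)) == (6, 1, 3)

    def test_deterministic_given_seed(self):
        labels = [i % 3 for i in range(50)]
        a = split_dataset(labels, seed=9)
        b = split_dataset(labels, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 6, size=83)
        train, val, test = split_dataset(labels, seed=4)
        combined = np.concatenate([train, val, test])
        assert len(combined) == len(labels)
        assert len(np.unique(combined)) == len(labels)

    def test_stratification_per_class(self):
        labels = np.array([0] * 40 + [1] * 20)
        train, val, test = split_dataset(labels, seed=2)
        for cls, n in ((0, 40), (1, 20)):
            assert (labels[train] == cls).sum() == int(n * 0.6)
            assert (labels[test] == cls).sum() == int(n * 0.3)

    def test_tiny_class_kept_whole_in_train_with_warning(self):
        labels = [0] * 20 + [1] * 2
        with pytest.warns(UserWarning, match="kept whole"):
            train, val, test = split_dataset(labels, seed=3)
        assert set(np.where(np.array(labels) == 1)[0]) <= set(train.tolist())

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([0] * 9, seed=0)
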