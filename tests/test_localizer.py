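"""Localizer assembly conformance, mask prediction semantics, ROI-box
derivation, and crop geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catseg import nn
from catseg.blocks import NetworkConfig
from catseg.io_acdc import CardiacVolume
from catseg.localizer import (ROIBox, build_localizer, crop_volume, mask_to_roi,
                              predict_mask)


class TestAssembly:
    def test_default_encoder_has_nine_fire_modules(self):
        net = build_localizer(NetworkConfig())
        assert len(net.fire_modules) == 9

    def test_default_encoder_has_three_pooling_stages(self):
        assert build_localizer(NetworkConfig()).n_pool_stages == 3

    def test_forward_shape_is_four_class_score_map(self, tiny_net_config):
        net = build_localizer(tiny_net_config)
        x = nn.Tensor(np.random.default_rng(0).standard_normal(
            (1, 1, 48, 48)).astype(np.float32))
        assert net(x).shape == (1, 4, 48, 48)

    def test_input_not_divisible_by_eight_rejected(self, tiny_net_config):
        net = build_localizer(tiny_net_config)
        with pytest.raises(ValueError, match="divisible by 8"):
            net(nn.Tensor(np.zeros((1, 1, 50, 50), dtype=np.float32)))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            build_localizer(NetworkConfig(fire_specs=((2, 4, 4),) * 5))


class TestPredictMask:
    @pytest.fixture()
    def small_volume(self, rng):
        data = rng.standard_normal((48, 48, 3)).astype(np.float32)
        data = (data - data.mean()) / data.std()
        return CardiacVolume(data, (1.5, 1.5, 8.0))

    def test_deterministic_on_repeated_calls(self, tiny_net_config, small_volume):
        net = build_localizer(tiny_net_config)
        m1 = predict_mask(net, small_volume)
        m2 = predict_mask(net, small_volume)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert m1.shape == small_volume.shape

    def test_forced_background_scores_give_empty_mask(self, tiny_net_config, small_volume):
        net = build_localizer(tiny_net_config)
        net.head.weight.data[...] = 0.0
        net.head.bias.data[...] = 0.0
        net.head.bias.data[0] = 10.0  # background wins everywhere
        mask = predict_mask(net, small_volume)
        assert np.all(mask.data == 0)

    def test_non_normalized_input_rejected(self, tiny_net_config, small_volume):
        net = build_localizer(tiny_net_config)
        raw = CardiacVolume(small_volume.data * 40 + 100, small_volume.spacing)
        with pytest.raises(ValueError, match="normaliz"):
            predict_mask(net, raw)

    def test_ties_resolve_to_lowest_class(self, tiny_net_config, small_volume):
        net = build_localizer(tiny_net_config)
        net.head.weight.data[...] = 0.0
        net.head.bias.data[...] = 1.0  # all classes tie
        mask = predict_mask(net, small_volume)
        assert np.all(mask.data == 0)


class TestMaskToROI:
    def test_empty_mask_centered_fallback(self):
        box = mask_to_roi(np.zeros((160, 160, 4), dtype=int), margin=8, min_size=128)
        assert (box.r0, box.r1, box.c0, box.c1) == (16, 144, 16, 144)

    def test_single_voxel_hand_expansion(self):
        mask = np.zeros((64, 64, 2), dtype=int)
        mask[20, 30, 1] = 2
        box = mask_to_roi(mask, margin=8, min_size=0)
        assert (box.r0, box.r1, box.c0, box.c1) == (12, 29, 22, 39)

    def test_all_foreground_clips_to_grid(self):
        box = mask_to_roi(np.ones((40, 48, 2), dtype=int), margin=10, min_size=0)
        assert (box.r0, box.r1, box.c0, box.c1) == (0, 40, 0, 48)

    def test_min_size_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            mask_to_roi(np.zeros((32, 32, 2), dtype=int), min_size=64)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 1 << 31), st.integers(0, 12), st.integers(0, 40))
    def test_roi_invariants_hold_for_random_masks(self, seed, margin, min_size):
        rng = np.random.default_rng(seed)
        mask = (rng.random((40, 44, 3)) < 0.02).astype(int)
        if not mask.any() and min_size == 0:
            return
        box = mask_to_roi(mask, margin=margin, min_size=min_size)
        assert 0 <= box.r0 < box.r1 <= 40
        assert 0 <= box.c0 < box.c1 <= 44
        assert box.r1 - box.r0 >= min(min_size, 40)
        assert box.c1 - box.c0 >= min(min_size, 44)
        # the box contains every foreground voxel
        rr, cc, _ = np.nonzero(mask)
        if rr.size:
            assert box.r0 <= rr.min() and rr.max() < box.r1
            assert box.c0 <= cc.min() and cc.max() < box.c1

    def test_roi_of_phantom_ground_truth_contains_all_structures(self, nor_patient):
        _, lab = nor_patient.phase("ED")
        box = mask_to_roi(lab, margin=8, min_size=128)
        rr, cc, _ = np.nonzero(lab.data > 0)
        assert box.r0 <= rr.min() and rr.max() < box.r1
        assert box.c0 <= cc.min() and cc.max() < box.c1


class TestCropVolume:
    def test_full_grid_box_identity(self, rng):
        data = rng.standard_normal((32, 32, 4))
        box = ROIBox(0, 32, 0, 32)
        crop, t = crop_volume(data, box, (32, 32))
        np.testing.assert_array_equal(crop, data)
        assert t.pad_before == (0, 0) and t.crop_offset == (0, 0)

    def test_pad_split_smaller_first(self, rng):
        data = rng.standard_normal((40, 40, 2))
        box = ROIBox(0, 17, 0, 17)
        crop, t = crop_volume(data, box, (32, 32))
        assert crop.shape == (32, 32, 2)
        assert t.pad_before == (7, 7)
        np.testing.assert_array_equal(crop[7:24, 7:24], data[:17, :17])

    def test_labels_padded_with_background(self):
        labels = np.ones((10, 10, 2), dtype=np.int16)
        crop, _ = crop_volume(labels, ROIBox(0, 10, 0, 10), (16, 16))
        assert crop[0, 0, 0] == 0 and crop[8, 8, 0] == 1

    def test_volume_padded_with_minimum_intensity(self, rng):
        data = rng.standard_normal((10, 10, 2)) + 5.0
        crop, _ = crop_volume(data, ROIBox(0, 10, 0, 10), (16, 16))
        assert crop[0, 0, 0] == pytest.approx(data.min())

    def test_degenerate_target_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            crop_volume(np.zeros((8, 8, 2)), ROIBox(0, 8, 0, 8), (0, 8))

    def test_center_crop_when_box_larger_than_target(self, rng):
        data = rng.standard_normal((40, 40, 2))
        crop, t = crop_volume(data, ROIBox(0, 40, 0, 40), (20, 20))
        np.testing.assert_array_equal(crop, data[10:30, 10:30])
        assert t.crop_offset == (10, 10)
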