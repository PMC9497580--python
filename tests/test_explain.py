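"""Grad-CAM saliency, map averaging, masks, boxes, expert agreement."""

import numpy as np
import pytest
from skimage.transform import resize as sk_resize

from cxrtransfer import (agreement, average_maps, bounding_box,
                         build_fixture_cnn, grad_cam, quantile_mask)
from cxrtransfer.explain import SaliencyMap


def cam_oracle(net, x, class_index):
    """Classical class-activation map for a GAP-head net: dense weights times
    feature maps, rectified, upsampled, min-max normalized."""
    maps = net.conv_maps(x[None])[0]
    cam = np.maximum((net.Wd[class_index][:, None, None] * maps).sum(0), 0.0)
    cam = np.maximum(sk_resize(cam.astype(float), x.shape[1:], order=1,
                               mode="reflect", anti_aliasing=False,
                               preserve_range=True), 0.0)
    lo, hi = cam.min(), cam.max()
    return (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)


class TestGradCam:
    def test_equals_cam_on_gap_head_network(self, rng):
        x = rng.normal(size=(3, 32, 32)).astype(np.float32)
        net = build_fixture_cnn(3, seed=5, widths=(6, 12))
        for c in range(3):
            got = grad_cam(net, x, c)
            want = cam_oracle(net, x, c)
            assert np.abs(got.values - want).max() < 1e-5

    def test_all_negative_contributions_give_zero_map(self, rng):
        x = rng.normal(size=(3, 16, 16)).astype(np.float32)
        net = build_fixture_cnn(1, seed=0, widths=(4,))
        net.Wd[...] = -np.abs(net.Wd)  # every channel pulls the logit down
        out = grad_cam(net, x, 0)
        assert out.degenerate
        np.testing.assert_array_equal(out.values, 0.0)

    def test_deterministic_given_fixed_weights(self, rng):
        x = rng.normal(size=(3, 16, 16)).astype(np.float32)
        net = build_fixture_cnn(2, seed=1, widths=(4, 8))
        a = grad_cam(net, x, 0).values
        b = grad_cam(net, x, 0).values
        np.testing.assert_array_equal(a, b)

    def test_map_matches_image_shape_and_unit_range(self, blob_net):
        out = grad_cam(blob_net["net"], blob_net["test_X"][0], 0)
        assert out.values.shape == (64, 64)
        assert out.values.min() == 0.0 and out.values.max() == 1.0


class TestAverageMaps:
    def test_identical_maps_average_to_themselves(self, rng):
        m = rng.random((10, 10))
        normed = (m - m.min()) / (m.max() - m.min())
        out = average_maps([m, m, m])
        np.testing.assert_allclose(out.values, normed, atol=1e-12)

    def test_map_plus_complement_is_degenerate(self, rng):
        m = rng.random((8, 8))
        m = (m - m.min()) / (m.max() - m.min())
        out = average_maps([m, 1.0 - m])
        assert out.degenerate

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_maps([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_population_map_concentrates_on_signature_region(self, blob_net):
        """Mean saliency over >=100 positives is higher inside the blob
        quadrant than along the image border band."""
        net = blob_net["net"]
        pos = np.flatnonzero(blob_net["test_y"][:, 0] == 1)[:100]
        maps = [grad_cam(net, blob_net["test_X"][i], 0) for i in pos]
        avg = average_maps(maps).values
        region = avg[2:32, 2:32].mean()       # signature quadrant
        border = np.concatenate([avg[:2].ravel(), avg[-2:].ravel(),
                                 avg[:, :2].ravel(), avg[:, -2:].ravel()])
        assert region > border.mean()


class TestQuantileMask:
    def test_distinct_valued_map_covers_one_minus_q(self, rng):
        v = rng.permutation(224 * 224).reshape(224, 224).astype(float)
        frac = quantile_mask(v, 0.8).mean()
        assert 0.199 <= frac <= 0.201

    def test_constant_map_gives_empty_mask(self, caplog):
        assert quantile_mask(np.full((16, 16), 0.3), 0.8).sum() == 0

    def test_raising_q_shrinks_mask(self, rng):
        v = rng.random((64, 64))
        m1 = quantile_mask(v, 0.6)
        m2 = quantile_mask(v, 0.9)
        assert m2.sum() < m1.sum()
        assert np.all(m1[m2])  # nested

    def test_accepts_saliency_map_objects(self, rng):
        sm = SaliencyMap(values=rng.random((8, 8)))
        assert quantile_mask(sm, 0.5).shape == (8, 8)

    @pytest.mark.parametrize("q", [0.0, 1.0, -1.0])
    def test_invalid_quantile_rejected(self, q):
        with pytest.raises(ValueError):
            quantile_mask(np.zeros((4, 4)), q)


class TestBoundingBox:
    def test_union_box_spans_extreme_pixels(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 3] = mask[5, 7] = True
        box = bounding_box(mask)
        assert (box.row_min, box.row_max, box.col_min, box.col_max) == (2, 5, 3, 7)

    def test_single_pixel_degenerate_box(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        box = bounding_box(mask)
        assert (box.row_min, box.row_max, box.col_min, box.col_max) == (1, 1, 2, 2)

    def test_component_mode_separates_two_blobs(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:4, 1:5] = True
        mask[10:15, 12:16] = True
        boxes = bounding_box(mask, mode="components")
        extents = sorted((b.row_min, b.row_max, b.col_min, b.col_max)
                         for b in boxes)
        assert extents == [(1, 3, 1, 4), (10, 14, 12, 15)]

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = True  # 8-connected
        assert len(bounding_box(mask, mode="components")) == 1

    def test_empty_mask_yields_no_box(self):
        assert bounding_box(np.zeros((4, 4), dtype=bool)) is None
        assert bounding_box(np.zeros((4, 4), dtype=bool), mode="components") == []


class TestAgreement:
    def test_prediction_superset_of_expert_scores_one(self):
        expert = np.zeros((10, 10), dtype=bool)
        expert[2:5, 2:5] = True
        pred = np.ones((10, 10), dtype=bool)
        assert agreement(pred, expert) == 1.0

    def test_disjoint_masks_score_zero(self):
        expert = np.zeros((10, 10), dtype=bool)
        expert[:2] = True
        pred = np.zeros((10, 10), dtype=bool)
        pred[5:] = True
        assert agreement(pred, expert) == 0.0

    def test_partial_overlap_fraction(self):
        expert = np.zeros((20, 20), dtype=bool)
        expert[:10, :10] = True  # 100 px
        pred = np.zeros((20, 20), dtype=bool)
        pred[:10, :5] = True
        pred[10:12, :] = True    # 75 px inside + noise outside
        expert_hits = (pred & expert).sum()
        assert agreement(pred, expert) == pytest.approx(expert_hits / 100)

    def test_empty_expert_mask_is_undefined(self, caplog):
        assert agreement(np.ones((4, 4), bool), np.zeros((4, 4), bool)) is None

    def test_monotone_in_predicted_mask(self, rng):
        expert = rng.random((16, 16)) < 0.3
        pred = rng.random((16, 16)) < 0.2
        grown = pred | (rng.random((16, 16)) < 0.2)
        assert agreement(grown, expert) >= agreement(pred, expert)

    def test_box_variant_uses_filled_bounding_box(self):
        expert = np.zeros((10, 10), dtype=bool)
        expert[4:6, 4:6] = True
        pred = np.zeros((10, 10), dtype=bool)
        pred[3, 3] = pred[7, 7] = True  # box covers 3..7 square
        assert agreement(pred, expert) == 0.0
        assert agreement(pred, expert, use_box=True) == 1.0
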