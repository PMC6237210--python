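"""Segmentation and tracking: thresholding, component filtering, IoU linking."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from osteodyn.segment import (
    LabelMap,
    SegmentationParams,
    segment_frame,
    segment_stack,
    track_cells,
    tracks_to_dataframe,
)


def _disc_image(shape, discs, amplitude=100.0, background=0.0):
    img = np.full(shape, background)
    for cy, cx, r in discs:
        rr, cc = draw_disk((cy, cx), r, shape=shape)
        img[rr, cc] = amplitude
    return img


def _iou(a, b):
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


class TestSegmentFrame:
    def test_blank_field_no_labels(self):
        lm = segment_frame(np.zeros((64, 64)))
        assert lm.n_labels == 0

    def test_constant_image_otsu_empty_not_error(self):
        lm = segment_frame(np.full((64, 64), 42.0))
        assert lm.n_labels == 0

    def test_single_disc_area_matches_rasterized_count(self):
        img = _disc_image((64, 64), [(32, 32, 10)])
        lm = segment_frame(img, SegmentationParams(min_area=20))
        assert lm.n_labels == 1
        area = int((lm.labels == 1).sum())
        assert area == pytest.approx(np.pi * 10 ** 2, rel=0.05)

    def test_two_separated_discs_two_labels(self):
        img = _disc_image((96, 96), [(30, 30, 10), (70, 70, 10)])
        lm = segment_frame(img, SegmentationParams(min_area=20))
        assert lm.n_labels == 2

    def test_min_area_drops_small_regions(self):
        img = _disc_image((96, 96), [(30, 30, 10), (70, 70, 3)])
        lm = segment_frame(img, SegmentationParams(min_area=60, opening_radius=0))
        assert lm.n_labels == 1

    def test_border_touching_region_dropped_by_default(self):
        img = _disc_image((64, 64), [(0, 32, 8), (32, 32, 8)])
        lm_cleared = segment_frame(img, SegmentationParams(min_area=20))
        lm_kept = segment_frame(img, SegmentationParams(min_area=20,
                                                        clear_border=False))
        assert lm_cleared.n_labels == 1
        assert lm_kept.n_labels == 2

    def test_fixed_threshold_method(self):
        img = _disc_image((64, 64), [(32, 32, 10)], amplitude=30.0, background=20.0)
        params = SegmentationParams(threshold_method="fixed", fixed_threshold=25.0,
                                    min_area=20)
        assert segment_frame(img, params).n_labels == 1

    def test_labels_contiguous_and_min_area_enforced(self, small_untreated):
        stack, _ = small_untreated
        params = SegmentationParams(min_area=50)
        for lm in segment_stack(stack, params=params):
            labels = np.unique(lm.labels)
            assert np.array_equal(labels, np.arange(lm.n_labels + 1))
            areas = np.bincount(lm.labels.ravel())[1:]
            assert np.all(areas >= params.min_area)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            segment_frame(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            segment_frame(np.full((8, 8), -1.0))
        with pytest.raises(ValueError):
            SegmentationParams(threshold_method="magic")


class TestTracking:
    def _maps(self, frames):
        return [LabelMap(f.astype(np.int32), frame_index=i)
                for i, f in enumerate(frames)]

    def test_static_cell_single_track(self):
        frame = np.zeros((32, 32), dtype=int)
        frame[10:20, 10:20] = 1
        tracks = track_cells(self._maps([frame] * 6))
        assert len(tracks) == 1
        assert len(tracks[0]) == 6
        assert tracks[0].frames == list(range(6))

    def test_two_static_cells_no_identity_swap(self):
        frame = np.zeros((48, 48), dtype=int)
        frame[5:15, 5:15] = 1
        frame[30:40, 30:40] = 2
        tracks = track_cells(self._maps([frame] * 4))
        assert len(tracks) == 2
        for tr in tracks:
            labels = {lab for _, lab in tr.members}
            assert len(labels) == 1  # same label throughout

    def test_disjoint_jump_starts_new_track(self):
        f0 = np.zeros((48, 48), dtype=int)
        f0[5:15, 5:15] = 1
        f1 = np.zeros((48, 48), dtype=int)
        f1[30:40, 30:40] = 1  # zero overlap with f0's cell
        tracks = track_cells(self._maps([f0, f1]), min_iou=0.3)
        assert len(tracks) == 2
        assert all(len(tr) == 1 for tr in tracks)

    def test_below_min_iou_not_linked(self):
        f0 = np.zeros((48, 48), dtype=int)
        f0[0:10, 0:10] = 1
        f1 = np.zeros((48, 48), dtype=int)
        f1[8:18, 8:18] = 1  # IoU = 4/196 ≈ 0.02
        assert len(track_cells(self._maps([f0, f1]), min_iou=0.3)) == 2
        assert len(track_cells(self._maps([f0, f1]), min_iou=0.01)) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least one frame"):
            track_cells([])

    def test_deterministic(self, small_untreated):
        stack, _ = small_untreated
        lms = segment_stack(stack)
        t1 = track_cells(lms)
        t2 = track_cells(lms)
        assert [(tr.track_id, tr.members) for tr in t1] == \
               [(tr.track_id, tr.members) for tr in t2]

    def test_track_table_columns(self, small_untreated):
        stack, _ = small_untreated
        lms = segment_stack(stack)
        df = tracks_to_dataframe(track_cells(lms), lms, pixel_size=stack.pixel_size)
        assert list(df.columns) == ["track_id", "frame", "label", "centroid_y",
                                    "centroid_x", "area_px", "area_um2"]
        assert (df.area_px > 0).all()


class TestRecallOnSyntheticData:
    def test_ground_truth_cells_recovered(self, small_untreated):
        """With default parameters and 5% noise, every eligible ground-truth
        cell (area ≥ min_area, not touching the border) is recovered with
        IoU ≥ 0.7 by some segmented region."""
        stack, gt = small_untreated
        params = SegmentationParams()
        label_maps = segment_stack(stack, params=params)
        recovered = eligible = 0
        for t in range(gt.masks.shape[0]):
            lm = label_maps[t]
            for i in range(gt.masks.shape[1]):
                m = gt.masks[t, i]
                border = (m[0].any() or m[-1].any()
                          or m[:, 0].any() or m[:, -1].any())
                if m.sum() < params.min_area or border:
                    continue
                eligible += 1
                ious = [_iou(m, lm.labels == lab)
                        for lab in range(1, lm.n_labels + 1)]
                if ious and max(ious) >= 0.7:
                    recovered += 1
        assert eligible > 0
        assert recovered / eligible >= 0.95
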