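"""Osteoclast segmentation and overlap-based frame-to-frame tracking.

Per frame: threshold (Otsu by default, or a fixed value), morphological
opening, 8-connected component labeling, small-region and optional
border-region removal, contiguous relabeling. Tracks link labels across
consecutive frames by greedy maximum pixel overlap, accepting a match only
when intersection-over-union clears ``min_iou``; osteoclasts are large,
sparse and slow relative to the frame interval, so greedy overlap matching
is adequate and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening as _opening
from skimage.segmentation import clear_border as _clear_border

from .stack import ImageStack

__all__ = [
    "SegmentationParams",
    "LabelMap",
    "CellTrack",
    "segment_frame",
    "segment_stack",
    "track_cells",
    "tracks_to_dataframe",
]


@dataclass(frozen=True)
class SegmentationParams:
    threshold_method: str = "otsu"  # "otsu" or "fixed"
    fixed_threshold: float = 0.0  # used iff threshold_method == "fixed"
    min_area: int = 50  # pixels
    opening_radius: int = 1  # pixels; 0 disables opening
    clear_border: bool = True

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")


@dataclass
class LabelMap:
    """Integer-labeled regions of one frame; 0 = background, labels 1..K."""

    labels: np.ndarray  # (Y, X) int
    frame_index: int = 0

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class CellTrack:
    """One cell identity followed across consecutive frames (no gaps)."""

    track_id: int
    members: list[tuple[int, int]] = field(default_factory=list)  # (frame, label)

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.members]

    def label_at(self, frame: int) -> int:
        for f, lab in self.members:
            if f == frame:
                return lab
        raise KeyError(f"track {self.track_id} has no member at frame {frame}")

    def __len__(self) -> int:
        return len(self.members)


def segment_frame(channel_image: np.ndarray,
                  params: SegmentationParams = SegmentationParams(),
                  frame_index: int = 0) -> LabelMap:
    """Binarize one frame and extract labeled osteoclast regions.

    A constant image under Otsu yields an empty label map rather than an
    error (Otsu is undefined on a single gray level, so nothing is
    foreground).
    """
    img = np.asarray(channel_image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("channel_image must be a nonempty 2-D array")
    if np.any(img < 0):
        raise ValueError("intensities must be nonnegative")

    if params.threshold_method == "otsu":
        if np.ptp(img) == 0:
            return LabelMap(np.zeros(img.shape, dtype=np.int32), frame_index)
        thr = threshold_otsu(img)
    else:
        thr = params.fixed_threshold
    binary = img > thr
    if params.opening_radius > 0:
        binary = _opening(binary, disk(params.opening_radius))
    if params.clear_border:
        binary = _clear_border(binary)
    labels = cc_label(binary, connectivity=2)  # 8-connectivity
    if params.min_area > 0 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < params.min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    labels = cc_label(labels > 0, connectivity=2)  # relabel 1..K contiguously
    return LabelMap(labels.astype(np.int32), frame_index)


def segment_stack(stack: ImageStack, channel: str = "reporter",
                  params: SegmentationParams = SegmentationParams()) -> list[LabelMap]:
    """Segment every frame of one channel."""
    planes = stack.channel(channel)
    return [segment_frame(planes[t], params, frame_index=t)
            for t in range(planes.shape[0])]


def _overlap_matrix(prev: np.ndarray, cur: np.ndarray):
    """Pixel-overlap counts between labels of two frames, via a joint histogram."""
    np_prev, np_cur = prev.max(), cur.max()
    joint = prev.astype(np.int64) * (np_cur + 1) + cur
    counts = np.bincount(joint.ravel(), minlength=(np_prev + 1) * (np_cur + 1))
    return counts.reshape(np_prev + 1, np_cur + 1)


def track_cells(label_maps: list[LabelMap], min_iou: float = 0.3) -> list[CellTrack]:
    """Link labels across frames into tracks by greedy maximum overlap.

    A previous-frame label and a current-frame label are matched when their
    IoU ≥ ``min_iou``; candidate pairs are taken largest-intersection
    first, ties broken toward the smaller (prev, cur) label pair so the
    assignment is deterministic. Unmatched current labels start new
    tracks; a track that finds no match simply ends (no gap closing).
    """
    if not label_maps:
        raise ValueError("label_maps must contain at least one frame")
    if not 0.0 <= min_iou <= 1.0:
        raise ValueError("min_iou must be in [0, 1]")

    tracks: list[CellTrack] = []
    next_id = 0
    # active[label in current frame] -> track
    active: dict[int, CellTrack] = {}
    first = label_maps[0]
    areas_prev = np.bincount(first.labels.ravel())
    for lab in range(1, first.n_labels + 1):
        tr = CellTrack(next_id, [(first.frame_index, lab)])
        tracks.append(tr)
        active[lab] = tr
        next_id += 1

    for prev_map, cur_map in zip(label_maps[:-1], label_maps[1:]):
        overlap = _overlap_matrix(prev_map.labels, cur_map.labels)
        areas_prev = np.bincount(prev_map.labels.ravel(),
                                 minlength=overlap.shape[0])
        areas_cur = np.bincount(cur_map.labels.ravel(),
                                minlength=overlap.shape[1])
        pairs = []
        for p in range(1, overlap.shape[0]):
            for c in range(1, overlap.shape[1]):
                inter = overlap[p, c]
                if inter == 0:
                    continue
                union = areas_prev[p] + areas_cur[c] - inter
                if union > 0 and inter / union >= min_iou:
                    pairs.append((-int(inter), p, c))
        pairs.sort()  # largest intersection first, then smaller label ids
        matched_prev: set[int] = set()
        matched_cur: set[int] = set()
        new_active: dict[int, CellTrack] = {}
        for _, p, c in pairs:
            if p in matched_prev or c in matched_cur:
                continue
            matched_prev.add(p)
            matched_cur.add(c)
            tr = active.get(p)
            if tr is None:
                continue
            tr.members.append((cur_map.frame_index, c))
            new_active[c] = tr
        for c in range(1, cur_map.n_labels + 1):
            if c not in matched_cur:
                tr = CellTrack(next_id, [(cur_map.frame_index, c)])
                tracks.append(tr)
                new_active[c] = tr
                next_id += 1
        active = new_active
    return tracks


def tracks_to_dataframe(tracks: list[CellTrack],
                        label_maps: list[LabelMap],
                        pixel_size: float = 1.0) -> pd.DataFrame:
    """Tabulate tracks: one row per (track, frame) with centroid and area."""
    by_frame = {lm.frame_index: lm for lm in label_maps}
    rows = []
    for tr in tracks:
        for frame, lab in tr.members:
            lm = by_frame[frame]
            props = regionprops((lm.labels == lab).astype(np.uint8))
            cy, cx = props[0].centroid
            area = props[0].area
            rows.append({
                "track_id": tr.track_id,
                "frame": frame,
                "label": lab,
                "centroid_y": cy,
                "centroid_x": cx,
                "area_px": int(area),
                "area_um2": float(area) * pixel_size ** 2,
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "label", "centroid_y",
                                       "centroid_x", "area_px", "area_um2"])
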