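"""Cell deformation index from mask overlap between two time points.

For one tracked cell, compare its binarized footprint at the start and end
of a window (default 5 frames ≙ 5 min at 1 min/frame) and split the pixels
into three areas: A = in the initial mask only, B = in both, C = in the
final mask only. The deformation index is

    (A + C) / (A + B),

the area changed over the window relative to the initial area; it is 0 for
a perfectly static cell and grows with boundary movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import CellTrack, LabelMap

__all__ = [
    "DeformationRecord",
    "overlap_areas",
    "deformation_index",
    "compute_track_deformation",
    "masks_deformation",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class DeformationRecord:
    track_id: int
    t_start: int
    t_end: int
    area_A: int  # initial-only pixels
    area_B: int  # overlap pixels
    area_C: int  # final-only pixels
    index: float
    disappeared: bool = False  # final mask empty; index = 1 by the formula


def overlap_areas(mask_initial: np.ndarray, mask_final: np.ndarray):
    """Pixel counts (A, B, C) of initial-only, overlap, final-only areas."""
    mask_initial = np.asarray(mask_initial, dtype=bool)
    mask_final = np.asarray(mask_final, dtype=bool)
    if mask_initial.shape != mask_final.shape:
        raise ValueError(
            f"mask shapes differ: {mask_initial.shape} vs {mask_final.shape}"
        )
    area_B = int(np.count_nonzero(mask_initial & mask_final))
    area_A = int(np.count_nonzero(mask_initial)) - area_B
    area_C = int(np.count_nonzero(mask_final)) - area_B
    return area_A, area_B, area_C


def deformation_index(area_A: float, area_B: float, area_C: float) -> float:
    """(A + C) / (A + B); undefined (rejected) when the initial mask is empty."""
    if min(area_A, area_B, area_C) < 0:
        raise ValueError("areas must be nonnegative")
    denom = area_A + area_B
    if denom == 0:
        raise ValueError(
            "deformation index undefined: initial mask is empty (A + B = 0)"
        )
    return (area_A + area_C) / denom


def compute_track_deformation(track: CellTrack, label_maps: list[LabelMap],
                              window: int = 5) -> list[DeformationRecord]:
    """One record per sliding start frame t, comparing masks at t and t+window.

    A track spanning fewer than ``window + 1`` frames yields an empty list.
    If the cell's final mask is empty (it vanished), the record is emitted
    with ``disappeared=True`` and index 1.0 rather than dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    by_frame = {lm.frame_index: lm for lm in label_maps}
    frame_to_label = dict(track.members)
    records = []
    for t, lab in track.members:
        t_end = t + window
        if t_end not in frame_to_label:
            continue
        m0 = by_frame[t].mask(lab)
        m1 = by_frame[t_end].mask(frame_to_label[t_end])
        a, b, c = overlap_areas(m0, m1)
        records.append(DeformationRecord(
            track_id=track.track_id, t_start=t, t_end=t_end,
            area_A=a, area_B=b, area_C=c,
            index=deformation_index(a, b, c),
            disappeared=(b + c == 0),
        ))
    return records


def masks_deformation(masks: np.ndarray, window: int = 5,
                      track_id: int = 0) -> list[DeformationRecord]:
    """Deformation records for one cell given directly as a T×Y×X mask array.

    Used to evaluate the index on ground-truth masks without segmentation.
    Windows with an empty initial mask are skipped (the index is undefined
    there).
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3:
        raise ValueError("masks must be T×Y×X")
    records = []
    for t in range(masks.shape[0] - window):
        a, b, c = overlap_areas(masks[t], masks[t + window])
        if a + b == 0:
            continue
        records.append(DeformationRecord(
            track_id=track_id, t_start=t, t_end=t + window,
            area_A=a, area_B=b, area_C=c,
            index=deformation_index(a, b, c),
            disappeared=(b + c == 0),
        ))
    return records


def records_to_dataframe(records: list[DeformationRecord]) -> pd.DataFrame:
    cols = ["track_id", "t_start", "t_end", "area_A", "area_B", "area_C",
            "index", "disappeared"]
    return pd.DataFrame([vars(r) for r in records], columns=cols)


def per_cell_summary(records: list[DeformationRecord]) -> pd.DataFrame:
    """Per-track mean index over all sliding windows (the per-cell summary)."""
    df = records_to_dataframe(records)
    if df.empty:
        return pd.DataFrame(columns=["track_id", "n_windows", "mean_index"])
    g = df.groupby("track_id")["index"].agg(["count", "mean"]).reset_index()
    g.columns = ["track_id", "n_windows", "mean_index"]
    return g
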