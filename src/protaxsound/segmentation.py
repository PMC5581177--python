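"""Region-of-interest extraction from spectrograms.

The detector reconstructs the median-clipping template method widely used for
bird vocalization segmentation: a pixel is signal when it exceeds a multiple
of both its row (frequency-bin) median and its column (frame) median, the
binary mask is closed morphologically, small components are dropped, and
nearby components with overlapping frequency bands are merged.  Manual
validation of the automated ROIs is a scriptable CSV round-trip (export,
edit, re-import) rather than a GUI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops
from skimage.morphology import closing

from .audio import Spectrogram

__all__ = [
    "ROI",
    "denoise_median",
    "extract_rois",
    "apply_validation",
    "rois_to_frame",
    "rois_from_frame",
    "roi_iou",
    "match_recall",
]

_counter = itertools.count(1)


@dataclass
class ROI:
    """A half-open time-frequency box ``[t0, t1) x [f0, f1)`` in one file."""

    t0: float
    t1: float
    f0: float
    f1: float
    file: str | None = None
    label: str | None = None
    provenance: str = "automated"
    roi_id: int | None = None

    def __post_init__(self) -> None:
        if self.roi_id is None:
            self.roi_id = next(_counter)
        if not (self.t1 > self.t0):
            raise ValueError(f"ROI requires t1 > t0, got [{self.t0}, {self.t1})")
        if not (self.f1 > self.f0):
            raise ValueError(f"ROI requires f1 > f0, got [{self.f0}, {self.f1})")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


def denoise_median(spec: Spectrogram, factor: float = 3.0, min_db: float = -35.0) -> np.ndarray:
    """Binary signal mask by row-and-column median clipping.

    A pixel survives iff its magnitude exceeds ``factor`` times the median of
    its frequency row AND ``factor`` times the median of its time column.
    ``min_db`` adds an absolute floor relative to the spectrogram peak: with
    near-zero background (noiseless recordings) the medians collapse and
    windowing sidelobes would otherwise pass everywhere.
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    v = spec.values
    if v.size == 0:
        raise ValueError("empty spectrogram")
    row_med = np.median(v, axis=1, keepdims=True)
    col_med = np.median(v, axis=0, keepdims=True)
    floor = v.max() * 10.0 ** (min_db / 20.0)
    return (v > factor * row_med) & (v > factor * col_med) & (v > floor)


def _merge_boxes(boxes: list[list[float]], merge_gap: float) -> list[list[float]]:
    """Merge time-sorted boxes whose time gap < merge_gap and bands overlap."""
    merged: list[list[float]] = []
    for box in sorted(boxes, key=lambda b: (b[0], b[2])):
        for m in merged:
            gap = max(box[0] - m[1], 0.0)
            bands_overlap = box[2] < m[3] and m[2] < box[3]
            if gap < merge_gap and bands_overlap:
                m[0] = min(m[0], box[0])
                m[1] = max(m[1], box[1])
                m[2] = min(m[2], box[2])
                m[3] = max(m[3], box[3])
                break
        else:
            merged.append(box)
    return merged


def extract_rois(
    spec: Spectrogram,
    mask: np.ndarray,
    min_area: int = 12,
    merge_gap: float = 0.05,
    file: str | None = None,
) -> list[ROI]:
    """Connected components of the mask as physical-coordinate ROIs.

    A 3x3 morphological closing bridges one-pixel gaps, components smaller
    than ``min_area`` pixels are dropped, and components closer in time than
    ``merge_gap`` seconds with overlapping frequency bands are merged.  Pixel
    index ``i`` covers the half-open physical interval ``[i, i+1)`` on its
    axis, so conversions are exact.
    """
    if mask.shape != spec.values.shape:
        raise ValueError("mask shape must match spectrogram shape")
    closed = closing(mask, footprint=np.ones((3, 3), dtype=bool))
    lab = label(closed, connectivity=2)
    hop, df = spec.hop, spec.df
    boxes = []
    for rp in regionprops(lab):
        if rp.area < min_area:
            continue
        r0, c0, r1, c1 = rp.bbox  # half-open pixel rows (freq) x cols (time)
        boxes.append([c0 * hop, c1 * hop, r0 * df, r1 * df])
    merged = _merge_boxes(boxes, merge_gap) if merge_gap > 0 else sorted(boxes)
    return [
        ROI(t0=b[0], t1=b[1], f0=b[2], f1=b[3], file=file, provenance="automated")
        for b in sorted(merged, key=lambda b: (b[0], b[2]))
    ]


def rois_to_frame(rois: list[ROI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "file": r.file, "roi_id": r.roi_id, "t0": r.t0, "t1": r.t1,
                "f0": r.f0, "f1": r.f1, "label": r.label, "provenance": r.provenance,
            }
            for r in rois
        ]
    )


def rois_from_frame(df: pd.DataFrame) -> list[ROI]:
    return [
        ROI(
            t0=row.t0, t1=row.t1, f0=row.f0, f1=row.f1,
            file=getattr(row, "file", None),
            label=None if pd.isna(getattr(row, "label", None)) else row.label,
            provenance=getattr(row, "provenance", "automated"),
            roi_id=int(row.roi_id) if hasattr(row, "roi_id") else None,
        )
        for row in df.itertuples(index=False)
    ]


def apply_validation(auto_rois: list[ROI], edits: pd.DataFrame) -> list[ROI]:
    """Apply delete/redraw/add directives to automated ROIs.

    ``edits`` columns: roi_id, action in {delete, redraw, add}, t0, t1, f0,
    f1.  Directives are applied in file order; surviving ROIs are marked
    ``provenance="validated"``.  A directive naming an unknown ROI id fails.
    """
    by_id = {r.roi_id: r for r in auto_rois}
    for row in edits.itertuples(index=False):
        action = row.action
        if action == "add":
            new = ROI(t0=row.t0, t1=row.t1, f0=row.f0, f1=row.f1, provenance="validated")
            by_id[new.roi_id] = new
            continue
        rid = int(row.roi_id)
        if rid not in by_id:
            raise KeyError(f"edit directive references unknown ROI id {rid}")
        if action == "delete":
            del by_id[rid]
        elif action == "redraw":
            old = by_id[rid]
            by_id[rid] = replace(old, t0=row.t0, t1=row.t1, f0=row.f0, f1=row.f1)
        else:
            raise ValueError(f"unknown edit action {action!r}")
    return [replace(r, provenance="validated") for r in by_id.values()]


def roi_iou(a: ROI, b: ROI) -> float:
    """Intersection-over-union of two time-frequency boxes."""
    ti = max(0.0, min(a.t1, b.t1) - max(a.t0, b.t0))
    fi = max(0.0, min(a.f1, b.f1) - max(a.f0, b.f0))
    inter = ti * fi
    union = a.duration * (a.f1 - a.f0) + b.duration * (b.f1 - b.f0) - inter
    return inter / union if union > 0 else 0.0


def match_recall(predicted: list[ROI], truth: list[ROI], iou_threshold: float = 0.5) -> float:
    """Fraction of truth boxes matched by some prediction at the IoU cutoff."""
    if not truth:
        return 1.0
    hits = sum(
        1 for t in truth if any(roi_iou(p, t) >= iou_threshold for p in predicted)
    )
    return hits / len(truth)
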