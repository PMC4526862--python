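"""Overlap-based evaluation of closed boundaries on the pixel grid.

Recall is the overlap area divided by the reference (gold-standard) area;
precision is the overlap area divided by the test (reconstructed) area.
Areas are pixel counts from rasterization at image resolution: a pixel
belongs to a region when its center lies inside the polygon (even-odd
rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path

from .errors import BoundaryError, ScoreError
from .resampling import ClosedBoundary

__all__ = ["OverlapScores", "rasterize_boundary", "recall_precision"]


@dataclass(frozen=True)
class OverlapScores:
    recall: float
    precision: float
    overlap_area: int
    area_reference: int
    area_test: int


def rasterize_boundary(boundary, height: int, width: int) -> np.ndarray:
    """Binary mask of pixels whose centers lie inside the closed boundary.

    ``boundary`` may be a :class:`ClosedBoundary` or an (N, 2) point array
    (x = column, y = row).  Deterministic; pixels are tested only inside
    the polygon's bounding box.
    """
    pts = boundary.points if isinstance(boundary, ClosedBoundary) else np.asarray(
        boundary, dtype=np.float64
    )
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise BoundaryError("degenerate polygon: need at least 3 planar points")
    mask = np.zeros((height, width), dtype=bool)
    x0 = max(int(np.floor(pts[:, 0].min())), 0)
    x1 = min(int(np.ceil(pts[:, 0].max())) + 1, width)
    y0 = max(int(np.floor(pts[:, 1].min())), 0)
    y1 = min(int(np.ceil(pts[:, 1].max())) + 1, height)
    if x0 >= x1 or y0 >= y1:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    centers = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    inside = Path(pts, closed=False).contains_points(centers)
    mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return mask


def recall_precision(
    reference: ClosedBoundary,
    test: ClosedBoundary,
    height: int,
    width: int,
) -> OverlapScores:
    """Pixel-grid recall and precision of ``test`` against ``reference``."""
    ref_mask = rasterize_boundary(reference, height, width)
    test_mask = rasterize_boundary(test, height, width)
    area_ref = int(ref_mask.sum())
    area_test = int(test_mask.sum())
    if area_ref == 0 or area_test == 0:
        raise ScoreError("zero-area region: recall/precision undefined")
    overlap = int((ref_mask & test_mask).sum())
    return OverlapScores(
        recall=overlap / area_ref,
        precision=overlap / area_test,
        overlap_area=overlap,
        area_reference=area_ref,
        area_test=area_test,
    )
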