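"""Per-tree diameter estimation at the bottom image row.

A detected tree's width is read off the bottom row of its filled
contour.  Because flood fill can leave column gaps (and a contour can
drag a thin branch along), the bottom row is decomposed into maximal
solid runs and the widest run is taken as the true stem; the narrower
runs are assumed to be attached clutter.  The representative depth is
the median of the non-zero raw depths across the chosen span — zeros
(stereo dropout) never enter the median.  A tree whose whole span
dropped out borrows the median depth of the other trees in the frame.
Width and depth then go through the field-of-view conversion chain in
:mod:`salixmap.geometry` to give millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detection import DetectedTree
from .geometry import CameraModel, diameter_from_width

__all__ = ["MISSING", "BottomProfile", "bottom_profile", "resolve_missing_depth", "measure_trees"]

#: Sentinel for "no valid depth anywhere in the chosen span".
MISSING = None


@dataclass
class BottomProfile:
    """Bottom-row slice of one filled contour with its aligned depths.

    ``chosen_span`` is the half-open column interval of the widest solid
    run; ``pixel_width`` its length; ``depth_value`` the rounded median
    of non-zero depths over the span, or ``None`` when every depth in
    the span is zero.
    """

    contour_row: np.ndarray
    depth_row: np.ndarray
    chosen_span: tuple[int, int]
    pixel_width: int
    depth_value: Optional[int]


def _solid_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) intervals of maximal runs of ones."""
    row = np.asarray(row) != 0
    if not row.any():
        return []
    padded = np.concatenate(([False], row, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _median_depth(values: np.ndarray) -> Optional[int]:
    nz = values[values > 0]
    if nz.size == 0:
        return MISSING
    return int(round(float(np.median(nz))))


def bottom_profile(contour, depth_median: np.ndarray) -> BottomProfile:
    """Measure pixel width and representative depth at the bottom row.

    The contour's bottom-image-row occupancy is trimmed of leading and
    trailing zeros; if interior zeros remain, the row is split into
    solid runs and the widest run wins (leftmost on ties) — treating the
    whole extent as one solid stem would grossly overestimate the
    diameter whenever a gap or an attached branch is present.
    """
    if not contour.touches_bottom:
        raise ValueError("contour does not reach the bottom image row")
    depth_median = np.asarray(depth_median)
    row = contour.bottom_row(depth_median.shape[1])
    depth_row = depth_median[-1]
    runs = _solid_runs(row)
    start, end = max(runs, key=lambda se: (se[1] - se[0], -se[0]))
    return BottomProfile(
        contour_row=row,
        depth_row=depth_row,
        chosen_span=(start, end),
        pixel_width=end - start,
        depth_value=_median_depth(depth_row[start:end]),
    )


def resolve_missing_depth(
    trees: Sequence[tuple[int, Optional[float]]],
    fallback_depth: Optional[float] = None,
) -> list[tuple[int, float]]:
    """Fill missing depths with the median depth of the other trees.

    ``trees`` is a sequence of (pixel_width, depth-or-``None``) pairs.
    Each missing depth becomes the rounded median of the frame's real
    depths.  If *no* tree has a real depth, all are assigned
    ``fallback_depth`` (the row-plane distance, supplied by the caller
    in raw units); with no fallback either, an error is raised.
    """
    real = [d for _, d in trees if d is not MISSING]
    if real:
        fill = int(round(float(np.median(real))))
    elif fallback_depth is not None:
        fill = int(round(fallback_depth))
    elif any(d is MISSING for _, d in trees):
        raise ValueError("no real depths available and no fallback supplied")
    else:
        return []
    return [(w, float(fill) if d is MISSING else float(d)) for w, d in trees]


def measure_trees(
    trees: list[DetectedTree],
    depth_median: np.ndarray,
    camera: CameraModel,
) -> list[DetectedTree]:
    """Populate each detected tree's measurement in place.

    Pipeline per frame: bottom-row profile per tree → frame-level
    missing-depth resolution → pixel-to-millimetre conversion.  The
    fallback for an all-missing frame is the bottom-plane distance in
    raw depth units.
    """
    if not trees:
        return trees
    profiles = [bottom_profile(t.contour, depth_median) for t in trees]
    fallback = camera.bottom_plane_distance / camera.depth_scale
    resolved = resolve_missing_depth(
        [(p.pixel_width, p.depth_value) for p in profiles], fallback_depth=fallback
    )
    for tree, (width, depth) in zip(trees, resolved):
        tree.measurement = diameter_from_width(width, depth, camera)
    return trees
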