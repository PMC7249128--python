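"""Tree detection: mask clean-up, contour extraction and filtering.

The segmentation mask is closed with a tall, narrow structuring element
(stems are tall, narrow objects), its connected components become
contour candidates, and two filters remove non-trees: a minimum filled
area, and the requirement that a tree reaches the bottom image row —
stems enter the frame from below, they do not float.  Survivors get IDs
assigned left to right.

No regrouping of fragmented components is attempted: a stem split into
sub-threshold fragments is simply not detected.  This is a deliberate
fidelity choice and the main known source of missed stems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import TreeMeasurement

__all__ = [
    "TreeContour",
    "DetectedTree",
    "DetectionParams",
    "morphological_close",
    "find_contours",
    "filter_contours",
    "detect",
]


@dataclass
class TreeContour:
    """External boundary and filled-region features of one component.

    ``points`` are the boundary pixels of the filled component in
    row-major order; ``area`` is the filled pixel count (robust for
    shapes one or two pixels wide, where a polygon area would
    underestimate); ``bbox`` is (top, left, height, width).  ``filled``
    is the boolean component crop within the bbox, kept so downstream
    width measurement does not need to redraw the contour.
    """

    points: np.ndarray
    area: int
    bbox: tuple[int, int, int, int]
    touches_bottom: bool
    filled: np.ndarray = field(repr=False, default=None)

    def bottom_row(self, frame_width: int) -> np.ndarray:
        """Binary bottom-image-row occupancy vector, length frame_width."""
        row = np.zeros(frame_width, dtype=np.uint8)
        if self.touches_bottom:
            top, left, height, width = self.bbox
            row[left : left + width] = self.filled[-1].astype(np.uint8)
        return row


@dataclass
class DetectedTree:
    """A contour accepted as a tree, with its (optional) measurement."""

    tree_id: int
    contour: TreeContour
    measurement: Optional[TreeMeasurement] = None


@dataclass(frozen=True)
class DetectionParams:
    """Mask clean-up and contour filter settings.

    ``close_kernel`` is (rows, cols) of the solid closing rectangle —
    default 15 rows × 2 cols, an upright shape matching the expected
    stem geometry.  ``min_area`` is the filled-pixel threshold below
    which a contour is discarded.
    """

    min_area: int = 600
    close_kernel: tuple[int, int] = (15, 2)
    close_iterations: int = 1

    def __post_init__(self) -> None:
        if self.min_area < 0:
            raise ValueError("min_area must be non-negative")
        if min(self.close_kernel) < 1:
            raise ValueError("close_kernel sides must be >= 1")
        if self.close_iterations < 0:
            raise ValueError("close_iterations must be non-negative")


def morphological_close(
    mask: np.ndarray,
    kernel_shape: tuple[int, int] = (15, 2),
    iterations: int = 1,
) -> np.ndarray:
    """Binary closing with a solid rectangle: dilation then erosion.

    Bridges gaps smaller than the kernel (e.g. speckle holes left by the
    flood fill) without growing the overall region.  The erosion treats
    pixels beyond the border as set, so regions touching the frame edge
    are not eaten from outside.
    """
    mask = np.asarray(mask) != 0
    if iterations == 0:
        return mask.astype(np.uint8)
    selem = np.ones(kernel_shape, dtype=bool)
    out = mask
    for _ in range(iterations):
        out = ndimage.binary_dilation(out, structure=selem, border_value=0)
        out = ndimage.binary_erosion(out, structure=selem, border_value=1)
    return out.astype(np.uint8)


def find_contours(mask: np.ndarray) -> list[TreeContour]:
    """One contour per external connected component (8-connectivity).

    Area is the filled pixel count of the component; interior holes are
    ignored for the boundary (the boundary is the set of component
    pixels 4-adjacent to outside-the-component or to the frame edge).
    Components are returned in order of first appearance in a row-major
    scan.
    """
    mask = np.asarray(mask) != 0
    structure = ndimage.generate_binary_structure(2, 2)
    labels, n = ndimage.label(mask, structure=structure)
    h, w = mask.shape
    contours: list[TreeContour] = []
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        crop = labels[sl] == idx
        top, left = sl[0].start, sl[1].start
        height, width = crop.shape
        # fill interior holes so area and bottom-row occupancy describe
        # the filled region, as a drawn-and-filled contour would
        filled = ndimage.binary_fill_holes(crop)
        interior = ndimage.binary_erosion(
            filled, structure=ndimage.generate_binary_structure(2, 1), border_value=0
        )
        boundary = np.argwhere(filled & ~interior)
        boundary += (top, left)
        contours.append(
            TreeContour(
                points=boundary,
                area=int(filled.sum()),
                bbox=(top, left, height, width),
                touches_bottom=bool(top + height == h and filled[-1].any()),
                filled=filled,
            )
        )
    return contours


def filter_contours(
    contours: list[TreeContour], min_area: int = 600, frame_shape=None
) -> list[TreeContour]:
    """Keep contours that are big enough and reach the bottom image row.

    Both criteria must hold: ``area >= min_area`` and
    ``touches_bottom``.  Order is preserved.  ``frame_shape`` is
    accepted for interface symmetry; the bottom-row flag is already
    computed against the source frame.
    """
    return [c for c in contours if c.area >= min_area and c.touches_bottom]


def _leftmost_bottom_col(contour: TreeContour) -> int:
    cols = np.flatnonzero(contour.filled[-1])
    return contour.bbox[1] + int(cols[0])


def detect(binary_mask: np.ndarray, params: DetectionParams = DetectionParams()) -> list[DetectedTree]:
    """Full detection stage: close → contours → filter → assign IDs.

    IDs are assigned left to right by each contour's leftmost
    bottom-row column, starting at 1.
    """
    closed = morphological_close(binary_mask, params.close_kernel, params.close_iterations)
    contours = filter_contours(find_contours(closed), params.min_area)
    contours.sort(key=_leftmost_bottom_col)
    return [DetectedTree(tree_id=i + 1, contour=c) for i, c in enumerate(contours)]
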