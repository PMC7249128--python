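"""Stem-candidate segmentation from aligned grayscale + depth frame pairs.

The segmentation stage turns one frame pair into a binary mask of likely
stem pixels in four moves:

1. a **depth mask** keeps only pixels in front of the tilted threshold
   plane (the harvested row), discarding background and invalid (zero)
   depth;
2. **CLAHE** (contrast-limited adaptive histogram equalization) boosts
   local contrast of the grayscale frame so stems separate from the
   background under variable outdoor light;
3. **dynamic histogram thresholding** finds the band of intensities that
   spikes inside the depth mask — the stem population — and every masked
   pixel carrying one of those intensities becomes a *seed point*;
4. a **fixed-range flood fill** grows each seed into the connected set of
   pixels within an asymmetric brightness band around the seed's own
   intensity; the union of the grown components is the segmentation.

All operations are deterministic; there is no randomness anywhere in the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage

from .geometry import CameraModel, ThresholdPlane, build_threshold_plane

__all__ = [
    "FramePair",
    "HistogramParams",
    "FloodParams",
    "SegmentationResult",
    "median_filter_depth",
    "depth_mask",
    "equalize_clahe",
    "dynamic_histogram_threshold",
    "background_removed",
    "find_seed_points",
    "flood_fill_segment",
    "segment",
]


@dataclass
class FramePair:
    """Aligned 8-bit grayscale frame and raw depth map (0 = no depth)."""

    gray: np.ndarray
    depth: np.ndarray
    timestamp: float = 0.0
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray)
        self.depth = np.asarray(self.depth)
        if self.gray.shape != self.depth.shape:
            raise ValueError(
                f"gray {self.gray.shape} and depth {self.depth.shape} shapes differ"
            )
        if self.gray.min(initial=0) < 0 or self.gray.max(initial=0) > 255:
            raise ValueError("gray intensities must lie in [0, 255]")
        if self.depth.min(initial=0) < 0:
            raise ValueError("depth values must be non-negative")


@dataclass(frozen=True)
class HistogramParams:
    """Parameters of the dynamic histogram threshold.

    ``peak_range`` is the total width (in bins) of the candidate band
    centred on the histogram maximum; ``low_limit`` clips the band from
    below; ``count_difference`` is the drop (in normalized count units,
    0–255) below the peak at which bins stop qualifying.  ``low_limit``
    and ``count_difference`` defaults are package choices, not sensor
    constants.
    """

    peak_range: int = 50
    low_limit: int = 10
    count_difference: float = 200.0

    def __post_init__(self) -> None:
        if self.peak_range < 0:
            raise ValueError("peak_range must be non-negative")
        if not (0 <= self.low_limit <= 255):
            raise ValueError("low_limit must be in [0, 255]")
        if not (0 <= self.count_difference <= 255):
            raise ValueError("count_difference must be in [0, 255]")


@dataclass(frozen=True)
class FloodParams:
    """Fixed-range flood-fill band and pixel connectivity.

    A pixel joins a seed's component iff its intensity lies within
    ``[seed - lowdiff, seed + updiff]`` — the band always references the
    original seed, not the neighbouring pixel.
    """

    lowdiff: float = 10.0
    updiff: float = 30.0
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.lowdiff < 0 or self.updiff < 0:
            raise ValueError("lowdiff and updiff must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SegmentationResult:
    """All intermediates of the segmentation stage, kept for inspection."""

    depth_median: np.ndarray
    depth_mask: np.ndarray
    gray_eq: np.ndarray
    intensity_list: np.ndarray
    seed_points: np.ndarray
    seeds_flooded: int
    binary_mask: np.ndarray


def median_filter_depth(depth: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median-filter the raw depth map with an odd square kernel.

    Removes within-region speckle while keeping stem edges sharp (the
    reason a median is preferred to a Gaussian here).  Borders are
    replicated.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    depth = np.asarray(depth)
    if kernel == 1:
        return depth.copy()
    return ndimage.median_filter(depth, size=kernel, mode="nearest")


def depth_mask(
    depth_median: np.ndarray, plane: ThresholdPlane, camera: CameraModel
) -> np.ndarray:
    """Binary mask of pixels in front of the threshold plane.

    A pixel is kept iff its metric depth (raw value × depth scale) is
    strictly less than the plane cutoff for its row *and* its raw depth
    is non-zero — zero encodes "no confident stereo match" and carries
    no information, so it is masked out.
    """
    depth_median = np.asarray(depth_median)
    thr = plane.per_row_threshold
    if depth_median.shape[0] != thr.shape[0]:
        raise ValueError(
            f"depth has {depth_median.shape[0]} rows but plane has {thr.shape[0]}"
        )
    metric = depth_median.astype(float) * camera.depth_scale
    out = (metric < thr[:, None]) & (depth_median > 0)
    return out.astype(np.uint8)


def _clahe_luts(tiles_view: np.ndarray, clip_limit: float) -> np.ndarray:
    """Per-tile clipped-CDF lookup tables, shape (ty, tx, 256)."""
    ty, tx, th, tw = tiles_view.shape[:4]
    area = th * tw
    luts = np.empty((ty, tx, 256), dtype=np.uint8)
    clip = max(1, int(clip_limit * area / 256.0)) if clip_limit > 0 else area
    scale = 255.0 / area
    for i in range(ty):
        for j in range(tx):
            hist = np.bincount(tiles_view[i, j].ravel(), minlength=256)
            excess = int(np.sum(np.maximum(hist - clip, 0)))
            if excess:
                hist = np.minimum(hist, clip)
                hist += excess // 256
                hist[: excess % 256] += 1
            cdf = np.cumsum(hist)
            luts[i, j] = np.clip(np.rint(cdf * scale), 0, 255).astype(np.uint8)
    return luts


def equalize_clahe(
    gray: np.ndarray, clip_limit: float = 40.0, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an 8-bit frame.

    The frame is divided into a ``tiles`` = (rows, cols) grid of
    subregions.  Each tile's 256-bin histogram is clipped at
    ``clip_limit × tile_area / 256`` counts, the excess is redistributed
    uniformly (remainder to the lowest bins), and the clipped CDF gives
    the tile's grayscale mapping.  Every pixel is remapped by bilinear
    interpolation of the four nearest tile mappings, which removes tile
    seams.  Frames not divisible by the grid are padded by edge
    replication before tiling and cropped afterwards.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("gray must be a 2-D array")
    if gray.dtype != np.uint8:
        if gray.min(initial=0) < 0 or gray.max(initial=0) > 255:
            raise ValueError("gray values must lie in [0, 255]")
        gray = gray.astype(np.uint8)
    h, w = gray.shape
    ty, tx = int(tiles[0]), int(tiles[1])
    if ty < 1 or tx < 1:
        raise ValueError("tile grid must be at least 1x1")
    if ty > h or tx > w:
        raise ValueError(f"tile grid {tiles} exceeds frame shape {gray.shape}")

    th = -(-h // ty)  # ceil division
    tw = -(-w // tx)
    padded = np.pad(gray, ((0, ty * th - h), (0, tx * tw - w)), mode="edge")
    view = padded.reshape(ty, th, tx, tw).transpose(0, 2, 1, 3)
    luts = _clahe_luts(view, clip_limit)

    # bilinear interpolation between tile-centre mappings, clamped at edges
    fy = (np.arange(h) + 0.5) / th - 0.5
    fx = (np.arange(w) + 0.5) / tw - 0.5
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]
    y0c = np.clip(y0, 0, ty - 1)[:, None]
    y1c = np.clip(y0 + 1, 0, ty - 1)[:, None]
    x0c = np.clip(x0, 0, tx - 1)[None, :]
    x1c = np.clip(x0 + 1, 0, tx - 1)[None, :]

    g = gray
    out = (
        (1 - wy) * (1 - wx) * luts[y0c, x0c, g]
        + (1 - wy) * wx * luts[y0c, x1c, g]
        + wy * (1 - wx) * luts[y1c, x0c, g]
        + wy * wx * luts[y1c, x1c, g]
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def dynamic_histogram_threshold(
    gray_eq: np.ndarray,
    mask: Optional[np.ndarray],
    params: HistogramParams = HistogramParams(),
) -> np.ndarray:
    """Intensities whose (normalized) counts spike with the stem population.

    The 256-bin histogram of ``gray_eq`` — restricted to ``mask`` = 1
    pixels when a mask is given — is min-max normalized to [0, 255].
    A candidate band of total width ``peak_range`` is centred on the
    maximum bin (lowest intensity wins ties), clipped to
    ``[low_limit, 255]``.  Every intensity in the band whose normalized
    count exceeds ``max_count - count_difference`` is returned, sorted
    ascending.  An empty mask yields an empty list.
    """
    gray_eq = np.asarray(gray_eq)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != gray_eq.shape:
            raise ValueError("mask and image shapes differ")
        values = gray_eq[mask != 0]
    else:
        values = gray_eq.ravel()
    if values.size == 0:
        return np.empty(0, dtype=np.intp)

    hist = np.bincount(values.astype(np.intp), minlength=256).astype(float)
    lo, hi = hist.min(), hist.max()
    if hi > lo:
        norm = (hist - lo) * (255.0 / (hi - lo))
    else:
        norm = np.zeros_like(hist)

    peak = int(np.argmax(norm))  # argmax takes the lowest index on ties
    half = params.peak_range // 2
    band_lo = max(params.low_limit, peak - half)
    band_hi = min(255, peak + half)
    threshold = norm[peak] - params.count_difference
    band = np.arange(band_lo, band_hi + 1)
    return band[norm[band] > threshold].astype(np.intp)


def background_removed(gray_eq: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Grayscale frame with everything outside the depth mask zeroed."""
    gray_eq = np.asarray(gray_eq)
    mask = np.asarray(mask)
    if gray_eq.shape != mask.shape:
        raise ValueError("gray_eq and mask shapes differ")
    return np.where(mask != 0, gray_eq, 0).astype(gray_eq.dtype)


def find_seed_points(
    background: np.ndarray, intensity_list: Iterable[int]
) -> np.ndarray:
    """Coordinates (row, col) of pixels matching a listed intensity.

    Scanned in row-major order.  Value 0 never seeds — it encodes
    removed background — even if present in the list.
    """
    background = np.asarray(background)
    values = np.asarray(list(intensity_list))
    if values.size == 0:
        return np.empty((0, 2), dtype=np.intp)
    hit = np.isin(background, values) & (background != 0)
    return np.argwhere(hit)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def flood_fill_segment(
    gray_eq: np.ndarray,
    seeds: np.ndarray,
    params: FloodParams = FloodParams(),
) -> tuple[np.ndarray, int]:
    """Union of fixed-range flood fills grown from the seed list.

    Seeds are processed in order; a seed already covered by the
    accumulating mask is skipped (it would only re-grow pixels that are
    already set for its own band, and the skip keeps runtime bounded).
    A flooded seed contributes the connected component, under the chosen
    connectivity, of pixels whose intensity lies in
    ``[seed - lowdiff, seed + updiff]`` — the band always references the
    seed pixel's intensity.

    Returns the binary mask and the number of seeds actually flooded.
    """
    gray_eq = np.asarray(gray_eq)
    h, w = gray_eq.shape
    seeds = np.asarray(seeds, dtype=np.intp).reshape(-1, 2)
    if seeds.size and (
        seeds[:, 0].min() < 0
        or seeds[:, 1].min() < 0
        or seeds[:, 0].max() >= h
        or seeds[:, 1].max() >= w
    ):
        raise ValueError("seed point out of frame bounds")

    structure = _connectivity_structure(params.connectivity)
    mask = np.zeros((h, w), dtype=np.uint8)
    flat_mask = mask.ravel()
    img = gray_eq.astype(np.int16)
    label_cache: dict[int, np.ndarray] = {}
    flooded = 0
    for r, c in seeds:
        if flat_mask[r * w + c]:
            continue
        v = int(img[r, c])
        labels = label_cache.get(v)
        if labels is None:
            band = (img >= v - params.lowdiff) & (img <= v + params.updiff)
            labels, _ = ndimage.label(band, structure=structure)
            labels = labels.ravel()
            label_cache[v] = labels
        component = np.flatnonzero(labels == labels[r * w + c])
        flat_mask[component] = 1
        flooded += 1
    return mask, flooded


def segment(
    frame: FramePair,
    camera: CameraModel,
    hist_params: HistogramParams = HistogramParams(),
    flood_params: FloodParams = FloodParams(),
    *,
    median_kernel: int = 5,
    clip_limit: float = 40.0,
    tiles: tuple[int, int] = (8, 8),
    histogram_scope: str = "masked",
    plane: Optional[ThresholdPlane] = None,
) -> SegmentationResult:
    """Run the full segmentation stage on one frame pair.

    Composes, in pipeline order: depth median filter → depth mask →
    CLAHE → dynamic histogram threshold → background removal → seed
    points → fixed-range flood fill.  ``histogram_scope`` selects
    whether the intensity histogram is computed over depth-masked pixels
    only (``"masked"``, default) or the full equalized frame
    (``"full"``).  All intermediates are returned.
    """
    if histogram_scope not in ("masked", "full"):
        raise ValueError("histogram_scope must be 'masked' or 'full'")
    if plane is None:
        plane = build_threshold_plane(camera)
    depth_med = median_filter_depth(frame.depth, median_kernel)
    dmask = depth_mask(depth_med, plane, camera)
    gray_eq = equalize_clahe(frame.gray, clip_limit=clip_limit, tiles=tiles)
    intensity_list = dynamic_histogram_threshold(
        gray_eq, dmask if histogram_scope == "masked" else None, hist_params
    )
    background = background_removed(gray_eq, dmask)
    seeds = find_seed_points(background, intensity_list)
    binary_mask, flooded = flood_fill_segment(gray_eq, seeds, flood_params)
    return SegmentationResult(
        depth_median=depth_med,
        depth_mask=dmask,
        gray_eq=gray_eq,
        intensity_list=intensity_list,
        seed_points=seeds,
        seeds_flooded=flooded,
        binary_mask=binary_mask,
    )
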