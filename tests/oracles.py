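"""Brute-force reference implementations used as independent oracles.

Every function here recomputes a pipeline operation by direct definition
(nested loops, explicit set arithmetic, breadth-first search) with no
shared code with the package.  They are intentionally slow and only used
on small arrays.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def median_filter_ref(a: np.ndarray, k: int) -> np.ndarray:
    """Per-pixel median with replicated borders, by nested loops."""
    h, w = a.shape
    r = k // 2
    out = np.empty_like(a)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(a[ii, jj])
            out[i, j] = np.median(vals)
    return out


def depth_mask_ref(depth: np.ndarray, plane_m: np.ndarray, depth_scale: float) -> np.ndarray:
    """Elementwise threshold-plane comparison."""
    h, w = depth.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            if depth[i, j] > 0 and depth[i, j] * depth_scale < plane_m[i]:
                out[i, j] = 1
    return out


def clahe_ref(gray: np.ndarray, clip_limit: float, tiles: tuple[int, int]) -> np.ndarray:
    """Scalar-loop CLAHE: clipped per-tile CDF LUTs + bilinear remap.

    Same conventions as the package states in its docstring: tile grid
    of shape ``tiles``, edge-replication padding, clip at
    ``clip_limit * area / 256`` counts, uniform excess redistribution
    with the remainder added to the lowest bins, LUT = round(cdf *
    255 / area), interpolation between tile centres clamped at edges.
    """
    h, w = gray.shape
    ty, tx = tiles
    th = -(-h // ty)
    tw = -(-w // tx)
    padded = np.pad(gray, ((0, ty * th - h), (0, tx * tw - w)), mode="edge")
    area = th * tw
    clip = max(1, int(clip_limit * area / 256.0)) if clip_limit > 0 else area

    luts = np.zeros((ty, tx, 256))
    for i in range(ty):
        for j in range(tx):
            hist = [0] * 256
            for r in range(th):
                for c in range(tw):
                    hist[int(padded[i * th + r, j * tw + c])] += 1
            excess = sum(max(v - clip, 0) for v in hist)
            hist = [min(v, clip) for v in hist]
            hist = [v + excess // 256 for v in hist]
            for b in range(excess % 256):
                hist[b] += 1
            cdf = 0
            for b in range(256):
                cdf += hist[b]
                luts[i, j, b] = min(255, max(0, round(cdf * 255.0 / area)))

    out = np.empty((h, w), dtype=np.uint8)
    for r in range(h):
        fy = (r + 0.5) / th - 0.5
        y0 = int(np.floor(fy))
        wy = fy - y0
        y0c, y1c = min(max(y0, 0), ty - 1), min(max(y0 + 1, 0), ty - 1)
        for c in range(w):
            fx = (c + 0.5) / tw - 0.5
            x0 = int(np.floor(fx))
            wx = fx - x0
            x0c, x1c = min(max(x0, 0), tx - 1), min(max(x0 + 1, 0), tx - 1)
            g = int(gray[r, c])
            val = (
                (1 - wy) * (1 - wx) * luts[y0c, x0c, g]
                + (1 - wy) * wx * luts[y0c, x1c, g]
                + wy * (1 - wx) * luts[y1c, x0c, g]
                + wy * wx * luts[y1c, x1c, g]
            )
            out[r, c] = min(255, max(0, round(val)))
    return out


def hist_threshold_ref(
    gray: np.ndarray, mask, peak_range: int, low_limit: int, count_difference: float
) -> list[int]:
    """Exhaustive per-bin evaluation of the dynamic histogram threshold."""
    vals = [
        int(gray[i, j])
        for i in range(gray.shape[0])
        for j in range(gray.shape[1])
        if mask is None or mask[i, j]
    ]
    if not vals:
        return []
    hist = [0.0] * 256
    for v in vals:
        hist[v] += 1
    lo, hi = min(hist), max(hist)
    norm = [(v - lo) * 255.0 / (hi - lo) if hi > lo else 0.0 for v in hist]
    peak = max(range(256), key=lambda b: (norm[b], -b))
    band_lo = max(low_limit, peak - peak_range // 2)
    band_hi = min(255, peak + peak_range // 2)
    return [
        b for b in range(band_lo, band_hi + 1) if norm[b] > norm[peak] - count_difference
    ]


def seed_points_ref(background: np.ndarray, intensities) -> list[tuple[int, int]]:
    """Double-loop membership scan; zero never seeds."""
    hits = []
    wanted = set(int(v) for v in intensities)
    for i in range(background.shape[0]):
        for j in range(background.shape[1]):
            v = int(background[i, j])
            if v != 0 and v in wanted:
                hits.append((i, j))
    return hits


def flood_fill_ref(
    gray: np.ndarray, seeds, lowdiff: float, updiff: float, connectivity: int = 4
) -> tuple[np.ndarray, int]:
    """Breadth-first-search flood fill with the seed-skip rule."""
    h, w = gray.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    mask = np.zeros((h, w), dtype=np.uint8)
    flooded = 0
    for sr, sc in seeds:
        if mask[sr, sc]:
            continue
        flooded += 1
        v = int(gray[sr, sc])
        visited = np.zeros((h, w), dtype=bool)
        queue = deque([(sr, sc)])
        visited[sr, sc] = True
        while queue:
            r, c = queue.popleft()
            mask[r, c] = 1
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not visited[rr, cc]:
                    if v - lowdiff <= int(gray[rr, cc]) <= v + updiff:
                        visited[rr, cc] = True
                        queue.append((rr, cc))
    return mask, flooded


def closing_ref(mask: np.ndarray, kernel_shape: tuple[int, int]) -> np.ndarray:
    """Minkowski set-arithmetic closing (dilation then erosion).

    Offsets are structure indices minus ``shape // 2``; pixels beyond
    the frame count as background for the dilation and as foreground
    for the erosion (regions touching the edge are not eaten from
    outside).
    """
    h, w = mask.shape
    kh, kw = kernel_shape
    offs = [(i - kh // 2, j - kw // 2) for i in range(kh) for j in range(kw)]
    dil = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                for dr, dc in offs:
                    if 0 <= r + dr < h and 0 <= c + dc < w:
                        dil[r + dr, c + dc] = True
    ero = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                inside = 0 <= rr < h and 0 <= cc < w
                if inside and not dil[rr, cc]:
                    ok = False
                    break
            ero[r, c] = 1 if ok else 0
    return ero


def component_areas_ref(mask: np.ndarray) -> list[int]:
    """Filled areas of 8-connected components via BFS labelling."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    areas = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                area = 0
                queue = deque([(i, j)])
                seen[i, j] = True
                while queue:
                    r, c = queue.popleft()
                    area += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                areas.append(area)
    return areas


def filled_component_areas_ref(mask: np.ndarray) -> list[int]:
    """Hole-filled areas of 8-connected components.

    Background cells (4-connected) unreachable from the image border are
    holes; each hole region is enclosed by exactly one 8-connected
    component and its pixels count toward that component's filled area.
    """
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    areas = {}
    nxt = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not labels[i, j]:
                nxt += 1
                queue = deque([(i, j)])
                labels[i, j] = nxt
                count = 0
                while queue:
                    r, c = queue.popleft()
                    count += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                                labels[rr, cc] = nxt
                                queue.append((rr, cc))
                areas[nxt] = count
    # background reachable from the border (4-connectivity)
    outside = np.zeros((h, w), dtype=bool)
    queue = deque()
    for i in range(h):
        for j in range(w):
            if (i in (0, h - 1) or j in (0, w - 1)) and not mask[i, j]:
                if not outside[i, j]:
                    outside[i, j] = True
                    queue.append((i, j))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                queue.append((rr, cc))
    hole_seen = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if mask[i, j] or outside[i, j] or hole_seen[i, j]:
                continue
            # flood the whole hole region, remember any enclosing label
            region = []
            enclosing = 0
            queue = deque([(i, j)])
            hole_seen[i, j] = True
            while queue:
                r, c = queue.popleft()
                region.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w):
                            continue
                        if labels[rr, cc]:
                            enclosing = labels[rr, cc]
                        elif (
                            abs(dr) + abs(dc) == 1
                            and not mask[rr, cc]
                            and not outside[rr, cc]
                            and not hole_seen[rr, cc]
                        ):
                            hole_seen[rr, cc] = True
                            queue.append((rr, cc))
            areas[enclosing] += len(region)
    return list(areas.values())


def widest_run_ref(row) -> tuple[int, int]:
    """Enumerate all maximal solid runs, return the widest (leftmost tie)."""
    best = (0, 0)
    i = 0
    n = len(row)
    while i < n:
        if row[i]:
            j = i
            while j < n and row[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def threshold_plane_ref(
    fov_y: float, tilt: float, bottom: float, n_rows: int
) -> np.ndarray:
    """Per-row hypotenuse to a vertical plane, solved independently.

    The bottom ray (elevation tilt − fov_y/2) has length ``bottom``; the
    vertical plane passes through its endpoint at horizontal distance
    ``bottom · cos(θ_bottom)``.  Row r's ray has elevation increasing
    linearly to tilt + fov_y/2 at the top row, and its length is the
    horizontal distance over cos(elevation).  Monotonicity enforced by a
    running max from the bottom.
    """
    import math

    theta_b = math.radians(tilt - fov_y / 2.0)
    horiz = bottom * math.cos(theta_b)
    out = np.empty(n_rows)
    for r in range(n_rows):
        frac = (n_rows - 1 - r) / (n_rows - 1) if n_rows > 1 else 0.0
        theta = theta_b + frac * math.radians(fov_y)
        out[r] = horiz / math.cos(theta)
    out[-1] = bottom
    for r in range(n_rows - 2, -1, -1):
        out[r] = max(out[r], out[r + 1])
    return out
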