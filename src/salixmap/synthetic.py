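"""Synthetic willow-row scenes with exact ground truth.

The generator emulates what the harvest rig sees: near-vertical stems on
a row plane ≈1.22–1.23 m from the camera spanning the full frame height,
background well beyond the threshold plane, slanted branch clutter
leaning out of the row (the designated false-positive source), a
horizontal illumination gradient, oversaturated patches where sunlight
breaks through the canopy, and a depth map with Gaussian sensor noise
and dropout zeros where stereo matching failed.

Each stem is rendered at the pixel width obtained by inverting the
pixel-to-millimetre chain at its true depth, so a perfect pipeline
recovers its diameter up to quantization.  Everything is deterministic
per seed.

What this generator does *not* emulate: perspective foreshortening
within a frame, leaf canopy occlusion, motion blur, and photometric
stereo artefacts — results on these scenes bound algorithmic behaviour,
not field performance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .geometry import CameraModel
from .geotag import GeoFix, write_nmea
from .segmentation import FramePair

__all__ = [
    "SceneSpec",
    "GroundTruthObject",
    "generate_scene",
    "iter_scenes",
    "generate_suite",
    "PRESETS",
]

_STEM_MARGIN_PX = 20  # minimum free columns between stem bottom spans


@dataclass(frozen=True)
class SceneSpec:
    """Conditions of one synthetic frame.

    Defaults model the study row: eight stems per frame with diameters
    spanning the commercial size classes (lower bound 28.57 mm), stem
    depths inside the harvested row (1.218–1.229 m — the rig's depth
    mask is designed so the row sits in front of the 1.23 m bottom-row
    cutoff), background at 3 m, stems darker than the background
    (grey 80 vs 170) with fine bark texture.
    Clutter and degradation terms default to zero; presets switch them
    on.
    """

    n_stems: int = 8
    diameter_range_mm: tuple[float, float] = (28.57, 60.0)
    stem_depth_m: float = 1.2235
    stem_depth_jitter_m: float = 0.0055
    n_branches: int = 0
    branch_width_range_mm: tuple[float, float] = (8.0, 18.0)
    background_depth_m: float = 3.0
    stem_intensity: float = 80.0
    background_intensity: float = 170.0
    texture_sigma: float = 6.0
    gradient_amplitude: float = 0.0
    saturation_probability: float = 0.0
    depth_noise_sigma: float = 0.0
    depth_dropout_rate: float = 0.0
    force_dropped_stem: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_range_mm[0] <= 0:
            raise ValueError("diameters must be positive")
        if self.stem_depth_m >= self.background_depth_m:
            raise ValueError("stem depth must be closer than the background")
        for rate in (self.saturation_probability, self.depth_dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthObject:
    """One rendered object: its kind, bottom span and true size.

    ``span`` is the half-open bottom-row column interval (empty for a
    branch that does not reach the bottom row).  ``meets_min_width``
    flags objects at least 10 px wide at half frame height — the manual
    scoring floor for countable stems.  ``expect_false_positive`` marks
    branches that reach the bottom row with enough area to survive the
    contour filter; detecting them is the algorithm's documented failure
    mode, not a generator error.
    """

    kind: str
    span: tuple[int, int]
    diameter_mm: float
    depth_raw: int
    meets_min_width: bool
    expect_false_positive: bool = False


def _strip_mask(
    shape: tuple[int, int],
    rows: np.ndarray,
    centers: np.ndarray,
    width: int,
) -> np.ndarray:
    """Boolean mask of a (possibly slanted) vertical strip of fixed width."""
    h, w = shape
    lefts = np.clip(np.rint(centers - width / 2.0).astype(int), 0, w - width)
    mask = np.zeros(shape, dtype=bool)
    cols = np.arange(w)
    mask[rows] = (cols >= lefts[:, None]) & (cols < (lefts[:, None] + width))
    return mask


def generate_scene(
    spec: SceneSpec, camera: CameraModel, rng: Optional[np.random.Generator] = None
) -> tuple[FramePair, list[GroundTruthObject]]:
    """Render one grayscale + depth frame pair with its ground truth.

    Raises if the requested stems (plus margins) cannot be packed into
    the frame width.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = camera.frame_height, camera.frame_width

    gray = np.full((h, w), spec.background_intensity, dtype=float)
    depth = np.full((h, w), spec.background_depth_m / camera.depth_scale, dtype=float)
    truth: list[GroundTruthObject] = []
    all_rows = np.arange(h)

    # ---- stems: full-height, slightly slanted, disjoint bottom spans ----
    diameters = rng.uniform(*spec.diameter_range_mm, size=spec.n_stems)
    depths_m = spec.stem_depth_m + rng.uniform(
        -spec.stem_depth_jitter_m, spec.stem_depth_jitter_m, size=spec.n_stems
    )
    depth_raw = np.rint(depths_m / camera.depth_scale).astype(int)
    widths = np.array(
        [
            max(1, round(d / camera.mm_per_pixel(z)))
            for d, z in zip(diameters, depth_raw)
        ]
    )
    needed = int(widths.sum()) + (spec.n_stems + 1) * _STEM_MARGIN_PX
    if needed > w:
        raise ValueError(
            f"cannot pack {spec.n_stems} stems (need {needed} px, frame is {w})"
        )
    # distribute the leftover width randomly among the inter-stem gaps
    extra = w - needed
    gaps = _STEM_MARGIN_PX + np.floor(
        rng.dirichlet(np.ones(spec.n_stems + 1)) * extra
    ).astype(int)
    lefts = np.cumsum(gaps[:-1]) + np.concatenate(([0], np.cumsum(widths[:-1])))

    stem_masks = []
    for i in range(spec.n_stems):
        width = int(widths[i])
        slope = rng.uniform(-0.015, 0.015)  # px of drift per row upward
        center_bottom = lefts[i] + width / 2.0
        centers = center_bottom + slope * (h - 1 - all_rows)
        mask = _strip_mask((h, w), all_rows, centers, width)
        # pin the bottom-row span exactly
        mask[-1] = False
        mask[-1, lefts[i] : lefts[i] + width] = True
        stem_masks.append(mask)
        gray[mask] = spec.stem_intensity
        depth[mask] = depth_raw[i]
        truth.append(
            GroundTruthObject(
                kind="stem",
                span=(int(lefts[i]), int(lefts[i] + width)),
                diameter_mm=float(diameters[i]),
                depth_raw=int(depth_raw[i]),
                meets_min_width=width >= 10,
            )
        )

    # ---- branches: near-vertical strips leaning out of the row ----
    # Branches hang into the camera's view mostly between stems (one in
    # front of a stem just merges into the stem's silhouette); being
    # nearly vertical is exactly why the detector mistakes them for stems.
    gap_lo = np.concatenate(([0], lefts + widths))
    gap_hi = np.concatenate((lefts, [w]))
    for _ in range(spec.n_branches):
        width_mm = rng.uniform(*spec.branch_width_range_mm)
        branch_depth_m = spec.stem_depth_m - rng.uniform(0.05, 0.20)
        braw = int(round(branch_depth_m / camera.depth_scale))
        bwidth = max(1, round(width_mm / camera.mm_per_pixel(braw)))
        touches = rng.random() < 0.5
        length = int(rng.uniform(0.25, 0.55) * h)
        r_end = h - 1 if touches else int(rng.uniform(0.45, 0.85) * (h - 1))
        r_start = max(0, r_end - length)
        rows = np.arange(r_start, r_end + 1)
        slope = rng.choice([-1.0, 1.0]) * np.tan(np.radians(rng.uniform(5, 25)))
        gap_idx = int(rng.integers(0, len(gap_lo)))
        lo, hi = float(gap_lo[gap_idx]), float(gap_hi[gap_idx])
        base = rng.uniform(lo + bwidth, max(lo + bwidth + 1.0, hi - bwidth))
        centers = base + slope * (r_end - rows)
        inside = (centers > -bwidth) & (centers < w + bwidth)
        rows, centers = rows[inside], centers[inside]
        if rows.size == 0:
            continue
        mask = _strip_mask((h, w), rows, centers, bwidth)
        gray[mask] = spec.stem_intensity + rng.uniform(-8, 8)
        depth[mask] = braw
        span = (0, 0)
        if touches and mask[-1].any():
            cols = np.flatnonzero(mask[-1])
            span = (int(cols[0]), int(cols[-1] + 1))
        truth.append(
            GroundTruthObject(
                kind="branch",
                span=span,
                diameter_mm=float(width_mm),
                depth_raw=braw,
                meets_min_width=bool(mask[h // 2].sum() >= 10),
                expect_false_positive=bool(
                    touches and mask[-1].any() and int(mask.sum()) >= 600
                ),
            )
        )

    # ---- photometric effects ----
    gray += rng.normal(0.0, spec.texture_sigma, size=(h, w))
    if spec.gradient_amplitude:
        gray += spec.gradient_amplitude * (np.arange(w) / (w - 1) * 2.0 - 1.0)
    if spec.saturation_probability and rng.random() < spec.saturation_probability:
        # sunlight through the canopy: additive glare blobs in the upper
        # frame that wash out contrast and clip to 255 only at their core
        yy = np.arange(h, dtype=float)[:, None]
        xx = np.arange(w, dtype=float)[None, :]
        for _ in range(rng.integers(1, 4)):
            cy = rng.uniform(0.0, 0.4) * h
            cx = rng.uniform(0.0, 1.0) * w
            sy = rng.uniform(0.04, 0.12) * h
            sx = rng.uniform(0.04, 0.15) * w
            amp = rng.uniform(80.0, 160.0)
            gray += amp * np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))

    # ---- depth degradation ----
    if spec.depth_noise_sigma:
        depth += rng.normal(0.0, spec.depth_noise_sigma, size=(h, w))
    depth = np.clip(np.rint(depth), 0, np.iinfo(np.uint16).max)
    if spec.depth_dropout_rate:
        depth[rng.random((h, w)) < spec.depth_dropout_rate] = 0
    if spec.force_dropped_stem and stem_masks:
        # stereo dropout over the stem's whole measurement region: no
        # valid depth anywhere near the bottom row, so the diameter must
        # come from the frame-median fallback.  (Depth survives higher
        # up — a stem with no depth at all would never enter the depth
        # mask and could not be detected in the first place.)
        lower = stem_masks[0].copy()
        lower[: 2 * h // 3] = False
        depth[lower] = 0

    frame = FramePair(
        gray=np.clip(np.rint(gray), 0, 255).astype(np.uint8),
        depth=depth.astype(np.uint16),
    )
    return frame, truth


#: Named study conditions: ``clean`` isolates quantization effects,
#: ``paper_like`` adds branch clutter, light gradient, depth noise (σ=10
#: raw units) and 5% dropout, ``stress`` pushes every degradation term
#: further and, in the first frame, drops all depth in one stem's
#: measurement region to exercise the diameter fallback.
PRESETS: dict[str, dict] = {
    "clean": dict(),
    "paper_like": dict(
        n_branches=3,
        gradient_amplitude=25.0,
        saturation_probability=0.15,
        depth_noise_sigma=10.0,
        depth_dropout_rate=0.05,
    ),
    "stress": dict(
        n_branches=5,
        gradient_amplitude=35.0,
        saturation_probability=0.3,
        depth_noise_sigma=15.0,
        depth_dropout_rate=0.15,
    ),
}


def iter_scenes(
    preset: str,
    n_frames: int,
    seed: int,
    camera: CameraModel,
    *,
    frame_interval_s: float = 1.0,
    t0: float = 12 * 3600.0,
) -> Iterator[tuple[FramePair, list[GroundTruthObject]]]:
    """Yield deterministic frame pairs + ground truth for a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    master = np.random.default_rng(seed)
    frame_seeds = master.integers(0, 2**31 - 1, size=n_frames)
    for i in range(n_frames):
        overrides = dict(PRESETS[preset])
        if preset == "stress" and i == 0:
            overrides["force_dropped_stem"] = True
        spec = SceneSpec(seed=int(frame_seeds[i]), **overrides)
        frame, truth = generate_scene(spec, camera)
        frame.frame_id = i
        frame.timestamp = t0 + i * frame_interval_s
        yield frame, truth


def _track_fixes(
    timestamps: np.ndarray,
    *,
    lat0: float = 45.85,
    lon0: float = -73.45,
    speed_m_s: float = 0.639,
) -> list[GeoFix]:
    """Straight eastbound track at harvest speed (2.3 km/h)."""
    meters_per_deg_lon = 111320.0 * np.cos(np.radians(lat0))
    fixes = []
    t_start = float(timestamps[0])
    for t in timestamps:
        dx = speed_m_s * (float(t) - t_start)
        fixes.append(GeoFix(float(t), lat0, lon0 + dx / meters_per_deg_lon))
    return fixes


def generate_suite(
    preset: str,
    n_frames: int,
    seed: int,
    outdir,
    camera: Optional[CameraModel] = None,
) -> Path:
    """Write a frame-pair suite to disk and return the manifest path.

    Produces per-frame grayscale (8-bit PNG) and depth (16-bit PNG)
    images, ``manifest.csv`` (frame_id, gray_path, depth_path,
    timestamp), ``ground_truth.csv`` (one row per rendered object) and
    ``track.nmea``, a GGA log along a straight track at harvest speed.
    """
    import imageio.v3 as iio

    if camera is None:
        camera = CameraModel()
    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)

    manifest_rows, truth_rows, timestamps = [], [], []
    for frame, truth in iter_scenes(preset, n_frames, seed, camera):
        gray_path = outdir / "frames" / f"frame_{frame.frame_id:04d}_gray.png"
        depth_path = outdir / "frames" / f"frame_{frame.frame_id:04d}_depth.png"
        iio.imwrite(gray_path, frame.gray)
        iio.imwrite(depth_path, frame.depth)
        manifest_rows.append(
            {
                "frame_id": frame.frame_id,
                "gray_path": str(gray_path.relative_to(outdir)),
                "depth_path": str(depth_path.relative_to(outdir)),
                "timestamp": frame.timestamp,
            }
        )
        timestamps.append(frame.timestamp)
        for obj in truth:
            truth_rows.append({"frame_id": frame.frame_id, **dataclasses.asdict(obj)})

    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    tdf = pd.DataFrame(truth_rows)
    tdf[["span_start", "span_end"]] = pd.DataFrame(tdf["span"].tolist(), index=tdf.index)
    tdf.drop(columns=["span"]).to_csv(outdir / "ground_truth.csv", index=False)
    write_nmea(_track_fixes(np.asarray(timestamps)), outdir / "track.nmea")
    return manifest_path
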