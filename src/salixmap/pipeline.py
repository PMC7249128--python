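"""Frame-level and run-level drivers binding all pipeline stages.

``process_frame`` runs segmentation → detection → diameter measurement
on one frame pair.  ``run_manifest`` processes a whole recording (a
manifest CSV pointing at grayscale/depth image pairs), optionally
geotags frames from an NMEA log, and writes the detection CSV and
transect outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .detection import DetectedTree, detect
from .diameter import bottom_profile, measure_trees
from .geometry import build_threshold_plane
from .geotag import build_transect, parse_nmea, tag_frames, write_transect
from .segmentation import FramePair, SegmentationResult, segment

__all__ = ["process_frame", "detections_to_frame", "read_frame_pair", "run_manifest"]

logger = logging.getLogger(__name__)


def process_frame(
    frame: FramePair, config: Optional[PipelineConfig] = None, *, plane=None
) -> tuple[SegmentationResult, list[DetectedTree]]:
    """Segment, detect and measure one frame pair."""
    if config is None:
        config = PipelineConfig()
    seg = segment(
        frame,
        config.camera,
        config.histogram,
        config.flood,
        median_kernel=config.median_kernel,
        clip_limit=config.clahe_clip_limit,
        tiles=config.clahe_tiles,
        histogram_scope=config.histogram_scope,
        plane=plane,
    )
    trees = detect(seg.binary_mask, config.detection)
    measure_trees(trees, seg.depth_median, config.camera)
    return seg, trees


def detections_to_frame(
    trees: list[DetectedTree], depth_median: np.ndarray, frame_id: int
) -> pd.DataFrame:
    """Per-tree detection rows (one frame) ready for CSV output."""
    rows = []
    for t in trees:
        profile = bottom_profile(t.contour, depth_median)
        m = t.measurement
        rows.append(
            {
                "frame_id": frame_id,
                "tree_id": t.tree_id,
                "area": t.contour.area,
                "bbox_top": t.contour.bbox[0],
                "bbox_left": t.contour.bbox[1],
                "bbox_height": t.contour.bbox[2],
                "bbox_width": t.contour.bbox[3],
                "span_start": profile.chosen_span[0],
                "span_end": profile.chosen_span[1],
                "pixel_width": m.pixel_width if m else profile.pixel_width,
                "depth_raw": m.depth_value if m else profile.depth_value,
                "diameter_mm": round(m.diameter_mm, 2) if m else float("nan"),
            }
        )
    columns = [
        "frame_id", "tree_id", "area", "bbox_top", "bbox_left", "bbox_height",
        "bbox_width", "span_start", "span_end", "pixel_width", "depth_raw",
        "diameter_mm",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_frame_pair(gray_path, depth_path, timestamp: float, frame_id: int) -> FramePair:
    """Load one grayscale (8-bit) + depth (16-bit) image pair."""
    import imageio.v3 as iio

    gray = np.asarray(iio.imread(gray_path))
    depth = np.asarray(iio.imread(depth_path))
    if gray.ndim == 3:
        gray = gray[..., 0]
    return FramePair(gray=gray, depth=depth, timestamp=timestamp, frame_id=frame_id)


def run_manifest(
    manifest_path,
    config: Optional[PipelineConfig] = None,
    outdir=None,
    nmea_path=None,
) -> pd.DataFrame:
    """Process every frame of a recording manifest; return the detections.

    Writes ``detections.csv`` (and, when an NMEA log is given,
    ``transect.csv`` + ``transect.geojson``) under ``outdir``.  An
    unreadable frame is logged and skipped; if every frame fails, an
    error is raised.
    """
    if config is None:
        config = PipelineConfig()
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError(f"manifest {manifest_path} lists no frames")
    base = manifest_path.parent
    plane = build_threshold_plane(config.camera)

    per_frame: list[pd.DataFrame] = []
    frame_meta: list[tuple[int, float, list[float]]] = []
    n_failed = 0
    for row in manifest.itertuples():
        try:
            frame = read_frame_pair(
                base / row.gray_path, base / row.depth_path, row.timestamp, row.frame_id
            )
            seg, trees = process_frame(frame, config, plane=plane)
        except Exception:
            logger.exception("frame %s failed, skipping", row.frame_id)
            n_failed += 1
            continue
        det = detections_to_frame(trees, seg.depth_median, int(row.frame_id))
        per_frame.append(det)
        frame_meta.append(
            (int(row.frame_id), float(row.timestamp), det["diameter_mm"].tolist())
        )
        logger.info(
            "frame %s: seeds=%d flooded=%d trees=%d",
            row.frame_id, len(seg.seed_points), seg.seeds_flooded, len(trees),
        )
    if not frame_meta:
        raise RuntimeError("all frames failed to process")
    if n_failed:
        logger.warning("%d of %d frames failed", n_failed, len(manifest))

    detections = (
        pd.concat(per_frame, ignore_index=True)
        if per_frame
        else detections_to_frame([], np.zeros((1, 1)), 0)
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        detections.to_csv(outdir / "detections.csv", index=False)
        if nmea_path is not None:
            fixes = parse_nmea(Path(nmea_path).read_text())
            positions = tag_frames(
                [t for _, t, _ in frame_meta], fixes,
                clock_offset=config.gnss_clock_offset_s,
            )
            records = build_transect(
                [fid for fid, _, _ in frame_meta],
                positions,
                [len(d) for _, _, d in frame_meta],
                [d for _, _, d in frame_meta],
            )
            write_transect(records, outdir / "transect.csv", outdir / "transect.geojson")
    return detections
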