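"""GNSS log parsing, frame tagging and yield-transect output.

The harvest rig logs raw NMEA 0183 sentences alongside the camera
stream.  This module parses GGA fixes (position, time of day, fix
quality) plus RMC for the date, associates a coordinate with every
frame timestamp by linear interpolation between bracketing fixes, and
emits the per-frame yield transect — geotagged tree counts and
diameters with a cumulative along-row distance — as CSV and GeoJSON.

No deduplication of trees seen in overlapping frames is attempted;
repeated sightings inflate the transect counts and are a known
over-count source.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeoFix",
    "TransectRecord",
    "parse_nmea",
    "tag_frames",
    "build_transect",
    "haversine_m",
    "format_gga",
    "write_nmea",
]

logger = logging.getLogger(__name__)

_EARTH_RADIUS_M = 6371000.0


@dataclass(frozen=True)
class GeoFix:
    """One GNSS fix: UTC seconds, decimal-degree coordinates, quality code."""

    timestamp: float
    lat: float
    lon: float
    quality: int = 1

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")


@dataclass
class TransectRecord:
    """Per-frame transect entry: position, detections, along-row distance."""

    frame_id: int
    lat: float
    lon: float
    tree_count: int
    diameters_mm: list[float] = field(default_factory=list)
    distance_along_row_m: float = 0.0

    def __post_init__(self) -> None:
        if self.tree_count != len(self.diameters_mm):
            raise ValueError("tree_count must equal the number of diameters")


def _nmea_checksum(payload: str) -> int:
    cs = 0
    for ch in payload:
        cs ^= ord(ch)
    return cs


def _dm_to_degrees(value: str, hemi: str) -> float:
    """ddmm.mmmm / dddmm.mmmm plus hemisphere letter → signed decimal degrees."""
    v = float(value)
    degrees = math.floor(v / 100.0)
    minutes = v - degrees * 100.0
    out = degrees + minutes / 60.0
    if hemi in ("S", "W"):
        out = -out
    return out


def _hms_to_seconds(token: str) -> float:
    hh = int(token[0:2])
    mm = int(token[2:4])
    ss = float(token[4:])
    return hh * 3600.0 + mm * 60.0 + ss


def parse_nmea(lines: Iterable[str] | str, *, drop_unfixed: bool = True) -> list[GeoFix]:
    """Parse raw NMEA text into time-ordered :class:`GeoFix` records.

    GGA sentences supply time-of-day, position and fix quality; an RMC
    sentence (when present) anchors the date so timestamps become epoch
    seconds, otherwise they are UTC seconds since midnight.  Checksums
    are validated; malformed or failing lines are skipped with a logged
    warning.  Fixes with quality code 0 (no fix) are dropped unless
    ``drop_unfixed`` is false.  Raises if no valid fix survives.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    fixes: list[GeoFix] = []
    date_offset: Optional[float] = None
    for raw in lines:
        line = raw.strip()
        if not line.startswith("$"):
            continue
        if "*" not in line:
            logger.warning("NMEA line without checksum skipped: %r", line)
            continue
        payload, _, cs_text = line[1:].rpartition("*")
        try:
            if _nmea_checksum(payload) != int(cs_text, 16):
                logger.warning("NMEA checksum mismatch, line skipped: %r", line)
                continue
        except ValueError:
            logger.warning("unreadable NMEA checksum, line skipped: %r", line)
            continue
        fieldv = payload.split(",")
        talker = fieldv[0]
        try:
            if talker.endswith("RMC") and len(fieldv) > 9 and fieldv[9]:
                day, month, year = int(fieldv[9][0:2]), int(fieldv[9][2:4]), int(fieldv[9][4:6])
                date = _dt.datetime(2000 + year, month, day, tzinfo=_dt.timezone.utc)
                date_offset = date.timestamp()
            elif talker.endswith("GGA"):
                if not (fieldv[1] and fieldv[2] and fieldv[4]):
                    logger.warning("incomplete GGA fix skipped: %r", line)
                    continue
                fixes.append(
                    GeoFix(
                        timestamp=_hms_to_seconds(fieldv[1]),
                        lat=_dm_to_degrees(fieldv[2], fieldv[3]),
                        lon=_dm_to_degrees(fieldv[4], fieldv[5]),
                        quality=int(fieldv[6] or 0),
                    )
                )
        except (ValueError, IndexError):
            logger.warning("malformed NMEA sentence skipped: %r", line)
    if date_offset is not None:
        fixes = [
            GeoFix(f.timestamp + date_offset, f.lat, f.lon, f.quality) for f in fixes
        ]
    if drop_unfixed:
        fixes = [f for f in fixes if f.quality != 0]
    if not fixes:
        raise ValueError("no valid GNSS fixes in input")
    fixes.sort(key=lambda f: f.timestamp)
    return fixes


def tag_frames(
    frame_timestamps: Sequence[float],
    fixes: Sequence[GeoFix],
    *,
    clock_offset: float = 0.0,
) -> np.ndarray:
    """Interpolate a (lat, lon) for every frame timestamp.

    Linear interpolation between bracketing fixes; frames outside the
    covered interval clamp to the nearest fix.  ``clock_offset`` (added
    to frame clocks) absorbs a constant camera/GNSS clock disagreement.
    Returns an (n, 2) array of (lat, lon).
    """
    if not fixes:
        raise ValueError("no GNSS fixes to interpolate from")
    t = np.asarray([f.timestamp for f in fixes])
    lat = np.asarray([f.lat for f in fixes])
    lon = np.asarray([f.lon for f in fixes])
    ft = np.asarray(frame_timestamps, dtype=float) + clock_offset
    return np.column_stack([np.interp(ft, t, lat), np.interp(ft, t, lon)])


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres between two coordinates."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_M * math.asin(math.sqrt(a))


def build_transect(
    frame_ids: Sequence[int],
    positions: np.ndarray,
    tree_counts: Sequence[int],
    diameters_mm: Sequence[Sequence[float]],
) -> list[TransectRecord]:
    """Assemble the yield transect: per-frame records with cumulative distance."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(frame_ids)
    if not (len(positions) == len(tree_counts) == len(diameters_mm) == n):
        raise ValueError("frame_ids, positions, counts and diameters must align")
    records: list[TransectRecord] = []
    dist = 0.0
    for i in range(n):
        if i > 0:
            dist += haversine_m(*positions[i - 1], *positions[i])
        records.append(
            TransectRecord(
                frame_id=int(frame_ids[i]),
                lat=float(positions[i, 0]),
                lon=float(positions[i, 1]),
                tree_count=int(tree_counts[i]),
                diameters_mm=[float(d) for d in diameters_mm[i]],
                distance_along_row_m=dist,
            )
        )
    return records


def transect_to_frame(records: Sequence[TransectRecord]) -> pd.DataFrame:
    """Transect records as a DataFrame ready for CSV output."""
    return pd.DataFrame(
        {
            "frame_id": [r.frame_id for r in records],
            "lat": [r.lat for r in records],
            "lon": [r.lon for r in records],
            "count": [r.tree_count for r in records],
            "mean_diameter_mm": [
                round(float(np.mean(r.diameters_mm)), 2) if r.diameters_mm else float("nan")
                for r in records
            ],
            "distance_m": [r.distance_along_row_m for r in records],
        }
    )


def transect_to_geojson(records: Sequence[TransectRecord]) -> dict:
    """Transect records as a GeoJSON FeatureCollection of points."""
    features = []
    for r in records:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
                "properties": {
                    "frame_id": r.frame_id,
                    "tree_count": r.tree_count,
                    "diameters_mm": [round(d, 2) for d in r.diameters_mm],
                    "distance_along_row_m": r.distance_along_row_m,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_transect(records: Sequence[TransectRecord], csv_path, geojson_path=None) -> None:
    transect_to_frame(records).to_csv(csv_path, index=False)
    if geojson_path is not None:
        with open(geojson_path, "w") as fh:
            json.dump(transect_to_geojson(records), fh, indent=1)


def format_gga(
    timestamp: float,
    lat: float,
    lon: float,
    quality: int = 1,
    n_satellites: int = 8,
    hdop: float = 1.0,
    altitude_m: float = 50.0,
) -> str:
    """Render one GGA sentence (with checksum) from decimal-degree inputs.

    ``timestamp`` is UTC seconds since midnight.  Minutes are written
    with six decimals, so a parse round-trip is exact to well below the
    receiver's resolution.
    """
    hh = int(timestamp // 3600) % 24
    mm = int(timestamp // 60) % 60
    ss = timestamp % 60.0
    lat_h = "N" if lat >= 0 else "S"
    lon_h = "E" if lon >= 0 else "W"
    alat, alon = abs(lat), abs(lon)
    lat_txt = f"{int(alat):02d}{(alat - int(alat)) * 60:09.6f}"
    lon_txt = f"{int(alon):03d}{(alon - int(alon)) * 60:09.6f}"
    payload = (
        f"GPGGA,{hh:02d}{mm:02d}{ss:05.2f},{lat_txt},{lat_h},{lon_txt},{lon_h},"
        f"{quality},{n_satellites:02d},{hdop:.1f},{altitude_m:.1f},M,0.0,M,,"
    )
    return f"${payload}*{_nmea_checksum(payload):02X}"


def write_nmea(fixes: Sequence[GeoFix], path) -> None:
    """Write fixes as a GGA log (test-fixture writer)."""
    with open(path, "w") as fh:
        for f in fixes:
            fh.write(format_gga(f.timestamp, f.lat, f.lon, f.quality) + "\n")
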