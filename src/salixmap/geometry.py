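"""Camera geometry for row-crop stem imaging.

The imaging rig looks at a single willow row from a fixed perpendicular
distance, tilted upward so the region of interest (the stem section a few
metres above ground) fills the frame.  Two geometric constructions live
here:

* the *threshold plane* — a per-image-row distance cutoff, tilted with the
  camera pitch, that separates the harvested row from everything behind
  it; and
* the *pixel-to-millimetre* conversion — horizontal field-of-view
  trigonometry that turns a stem's pixel width at a known depth into a
  diameter in millimetres.

Angles are specified in degrees in all public interfaces and converted to
radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "CameraModel",
    "ThresholdPlane",
    "TreeMeasurement",
    "build_threshold_plane",
    "diameter_from_width",
]


@dataclass(frozen=True)
class CameraModel:
    """Optics and mounting geometry of the stereo depth camera.

    Parameters
    ----------
    fov_x, fov_y:
        Horizontal and vertical field of view of the monochrome imager,
        in degrees.  Must lie in (0, 180).
    tilt:
        Camera pitch above the ground plane, degrees.
    depth_scale:
        Metres per raw depth unit (1 mm per unit for the default sensor).
    frame_width, frame_height:
        Frame resolution in pixels.
    row_distance:
        Perpendicular distance from the camera to the tree row, metres.
    bottom_plane_distance:
        Threshold-plane distance fixed at the bottom image row, metres.
        Corresponds to the centre of the row as seen along the bottom ray.
    top_plane_distance:
        Optional override for the plane distance at the top row.  When
        set, the plane is linearly interpolated between bottom and top
        instead of being derived trigonometrically.
    """

    fov_x: float = 87.0
    fov_y: float = 58.0
    tilt: float = 28.5
    depth_scale: float = 0.001
    frame_width: int = 1280
    frame_height: int = 720
    row_distance: float = 1.22
    bottom_plane_distance: float = 1.23
    top_plane_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fov_x < 180.0):
            raise ValueError(f"fov_x must be in (0, 180), got {self.fov_x}")
        if not (0.0 <= self.fov_y < 180.0):
            raise ValueError(f"fov_y must be in [0, 180), got {self.fov_y}")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.bottom_plane_distance <= 0:
            raise ValueError("bottom_plane_distance must be positive")
        if self.top_plane_distance is not None and self.top_plane_distance <= 0:
            raise ValueError("top_plane_distance must be positive when set")

    def mm_per_pixel(self, depth_value: float) -> float:
        """Horizontal millimetres covered by one pixel at a raw depth value."""
        distance_mm = depth_value * self.depth_scale * 1000.0
        half_width_mm = math.tan(math.radians(self.fov_x) / 2.0) * distance_mm
        return half_width_mm / (self.frame_width / 2.0)


@dataclass(frozen=True)
class ThresholdPlane:
    """Per-row depth cutoff in metres; row 0 is the top image row."""

    per_row_threshold: np.ndarray

    def __post_init__(self) -> None:
        thr = np.asarray(self.per_row_threshold, dtype=float)
        object.__setattr__(self, "per_row_threshold", thr)
        if thr.ndim != 1:
            raise ValueError("per_row_threshold must be one-dimensional")
        if np.any(thr <= 0):
            raise ValueError("threshold plane distances must be positive")
        if np.any(np.diff(thr) > 1e-12):
            raise ValueError("threshold plane must be non-increasing top to bottom")

    def __len__(self) -> int:
        return len(self.per_row_threshold)

    def __getitem__(self, row: int) -> float:
        return float(self.per_row_threshold[row])


@dataclass(frozen=True)
class TreeMeasurement:
    """Stem width measurement converted to millimetres.

    ``diameter_mm`` is exactly ``pixel_width * ratio_mm_per_px``.
    """

    pixel_width: float
    depth_value: float
    distance_mm: float
    half_frame_width_mm: float
    ratio_mm_per_px: float
    diameter_mm: float


def build_threshold_plane(camera: CameraModel) -> ThresholdPlane:
    """Construct the tilted per-row depth cutoff separating row from background.

    The bottom-row cutoff is pinned at ``camera.bottom_plane_distance``
    (the hypotenuse from the camera centre to the row centre along the
    bottom ray).  Each row above is assigned the hypotenuse length from
    the camera centre to that row's intersection with the vertical plane
    through the bottom-row point: ray elevation runs linearly from
    ``tilt - fov_y/2`` (bottom row) to ``tilt + fov_y/2`` (top row).

    With rig defaults (58° vertical FOV, 28.5° tilt, 1.23 m bottom) the
    top-row cutoff comes out at ≈2.29 m.  The bottom ray points 0.5°
    below horizontal, which would give a sub-50-µm dip just above the
    bottom row; a running maximum from the bottom up enforces the
    monotone non-increasing profile.

    If ``camera.top_plane_distance`` is set, the plane is instead a
    linear interpolation between the bottom and top distances.
    """
    n_rows = camera.frame_height
    if camera.top_plane_distance is not None:
        thr = np.linspace(camera.top_plane_distance, camera.bottom_plane_distance, n_rows)
        return ThresholdPlane(thr)

    half_fov = math.radians(camera.fov_y) / 2.0
    tilt = math.radians(camera.tilt)
    theta_bottom = tilt - half_fov
    if abs(theta_bottom) >= math.pi / 2:
        raise ValueError("bottom ray at or beyond vertical: invalid geometry")
    # horizontal distance to the vertical plane through the bottom-row point
    horiz = camera.bottom_plane_distance * math.cos(theta_bottom)

    if n_rows == 1:
        return ThresholdPlane(np.array([camera.bottom_plane_distance]))

    # elevation per row; row 0 = top ray
    frac = (n_rows - 1 - np.arange(n_rows)) / (n_rows - 1)
    theta = theta_bottom + frac * 2.0 * half_fov
    if np.any(theta >= math.pi / 2):
        raise ValueError("ray elevation reaches 90°: invalid geometry")
    cos_theta = np.cos(theta)
    if np.any(cos_theta <= 0):
        raise ValueError("non-positive plane distance: invalid geometry")
    thr = horiz / cos_theta
    thr[-1] = camera.bottom_plane_distance  # exact by construction, kill rounding
    # enforce monotone non-increase top -> bottom
    thr = np.maximum.accumulate(thr[::-1])[::-1]
    return ThresholdPlane(thr)


def diameter_from_width(
    pixel_width: float, depth_value: float, camera: CameraModel
) -> TreeMeasurement:
    """Convert a stem's pixel width at a raw depth value into millimetres.

    The chain: raw depth → distance in mm (via the depth scale), →
    half-frame width in mm at that distance (horizontal FOV tangent), →
    mm-per-pixel ratio (half width over half resolution), → diameter =
    pixel width × ratio.  Linear in both pixel width and depth; zero
    inputs yield zero outputs.
    """
    if pixel_width < 0:
        raise ValueError("pixel_width must be non-negative")
    if depth_value < 0:
        raise ValueError("depth_value must be non-negative")
    distance_mm = depth_value * camera.depth_scale * 1000.0
    half_frame_width_mm = math.tan(math.radians(camera.fov_x) / 2.0) * distance_mm
    ratio = half_frame_width_mm / (camera.frame_width / 2.0)
    return TreeMeasurement(
        pixel_width=float(pixel_width),
        depth_value=float(depth_value),
        distance_mm=distance_mm,
        half_frame_width_mm=half_frame_width_mm,
        ratio_mm_per_px=ratio,
        diameter_mm=float(pixel_width) * ratio,
    )
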