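"""Pixel-space annotation to physical measurement conversion.

Emulates the manual measurement workflow on en-face optic-nerve-head scans:
a scale is set from a known physical distance (the 6 mm scan width), straight
lines give vessel calibers, and hand-drawn polygons give cup and disc areas.

Coordinate convention: image frame, origin at the top-left, x rightward,
y downward.  "Vertical" is the image y axis; no rotation correction is
applied.  Vertices may be sub-pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import CalibrationError, InvalidROIError

__all__ = [
    "ScaleCalibration",
    "PointPx",
    "PolygonPx",
    "set_scale",
    "line_length_mm",
    "polygon_area_mm2",
    "vertical_extent_mm",
]


@dataclass(frozen=True)
class ScaleCalibration:
    """Linear pixel-to-millimeter scale from one known distance."""

    known_distance_mm: float
    known_distance_px: float

    def __post_init__(self) -> None:
        for name in ("known_distance_mm", "known_distance_px"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise CalibrationError(f"{name} must be positive, got {v!r}")

    @property
    def mm_per_px(self) -> float:
        return self.known_distance_mm / self.known_distance_px


class PointPx(NamedTuple):
    x: float
    y: float


@dataclass(frozen=True)
class PolygonPx:
    """A simple polygon in pixel coordinates, implicitly closed."""

    vertices: tuple[PointPx, ...]

    def __init__(self, vertices: Iterable) -> None:
        verts = tuple(PointPx(float(x), float(y)) for x, y in vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise InvalidROIError(f"polygon needs >= 3 vertices, got {len(verts)}")
        if not all(math.isfinite(c) for p in verts for c in p):
            raise InvalidROIError("polygon vertices must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def validate_simple(self) -> None:
        """Reject self-intersecting or zero-area polygons."""
        shp = _ShapelyPolygon(self.vertices)
        if not shp.is_valid or shp.area <= 0.0:
            raise InvalidROIError("polygon is self-intersecting or degenerate")


def set_scale(known_distance_mm: float, known_distance_px: float) -> ScaleCalibration:
    """Build the pixel-to-mm calibration from one known physical distance.

    The study sets 6 mm — the physical width of the optic-nerve-head scan —
    against the image width in pixels.
    """
    return ScaleCalibration(float(known_distance_mm), float(known_distance_px))


def line_length_mm(p1: PointPx, p2: PointPx, cal: ScaleCalibration) -> float:
    """Euclidean length of a straight annotation line, in mm."""
    p1, p2 = PointPx(*p1), PointPx(*p2)
    return math.hypot(p2.x - p1.x, p2.y - p1.y) * cal.mm_per_px


def polygon_area_mm2(poly: PolygonPx, cal: ScaleCalibration) -> float:
    """Area of a region-of-interest polygon, in mm².

    Shoelace formula on the vertices; orientation-independent.  The polygon
    must be simple — self-intersections are rejected, never silently folded
    into a signed-area artifact.
    """
    poly.validate_simple()
    v = poly.as_array()
    x, y = v[:, 0], v[:, 1]
    area_px2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_px2) * cal.mm_per_px**2


def vertical_extent_mm(poly: PolygonPx, cal: ScaleCalibration) -> float:
    """Vertical (image y-axis) extent of a polygon's vertices, in mm.

    Supplies the vertical cup and disc diameters for the cup/disc ratio.
    Not rotation-invariant by construction.
    """
    ys = poly.as_array()[:, 1]
    extent_px = float(ys.max() - ys.min())
    if extent_px <= 0.0:
        raise InvalidROIError("polygon has zero vertical extent")
    return extent_px * cal.mm_per_px
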