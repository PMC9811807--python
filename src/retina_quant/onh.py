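"""Optic-nerve-head morphometry assembled from calibrated annotations.

Per eye: disc area and cup area (mm², from hand-drawn ROI polygons through the
scale-calibrated shoelace path), the vertical cup/disc ratio (ratio of the ROI
vertical extents) and the neuroretinal rim height (μm).  Rim height is not
computed here — it is a pass-through value from the OCT device software, the
one ONH quantity the study trusted that software for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .calibration import PolygonPx, ScaleCalibration, polygon_area_mm2, vertical_extent_mm
from .errors import AnatomicalConsistencyError, InvalidMeasurementError

__all__ = ["ONHMeasurement", "onh_from_annotations"]

#: Tolerance for cup<=disc comparisons on independently-annotated polygons.
_REL_TOL = 1e-9


@dataclass(frozen=True)
class ONHMeasurement:
    """Optic-nerve-head parameter set for one eye.

    Invariants are enforced, never clamped: cup_area <= disc_area and the
    vertical cup/disc ratio lies in [0, 1].
    """

    disc_area_mm2: float
    cup_area_mm2: float
    vertical_cdr: float
    rim_height_um: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.disc_area_mm2) and self.disc_area_mm2 > 0):
            raise InvalidMeasurementError(f"disc area must be > 0, got {self.disc_area_mm2!r}")
        if not (math.isfinite(self.cup_area_mm2) and self.cup_area_mm2 >= 0):
            raise InvalidMeasurementError(f"cup area must be >= 0, got {self.cup_area_mm2!r}")
        if not (math.isfinite(self.rim_height_um) and self.rim_height_um > 0):
            raise InvalidMeasurementError(f"rim height must be > 0, got {self.rim_height_um!r}")
        if self.cup_area_mm2 > self.disc_area_mm2 * (1 + _REL_TOL):
            raise AnatomicalConsistencyError(
                f"cup area {self.cup_area_mm2} mm² exceeds disc area {self.disc_area_mm2} mm²"
            )
        if not (0.0 <= self.vertical_cdr <= 1.0 + _REL_TOL):
            raise AnatomicalConsistencyError(
                f"vertical cup/disc ratio {self.vertical_cdr!r} outside [0, 1]"
            )


def onh_from_annotations(
    disc: PolygonPx,
    cup: PolygonPx,
    cal: ScaleCalibration,
    rim_height_um: float,
) -> ONHMeasurement:
    """Measure one eye's ONH parameters from disc and cup ROI polygons.

    Areas come from the calibrated shoelace path; the vertical cup/disc ratio
    is the ratio of the two polygons' vertical extents.  The cup must fit the
    disc in area and vertical extent (full polygon containment is not
    required — hand-drawn ROIs guarantee nothing stronger).
    """
    disc_area = polygon_area_mm2(disc, cal)
    cup_area = polygon_area_mm2(cup, cal)
    cdr = vertical_extent_mm(cup, cal) / vertical_extent_mm(disc, cal)
    return ONHMeasurement(
        disc_area_mm2=disc_area,
        cup_area_mm2=cup_area,
        vertical_cdr=cdr,
        rim_height_um=float(rim_height_um),
    )
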