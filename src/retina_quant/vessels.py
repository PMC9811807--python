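"""Summarization of retinal branch-vessel diameters into CRAE, CRVE and AVR.

The central retinal artery equivalent (CRAE) and central retinal vein
equivalent (CRVE) condense the calibers of the largest branch arterioles and
venules crossing a peripapillary measurement circle into a single trunk-vessel
caliber per type.  The revised (Knudtson) branching model combines a pair of
branch widths ``w1, w2`` into the parent trunk width

    w_trunk = k * sqrt(w1**2 + w2**2)

with ``k = 0.88`` for arterioles and ``k = 0.95`` for venules.  With more than
two branches the formula is applied iteratively: widths are sorted, the widest
is paired with the narrowest, the second-widest with the second-narrowest and
so on, each pair collapsing into one trunk width; an odd median width carries
into the next round unchanged.  The procedure repeats until one value — the
equivalent — remains.  Because the pair formula is a scaled Euclidean norm,
the result for four branches has the closed form ``k**2 * sqrt(sum(w**2))``
and is independent of the pairing order.

AVR (artery-to-vein ratio) is CRAE / CRVE, a dimensionless index of relative
arteriolar narrowing.

All widths are millimeters end to end; display rounding is left to callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    IncompleteEyeError,
    InsufficientVesselsError,
    InvalidMeasurementError,
)

__all__ = [
    "ARTERIOLE_K",
    "VENULE_K",
    "VesselType",
    "Quadrant",
    "BranchDiameter",
    "BranchDiameterSet",
    "VesselSummary",
    "knudtson_pair",
    "summarize_equivalent",
    "vessel_summary",
]

#: Branching coefficients of the revised trunk formula.
ARTERIOLE_K = 0.88
VENULE_K = 0.95

#: Sanity ceiling for a single retinal branch width on a 6 mm scan (mm).
MAX_BRANCH_WIDTH_MM = 1.0


class VesselType(str, Enum):
    ARTERY = "artery"
    VEIN = "vein"

    @property
    def k(self) -> float:
        return ARTERIOLE_K if self is VesselType.ARTERY else VENULE_K


class Quadrant(str, Enum):
    """Peripapillary quadrant in which a branch crosses the measurement circle."""

    SUPERIOR_NASAL = "superior_nasal"
    INFERIOR_NASAL = "inferior_nasal"
    SUPERIOR_TEMPORAL = "superior_temporal"
    INFERIOR_TEMPORAL = "inferior_temporal"


#: Short codes used in the branch CSV dialect.
QUADRANT_CODES = {
    "SN": Quadrant.SUPERIOR_NASAL,
    "IN": Quadrant.INFERIOR_NASAL,
    "ST": Quadrant.SUPERIOR_TEMPORAL,
    "IT": Quadrant.INFERIOR_TEMPORAL,
}
VESSEL_CODES = {"A": VesselType.ARTERY, "V": VesselType.VEIN}


def _check_width(width_mm: float) -> float:
    width_mm = float(width_mm)
    if not math.isfinite(width_mm) or width_mm <= 0.0:
        raise InvalidMeasurementError(f"branch width must be positive, got {width_mm!r}")
    if width_mm >= MAX_BRANCH_WIDTH_MM:
        raise InvalidMeasurementError(
            f"branch width {width_mm} mm exceeds the {MAX_BRANCH_WIDTH_MM} mm sanity bound"
        )
    return width_mm


@dataclass(frozen=True)
class BranchDiameter:
    """One measured branch-vessel width."""

    width_mm: float
    vessel_type: VesselType
    quadrant: Quadrant

    def __post_init__(self) -> None:
        object.__setattr__(self, "width_mm", _check_width(self.width_mm))
        object.__setattr__(self, "vessel_type", VesselType(self.vessel_type))
        object.__setattr__(self, "quadrant", Quadrant(self.quadrant))


@dataclass
class BranchDiameterSet:
    """All measured branch widths of one eye.

    The study protocol measures the largest artery and the largest vein
    crossing the circle in each of the four quadrants, i.e. exactly four
    widths per vessel type; the general API accepts 1-8 per type.
    """

    eye_id: str
    branches: list[BranchDiameter] = field(default_factory=list)

    def widths(self, vessel_type: VesselType) -> list[float]:
        vessel_type = VesselType(vessel_type)
        return [b.width_mm for b in self.branches if b.vessel_type is vessel_type]

    @property
    def artery_widths(self) -> list[float]:
        return self.widths(VesselType.ARTERY)

    @property
    def vein_widths(self) -> list[float]:
        return self.widths(VesselType.VEIN)


@dataclass(frozen=True)
class VesselSummary:
    """CRAE, CRVE and their ratio for one eye."""

    crae_mm: float
    crve_mm: float
    avr: float

    def __post_init__(self) -> None:
        for name in ("crae_mm", "crve_mm", "avr"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidMeasurementError(f"{name} must be finite and > 0, got {v!r}")
        if not math.isclose(self.avr, self.crae_mm / self.crve_mm, rel_tol=1e-9):
            raise InvalidMeasurementError("avr must equal crae_mm / crve_mm")


def knudtson_pair(w1: float, w2: float, vessel_type: VesselType) -> float:
    """Combine two branch widths (mm) into the parent-trunk width (mm).

    Symmetric in ``(w1, w2)``; uses k = 0.88 for arteries, 0.95 for veins.
    """
    w1 = _check_width(w1)
    w2 = _check_width(w2)
    k = VesselType(vessel_type).k
    return k * math.hypot(w1, w2)


def summarize_equivalent(widths: list[float], vessel_type: VesselType) -> float:
    """Iteratively reduce branch widths (mm) to the central vessel equivalent (mm).

    Sort descending, pair widest with narrowest (2nd-widest with
    2nd-narrowest, ...), collapse each pair with :func:`knudtson_pair`; an odd
    median carries unchanged; repeat until one width remains.  A single width
    is returned as-is.  Full precision is carried throughout — rounding is a
    display concern only.
    """
    vessel_type = VesselType(vessel_type)
    if len(widths) == 0:
        raise InsufficientVesselsError("at least one branch width is required")
    vals = sorted((_check_width(w) for w in widths), reverse=True)
    while len(vals) > 1:
        nxt = []
        i, j = 0, len(vals) - 1
        while i < j:
            nxt.append(knudtson_pair(vals[i], vals[j], vessel_type))
            i += 1
            j -= 1
        if i == j:  # odd count: median carries into the next round
            nxt.append(vals[i])
        vals = sorted(nxt, reverse=True)
    return vals[0]


def vessel_summary(branch_set: BranchDiameterSet, strict_four: bool = False) -> VesselSummary:
    """Summarize one eye's branch widths into CRAE, CRVE and AVR.

    Parameters
    ----------
    branch_set
        The eye's measured branch widths.
    strict_four
        Require exactly four widths per vessel type (one per quadrant, the
        study protocol).  The default accepts any count >= 1 per type.

    Raises
    ------
    IncompleteEyeError
        If artery or vein widths are missing (such eyes are excluded from the
        vessel analysis block), or ``strict_four`` is violated.
    """
    arteries = branch_set.artery_widths
    veins = branch_set.vein_widths
    if not arteries or not veins:
        missing = "artery" if not arteries else "vein"
        raise IncompleteEyeError(f"eye {branch_set.eye_id!r}: no {missing} widths")
    if strict_four and (len(arteries) != 4 or len(veins) != 4):
        raise IncompleteEyeError(
            f"eye {branch_set.eye_id!r}: strict mode needs 4 widths per type, "
            f"got {len(arteries)} arteries / {len(veins)} veins"
        )
    crae = summarize_equivalent(arteries, VesselType.ARTERY)
    crve = summarize_equivalent(veins, VesselType.VEIN)
    return VesselSummary(crae_mm=crae, crve_mm=crve, avr=crae / crve)
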