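"""File dialects, report writing and provenance.

CSV dialects use explicit headers and unit columns; nested ONH annotations
travel as JSON.  Row-level validation failures are collected into a rejects
report instead of aborting the run, mirroring the per-block exclusions of a
real measurement workflow (eyes dropped where vessels could not be
distinguished or ROIs could not be drawn).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import PolygonPx, set_scale
from .errors import (
    FormatError,
    IncompleteEyeError,
    InvalidMeasurementError,
    InvalidROIError,
    OutputError,
    ValidationError,
)
from .onh import onh_from_annotations
from .stats import COHORT_COLUMNS, ReportBundle
from .vessels import (
    QUADRANT_CODES,
    VESSEL_CODES,
    BranchDiameter,
    BranchDiameterSet,
    vessel_summary,
)

__all__ = [
    "Reject",
    "read_branches_csv",
    "write_branches_csv",
    "summarize_branches",
    "read_annotations_json",
    "write_annotations_json",
    "measure_annotations",
    "read_cohort_csv",
    "write_cohort_csv",
    "merge_cohort",
    "write_report",
    "sha256_file",
]

log = logging.getLogger("retina_quant")

BRANCH_COLUMNS = ["eye_id", "vessel_type", "quadrant", "width", "unit"]


@dataclass
class Reject:
    """A row or eye excluded at validation, with the reason."""

    eye_id: str
    context: str
    reason: str


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# Branch-width CSV

def read_branches_csv(
    path: str | Path, unit: Optional[str] = None
) -> tuple[list[BranchDiameterSet], list[Reject]]:
    """Read the per-branch CSV (eye_id, vessel_type{A,V}, quadrant{SN,IN,ST,IT},
    width, unit{mm,um}).

    ``unit`` supplies the unit when the file lacks a unit column; μm widths
    are converted to mm on ingest.  Invalid rows go to the rejects list.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read branch CSV {path}: {exc}") from exc
    required = {"eye_id", "vessel_type", "quadrant", "width"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"branch CSV {path} missing columns {sorted(required - set(df.columns))}"
        )
    if "unit" not in df.columns:
        if unit is None:
            raise FormatError(f"branch CSV {path} has no unit column and no --unit flag given")
        df["unit"] = unit

    sets: dict[str, BranchDiameterSet] = {}
    rejects: list[Reject] = []
    for i, row in df.iterrows():
        eye = str(row["eye_id"])
        try:
            vt = VESSEL_CODES.get(str(row["vessel_type"]).strip().upper())
            qd = QUADRANT_CODES.get(str(row["quadrant"]).strip().upper())
            if vt is None:
                raise InvalidMeasurementError(f"unknown vessel_type {row['vessel_type']!r}")
            if qd is None:
                raise InvalidMeasurementError(f"unknown quadrant {row['quadrant']!r}")
            u = str(row["unit"]).strip().lower()
            if u not in ("mm", "um"):
                raise InvalidMeasurementError(f"unknown unit {u!r}")
            width = float(row["width"])
            if u == "um":
                width /= 1000.0
            branch = BranchDiameter(width, vt, qd)
        except (ValidationError, ValueError) as exc:
            rejects.append(Reject(eye_id=eye, context=f"row {i}", reason=str(exc)))
            continue
        sets.setdefault(eye, BranchDiameterSet(eye_id=eye)).branches.append(branch)
    return list(sets.values()), rejects


def write_branches_csv(sets: list[BranchDiameterSet], path: str | Path) -> None:
    rows = [
        {
            "eye_id": s.eye_id,
            "vessel_type": "A" if b.vessel_type.value == "artery" else "V",
            "quadrant": {v: k for k, v in QUADRANT_CODES.items()}[b.quadrant],
            "width": repr(b.width_mm),
            "unit": "mm",
        }
        for s in sets
        for b in s.branches
    ]
    pd.DataFrame(rows, columns=BRANCH_COLUMNS).to_csv(path, index=False)


def summarize_branches(
    sets: list[BranchDiameterSet], strict_four: bool = False
) -> tuple[pd.DataFrame, list[Reject]]:
    """Summarize each eye into CRAE/CRVE/AVR; incomplete eyes become rejects."""
    rows = []
    rejects: list[Reject] = []
    for s in sets:
        n_a, n_v = len(s.artery_widths), len(s.vein_widths)
        if not strict_four and (n_a != 4 or n_v != 4):
            log.warning("eye %s: %d arteries / %d veins (protocol expects 4+4)",
                        s.eye_id, n_a, n_v)
        try:
            vs = vessel_summary(s, strict_four=strict_four)
        except IncompleteEyeError as exc:
            rejects.append(Reject(eye_id=s.eye_id, context="vessel summary", reason=str(exc)))
            continue
        rows.append({"eye_id": s.eye_id, "crae_mm": vs.crae_mm, "crve_mm": vs.crve_mm,
                     "avr": vs.avr, "n_arteries": n_a, "n_veins": n_v})
    cols = ["eye_id", "crae_mm", "crve_mm", "avr", "n_arteries", "n_veins"]
    return pd.DataFrame(rows, columns=cols), rejects


# --------------------------------------------------------------------------
# Annotation JSON and calibrated measurement

def read_annotations_json(path: str | Path) -> list[dict]:
    try:
        data = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read annotations {path}: {exc}") from exc
    if isinstance(data, dict):
        data = data.get("annotations", [data])
    if not isinstance(data, list):
        raise FormatError(f"annotations {path}: expected a list of eye annotations")
    return data


def write_annotations_json(annotations: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotations, indent=1) + "\n")


def measure_annotations(
    annotations: list[dict], rim_heights: Optional[dict[str, float]] = None
) -> tuple[pd.DataFrame, list[Reject]]:
    """Measure disc/cup ROIs of each annotated eye through the calibrated path.

    Each annotation carries its own image width and physical scan width
    (default 6 mm); eyes with missing or invalid ROIs become rejects.
    ``rim_heights`` optionally maps eye_id to the device-reported
    neuroretinal rim height (μm); without it rim height is left missing.
    """
    rows = []
    rejects: list[Reject] = []
    for ann in annotations:
        eye = str(ann.get("eye_id", "?"))
        try:
            width_px = float(ann["image_width_px"])
            scan_mm = float(ann.get("scan_width_mm", 6.0))
            cal = set_scale(scan_mm, width_px)
            rois = {r["label"]: PolygonPx(r["vertices"]) for r in ann.get("rois", [])}
            if "disc" not in rois or "cup" not in rois:
                raise InvalidROIError("annotation must contain both disc and cup ROIs")
            rim = (rim_heights or {}).get(eye, np.nan)
            if np.isnan(rim):
                # measure geometry only; rim height joined later if provided
                from .calibration import polygon_area_mm2, vertical_extent_mm
                disc_area = polygon_area_mm2(rois["disc"], cal)
                cup_area = polygon_area_mm2(rois["cup"], cal)
                cdr = vertical_extent_mm(rois["cup"], cal) / vertical_extent_mm(rois["disc"], cal)
                if cup_area > disc_area or not (0 <= cdr <= 1):
                    raise InvalidROIError(
                        f"anatomically inconsistent ROIs (cup {cup_area:.3f} / disc "
                        f"{disc_area:.3f} mm², CDR {cdr:.3f})")
                m = {"disc_area_mm2": disc_area, "cup_area_mm2": cup_area,
                     "vertical_cdr": cdr, "rim_height_um": np.nan}
            else:
                onh = onh_from_annotations(rois["disc"], rois["cup"], cal, rim)
                m = {"disc_area_mm2": onh.disc_area_mm2, "cup_area_mm2": onh.cup_area_mm2,
                     "vertical_cdr": onh.vertical_cdr, "rim_height_um": onh.rim_height_um}
        except (ValidationError, KeyError, TypeError, ValueError) as exc:
            rejects.append(Reject(eye_id=eye, context="annotation", reason=str(exc)))
            continue
        rows.append({"eye_id": eye, **m})
    cols = ["eye_id", "disc_area_mm2", "cup_area_mm2", "vertical_cdr", "rim_height_um"]
    return pd.DataFrame(rows, columns=cols), rejects


# --------------------------------------------------------------------------
# Cohort CSV and merging

def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read cohort CSV {path}: {exc}") from exc
    required = {"eye_id", "group", "hgb_g_per_L"}
    if not required.issubset(df.columns):
        raise FormatError(f"cohort CSV {path} missing {sorted(required - set(df.columns))}")
    if df["eye_id"].duplicated().any():
        dupes = df.loc[df["eye_id"].duplicated(), "eye_id"].tolist()
        raise FormatError(f"duplicate eye_ids {dupes}: one record (right eye) per subject")
    return df


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")


def merge_cohort(
    cohort: pd.DataFrame,
    vessels: Optional[pd.DataFrame] = None,
    measures: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Left-join vessel summaries and ONH measures onto the cohort table."""
    out = cohort.copy()
    for extra, cols in ((vessels, ["crae_mm", "crve_mm", "avr"]),
                        (measures, ["disc_area_mm2", "cup_area_mm2", "vertical_cdr"])):
        if extra is None:
            continue
        keep = ["eye_id"] + [c for c in cols if c in extra.columns]
        out = out.drop(columns=[c for c in cols if c in out.columns], errors="ignore")
        out = out.merge(extra[keep], on="eye_id", how="left")
    for col in COHORT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out[COHORT_COLUMNS + [c for c in out.columns if c not in COHORT_COLUMNS]]


# --------------------------------------------------------------------------
# Report writing

def _pkg_version() -> str:
    try:
        return version("retina-quant")
    except PackageNotFoundError:
        return "unknown"


def write_rejects(rejects: list[Reject], path: str | Path) -> None:
    rows = [{"eye_id": r.eye_id, "context": r.context, "reason": r.reason} for r in rejects]
    pd.DataFrame(rows, columns=["eye_id", "context", "reason"]).to_csv(path, index=False)


def write_report(bundle: ReportBundle, out_dir: str | Path) -> dict:
    """Write the report bundle to ``out_dir``; return a content-hash manifest.

    Deterministic file names; rerunning on identical inputs yields identical
    hashes (the SVG uses a fixed hash salt and no timestamp metadata).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OutputError(f"cannot write to {out}: {exc}") from exc

    if bundle.demographics.empty and bundle.oct_comparisons.empty:
        log.warning("empty report bundle: writing empty manifest")
        manifest: dict = {"version": _pkg_version(), "artifacts": {}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        return manifest

    bundle.demographics.to_csv(out / "table1_demographics.csv", index=False)
    bundle.oct_comparisons.to_csv(out / "table2_oct_comparisons.csv", index=False)
    bundle.correlations.to_csv(out / "table3_hgb_correlations.csv", index=False)

    md = ["# Cohort analysis report", "", "## Demographics", "",
          bundle.demographics.to_markdown(index=False), "",
          "## OCT parameter comparisons", "",
          bundle.oct_comparisons.to_markdown(index=False), "",
          "## HGB correlations (HAPC group)", "",
          bundle.correlations.to_markdown(index=False), ""]
    if bundle.notes:
        md += ["## Notes", ""] + [f"- {n}" for n in bundle.notes] + [""]
    md += ["Significance marked * at p < 0.05 (raw p-values, no multiplicity adjustment).", ""]
    (out / "report.md").write_text("\n".join(md))

    if bundle.figure is not None:
        import matplotlib
        matplotlib.rcParams["svg.hashsalt"] = "retina-quant"
        bundle.figure.savefig(out / "hgb_crve_scatter.svg", metadata={"Date": None})

    artifacts = {}
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            artifacts[p.name] = sha256_file(p)
    manifest = {"version": _pkg_version(), "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
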