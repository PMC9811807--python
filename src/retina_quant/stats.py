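"""Two-cohort statistical analysis: descriptives, group tests, HGB correlations.

Mirrors the study's analysis plan: independent-samples t-tests for continuous
variables (pooled-variance by default, Welch optional), Pearson chi-square for
categorical ones (no continuity correction by default), and Pearson
correlations between hemoglobin and every ocular parameter within the
polycythemia group.  Missing values are dropped per analysis block, so block
sample sizes differ just as they do in practice.  Raw p-values only — no
multiple-testing adjustment is applied — with significance flagged at 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedCorrelationError, ValidationError
from .onh import ONHMeasurement
from .vessels import VesselSummary

__all__ = [
    "Group",
    "EyeRecord",
    "GroupComparison",
    "CorrelationResult",
    "ReportBundle",
    "records_to_frame",
    "compare_groups",
    "compare_categorical",
    "correlate_hgb",
    "build_report",
]

ALPHA = 0.05

RNFL_KEYS = ("mean", "superior", "inferior", "nasal", "temporal")


class Group(str, Enum):
    HAPC = "HAPC"
    HEALTHY_HA = "healthy_HA"


@dataclass
class EyeRecord:
    """One subject-eye (right eye): covariates plus retinal measurements."""

    eye_id: str
    group: Group
    age_years: float
    sex: str  # "M" | "F"
    bmi: float
    hgb_g_per_L: float
    iop_mmHg: float
    rnfl_um: dict[str, float] = field(default_factory=dict)
    onh: Optional[ONHMeasurement] = None
    vessels: Optional[VesselSummary] = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not 50 < self.hgb_g_per_L < 300:
            raise ValidationError(f"HGB {self.hgb_g_per_L} g/L outside (50, 300) sanity range")
        for k, v in self.rnfl_um.items():
            if not 30 < v < 300:
                raise ValidationError(f"RNFL {k} {v} μm outside (30, 300) sanity range")


#: Flat column layout used across CSV files and the stats functions.
COHORT_COLUMNS = [
    "eye_id", "group", "age_years", "sex", "bmi", "iop_mmHg", "hgb_g_per_L",
    "rnfl_mean_um", "rnfl_superior_um", "rnfl_inferior_um", "rnfl_nasal_um",
    "rnfl_temporal_um", "rim_height_um", "cup_area_mm2", "disc_area_mm2",
    "vertical_cdr", "crae_mm", "crve_mm", "avr",
]


def records_to_frame(records: Sequence[EyeRecord]) -> pd.DataFrame:
    """Flatten EyeRecords into the canonical per-eye DataFrame."""
    rows = []
    seen: set[str] = set()
    for r in records:
        if r.eye_id in seen:
            raise ValidationError(f"duplicate eye_id {r.eye_id!r}: one record per subject")
        seen.add(r.eye_id)
        row: dict = {
            "eye_id": r.eye_id, "group": r.group.value, "age_years": r.age_years,
            "sex": r.sex, "bmi": r.bmi, "iop_mmHg": r.iop_mmHg,
            "hgb_g_per_L": r.hgb_g_per_L,
        }
        for k in RNFL_KEYS:
            row[f"rnfl_{k}_um"] = r.rnfl_um.get(k, np.nan)
        if r.onh is not None:
            row.update(
                rim_height_um=r.onh.rim_height_um, cup_area_mm2=r.onh.cup_area_mm2,
                disc_area_mm2=r.onh.disc_area_mm2, vertical_cdr=r.onh.vertical_cdr,
            )
        if r.vessels is not None:
            row.update(crae_mm=r.vessels.crae_mm, crve_mm=r.vessels.crve_mm, avr=r.vessels.avr)
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


Records = Union[pd.DataFrame, Sequence[EyeRecord]]


def _as_frame(records: Records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    r: float
    p_value: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.r * self.r

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _group_values(frame: pd.DataFrame, variable: str) -> tuple[np.ndarray, np.ndarray]:
    if variable not in frame.columns:
        raise InsufficientDataError(f"variable {variable!r} not present")
    a = frame.loc[frame["group"] == Group.HAPC.value, variable].dropna().to_numpy(float)
    b = frame.loc[frame["group"] == Group.HEALTHY_HA.value, variable].dropna().to_numpy(float)
    return a, b


def compare_groups(records: Records, variable: str, variant: str = "student") -> GroupComparison:
    """Two-sided independent-samples t-test, HAPC (a) versus healthy HA (b).

    ``variant`` selects the pooled-variance Student test (default, the
    primary line reported by mainstream statistics software) or the Welch
    unequal-variance test.  Missing values are dropped for this variable only.
    """
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    a, b = _group_values(_as_frame(records), variable)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"{variable!r}: need >= 2 values per group, got {len(a)}/{len(b)}"
        )
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        t, p = 0.0, 1.0  # identical constant groups: no evidence by convention
    else:
        t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(
        variable=variable,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        statistic=float(t), p_value=float(p),
    )


def compare_categorical(records: Records, variable: str, correction: bool = False) -> GroupComparison:
    """Pearson chi-square test of ``variable`` x group (Yates correction optional)."""
    frame = _as_frame(records)
    if variable not in frame.columns:
        raise InsufficientDataError(f"variable {variable!r} not present")
    sub = frame[[variable, "group"]].dropna()
    table = pd.crosstab(sub[variable], sub["group"])
    if table.shape[0] < 2 or table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
        raise InsufficientDataError(f"{variable!r}: degenerate contingency table {table.shape}")
    res = sps.chi2_contingency(table.to_numpy(), correction=correction)
    n_a = int(table.get(Group.HAPC.value, pd.Series(0)).sum())
    n_b = int(table.get(Group.HEALTHY_HA.value, pd.Series(0)).sum())
    return GroupComparison(
        variable=variable,
        mean_a=np.nan, sd_a=np.nan, n_a=n_a,
        mean_b=np.nan, sd_b=np.nan, n_b=n_b,
        statistic=float(res.statistic), p_value=float(res.pvalue),
    )


def correlate_hgb(records: Records, variable: str) -> CorrelationResult:
    """Pearson correlation between HGB and ``variable`` in the HAPC group."""
    frame = _as_frame(records)
    hapc = frame[frame["group"] == Group.HAPC.value]
    if variable not in frame.columns:
        raise InsufficientDataError(f"variable {variable!r} not present")
    pairs = hapc[["hgb_g_per_L", variable]].dropna()
    if len(pairs) < 3:
        raise InsufficientDataError(f"{variable!r}: need >= 3 pairs, got {len(pairs)}")
    x = pairs["hgb_g_per_L"].to_numpy(float)
    y = pairs[variable].to_numpy(float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(f"{variable!r}: zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(variable=variable, r=float(r), p_value=float(p), n=len(pairs))


# --------------------------------------------------------------------------
# Report assembly

#: Table-2-style analysis blocks: (block label, [(column, display label), ...])
OCT_BLOCKS: list[tuple[str, list[tuple[str, str]]]] = [
    ("RNFL thickness", [
        ("rnfl_mean_um", "Mean (μm)"),
        ("rnfl_superior_um", "Superior (μm)"),
        ("rnfl_inferior_um", "Inferior (μm)"),
        ("rnfl_nasal_um", "Nasal (μm)"),
        ("rnfl_temporal_um", "Temporal (μm)"),
    ]),
    ("ONH parameters", [
        ("rim_height_um", "Neuroretinal rim height (μm)"),
        ("cup_area_mm2", "Cup area (mm²)"),
        ("disc_area_mm2", "Disc area (mm²)"),
        ("vertical_cdr", "Vertical cup/disc ratio"),
    ]),
    ("Retinal vessel diameters", [
        ("crve_mm", "CRVE (mm)"),
        ("crae_mm", "CRAE (mm)"),
        ("avr", "AVR"),
    ]),
]

#: Correlation table rows (HGB versus each, within HAPC).
CORRELATION_VARIABLES = [c for _, block in OCT_BLOCKS for c, _ in block if c != "avr"]


@dataclass
class ReportBundle:
    """The assembled analysis: three tables plus the HGB-CRVE scatter."""

    demographics: pd.DataFrame
    oct_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    figure: Optional["object"]  # matplotlib Figure or None if no vessel data
    notes: list[str] = field(default_factory=list)


def _fmt_p(p: float) -> str:
    if not math.isfinite(p):
        return ""
    if p < 0.001:
        return "< 0.001*"
    return f"{p:.3g}" + ("*" if p < ALPHA else "")


def _mean_sd(v: np.ndarray) -> str:
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" if len(v) else ""


def build_report(
    records: Records,
    ttest: str = "student",
    chi2_correction: bool = False,
) -> ReportBundle:
    """Assemble the full two-cohort analysis.

    Produces a demographics table (age, sex, BMI, IOP, HGB), the block-wise
    OCT comparison table (RNFL / ONH / vessel blocks, each with its own Ns),
    the within-HAPC HGB correlation table, and an HGB-versus-CRVE scatter
    with fitted line and R² annotation.  Blocks without enough data degrade
    to an "insufficient data" marker rather than failing the whole report.
    """
    frame = _as_frame(records)
    notes: list[str] = []

    # --- demographics -----------------------------------------------------
    demo_rows = []
    a_all = frame[frame["group"] == Group.HAPC.value]
    b_all = frame[frame["group"] == Group.HEALTHY_HA.value]
    demo_rows.append({"Variable": "Number of subjects", "HAPC": str(len(a_all)),
                      "Healthy HA": str(len(b_all)), "P-value": ""})
    for col, label in [("age_years", "Age (years)"), ("bmi", "BMI"),
                       ("iop_mmHg", "IOP (mmHg)"), ("hgb_g_per_L", "HGB (g/L)")]:
        try:
            c = compare_groups(frame, col, variant=ttest)
            demo_rows.append({"Variable": label,
                              "HAPC": f"{c.mean_a:.2f} ± {c.sd_a:.2f}",
                              "Healthy HA": f"{c.mean_b:.2f} ± {c.sd_b:.2f}",
                              "P-value": _fmt_p(c.p_value)})
        except InsufficientDataError:
            demo_rows.append({"Variable": label, "HAPC": "insufficient data",
                              "Healthy HA": "", "P-value": ""})
    try:
        sex = compare_categorical(frame, "sex", correction=chi2_correction)
        m_a = int((a_all["sex"] == "M").sum()); f_a = int((a_all["sex"] == "F").sum())
        m_b = int((b_all["sex"] == "M").sum()); f_b = int((b_all["sex"] == "F").sum())
        demo_rows.append({"Variable": "Gender (male/female)", "HAPC": f"{m_a}/{f_a}",
                          "Healthy HA": f"{m_b}/{f_b}", "P-value": _fmt_p(sex.p_value)})
    except InsufficientDataError:
        notes.append("sex comparison skipped: degenerate table")
    demographics = pd.DataFrame(demo_rows)

    # --- OCT comparison blocks --------------------------------------------
    oct_rows = []
    for block, cols in OCT_BLOCKS:
        block_cols = [c for c, _ in cols]
        n_a = int(a_all[block_cols].dropna(how="all").shape[0])
        n_b = int(b_all[block_cols].dropna(how="all").shape[0])
        oct_rows.append({"Block": block, "Variable": "Eyes (n)",
                         "HAPC": str(n_a), "Healthy HA": str(n_b), "P-value": ""})
        for col, label in cols:
            try:
                c = compare_groups(frame, col, variant=ttest)
                oct_rows.append({"Block": block, "Variable": label,
                                 "HAPC": f"{c.mean_a:.2f} ± {c.sd_a:.2f}",
                                 "Healthy HA": f"{c.mean_b:.2f} ± {c.sd_b:.2f}",
                                 "P-value": _fmt_p(c.p_value)})
            except InsufficientDataError:
                oct_rows.append({"Block": block, "Variable": label,
                                 "HAPC": "insufficient data", "Healthy HA": "",
                                 "P-value": ""})
                notes.append(f"{block}: {label} insufficient data")
    oct_comparisons = pd.DataFrame(oct_rows)

    # --- HGB correlations (HAPC) ------------------------------------------
    corr_rows = []
    for col in CORRELATION_VARIABLES:
        try:
            c = correlate_hgb(frame, col)
            corr_rows.append({"Variable": col, "r": round(c.r, 3),
                              "P-value": _fmt_p(c.p_value), "n": c.n})
        except (InsufficientDataError, UndefinedCorrelationError):
            corr_rows.append({"Variable": col, "r": np.nan, "P-value": "", "n": 0})
    correlations = pd.DataFrame(corr_rows)

    figure = _scatter_figure(frame, notes)
    return ReportBundle(demographics=demographics, oct_comparisons=oct_comparisons,
                        correlations=correlations, figure=figure, notes=notes)


def _scatter_figure(frame: pd.DataFrame, notes: list[str]):
    """HGB vs CRVE scatter (HAPC) with least-squares line and R² annotation."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    try:
        c = correlate_hgb(frame, "crve_mm")
    except (InsufficientDataError, UndefinedCorrelationError):
        notes.append("HGB-CRVE scatter skipped: insufficient vessel data")
        return None
    hapc = frame[frame["group"] == Group.HAPC.value][["hgb_g_per_L", "crve_mm"]].dropna()
    x = hapc["hgb_g_per_L"].to_numpy(float)
    y = hapc["crve_mm"].to_numpy(float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, color="#31688e", alpha=0.8)
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.array([x.min(), x.max()])
    ax.plot(xs, slope * xs + intercept, color="#b40426", lw=1.5)
    ax.annotate(f"R² = {c.r_squared:.2f}", xy=(0.05, 0.92), xycoords="axes fraction")
    ax.set_xlabel("HGB (g/L)")
    ax.set_ylabel("CRVE (mm)")
    ax.set_title("HGB vs CRVE (HAPC group)")
    fig.tight_layout()
    return fig
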