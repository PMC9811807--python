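"""Synthetic two-cohort generator with the statistical structure of the study.

Emulates a cross-sectional comparison of high-altitude polycythemia (HAPC)
patients against healthy high-altitude residents: per-group truncated-normal
draws for covariates (age, sex, BMI, IOP, HGB), peripapillary RNFL quadrant
thicknesses, optic-nerve-head morphometry and central vessel equivalents,
with per-analysis-block missingness masks reproducing the differing block
sample sizes (RNFL 51/50, ONH 43/42, vessels 47/33 by default) and, in the
HAPC group, a bivariate Gaussian dependence between hemoglobin and CRVE.

Two constructions make the generated data exercise the *whole* measurement
pipeline rather than short-circuiting it:

* vessel targets are decomposed into four branch widths whose Knudtson
  re-summarization reproduces the target exactly (degree-1 homogeneity of
  the trunk formula makes the rescale exact);
* ONH targets are rendered as circle/ellipse ROI polygons whose calibrated
  shoelace area and vertical-extent ratio equal the drawn disc area, cup
  area and vertical cup/disc ratio.

Distribution shapes are an assumption: the study reports means and SDs only.
Truncated normals are moment-matched — the underlying Gaussian parameters
are solved so the *truncated* distribution has the configured mean and SD —
so configured moments are recovered even for variables (such as CRAE) whose
mean/SD combination puts appreciable Gaussian mass outside the physiological
bounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import ConfigError
from .stats import COHORT_COLUMNS, Group
from .vessels import (
    BranchDiameter,
    BranchDiameterSet,
    Quadrant,
    VesselType,
    summarize_equivalent,
)

__all__ = [
    "VariableSpec",
    "GroupScenario",
    "ScenarioConfig",
    "SyntheticCohort",
    "paper_default",
    "generate_cohort",
    "decompose_to_branches",
    "generate_hgb_crve_pairs",
    "circle_polygon_vertices",
]

_REDRAW_CAP = 1000
_POLY_N = 64  # vertices per ROI polygon; divisible by 4 so the vertical
              # extent of a circle/ellipse polygon is exactly twice its
              # vertical semi-axis


# --------------------------------------------------------------------------
# Scenario configuration

@dataclass(frozen=True)
class VariableSpec:
    """Moments and physiological bounds of one generated variable."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ConfigError(f"sd must be > 0, got {self.sd!r}")
        if not (self.lower < self.upper):
            raise ConfigError(f"bounds must satisfy lower < upper, got {self.lower}, {self.upper}")
        # infeasible truncation: mean further than 6 SD outside the bounds
        if self.mean < self.lower - 6 * self.sd or self.mean > self.upper + 6 * self.sd:
            raise ConfigError(
                f"mean {self.mean} is > 6 SD outside bounds [{self.lower}, {self.upper}]"
            )


#: Variables every group scenario must define (cohort column names).
VARIABLE_NAMES = (
    "age_years", "bmi", "iop_mmHg", "hgb_g_per_L",
    "rnfl_mean_um", "rnfl_superior_um", "rnfl_inferior_um",
    "rnfl_nasal_um", "rnfl_temporal_um",
    "rim_height_um", "cup_area_mm2", "disc_area_mm2", "vertical_cdr",
    "crve_mm", "crae_mm",
)


@dataclass(frozen=True)
class GroupScenario:
    name: str
    n_subjects: int
    n_onh: int
    n_vessels: int
    sex_male_prop: float
    variables: dict[str, VariableSpec]

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not (0 <= self.n_onh <= self.n_subjects and 0 <= self.n_vessels <= self.n_subjects):
            raise ConfigError("block Ns must lie in [0, n_subjects]")
        if not (0.0 <= self.sex_male_prop <= 1.0):
            raise ConfigError("sex_male_prop must be in [0, 1]")
        missing = set(VARIABLE_NAMES) - set(self.variables)
        if missing:
            raise ConfigError(f"group {self.name!r} missing variables: {sorted(missing)}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generator parameterization for one two-group scenario."""

    groups: dict[str, GroupScenario]
    hgb_crve_correlation: float = 0.0
    hgb_crve_pair_n: int = 38
    image_width_px: int = 600
    scan_width_mm: float = 6.0
    branch_count: int = 4
    branch_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.groups) != {Group.HAPC.value, Group.HEALTHY_HA.value}:
            raise ConfigError(f"groups must be exactly {{HAPC, healthy_HA}}, got {set(self.groups)}")
        if not (-1.0 < self.hgb_crve_correlation < 1.0):
            raise ConfigError("hgb_crve_correlation must lie in (-1, 1)")
        if self.hgb_crve_pair_n < 3:
            raise ConfigError("hgb_crve_pair_n must be >= 3")
        if self.branch_count < 1:
            raise ConfigError("branch_count must be >= 1")
        if self.branch_log_sd < 0:
            raise ConfigError("branch_log_sd must be >= 0")
        if self.image_width_px <= 0 or self.scan_width_mm <= 0:
            raise ConfigError("image geometry must be positive")

    # --- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        try:
            groups = {
                name: GroupScenario(
                    name=g.get("name", name),
                    n_subjects=int(g["n_subjects"]),
                    n_onh=int(g["n_onh"]),
                    n_vessels=int(g["n_vessels"]),
                    sex_male_prop=float(g["sex_male_prop"]),
                    variables={k: VariableSpec(**v) for k, v in g["variables"].items()},
                )
                for name, g in d["groups"].items()
            }
            kwargs = {k: d[k] for k in (
                "hgb_crve_correlation", "hgb_crve_pair_n", "image_width_px",
                "scan_width_mm", "branch_count", "branch_log_sd", "seed") if k in d}
            return cls(groups=groups, **kwargs)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scenario: {exc}") from exc

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"scenario file is not valid JSON: {exc}") from exc
        return cls.from_dict(d)


def paper_default() -> ScenarioConfig:
    """The packaged default scenario: the study's reported group moments.

    Sample sizes use the per-block analyzed Ns (51/50 subjects with RNFL,
    43/42 with ONH morphometry, 47/33 with vessel measurements); the
    HAPC-group HGB-CRVE correlation is 0.469 with a default effective pair
    count of 38 for correlation-recovery checks.
    """
    def v(mean, sd, lo, hi):
        return VariableSpec(mean, sd, lo, hi)

    rnfl = (30.0, 300.0)
    hapc = GroupScenario(
        name=Group.HAPC.value, n_subjects=51, n_onh=43, n_vessels=47,
        sex_male_prop=40 / 51,
        variables={
            "age_years": v(49.51, 9.06, 18, 65),
            "bmi": v(22.31, 2.45, 12, 45),
            "iop_mmHg": v(12.63, 2.48, 5, 40),
            "hgb_g_per_L": v(219.84, 9.32, 50, 300),
            "rnfl_mean_um": v(102.93, 11.59, *rnfl),
            "rnfl_superior_um": v(130.33, 17.20, *rnfl),
            "rnfl_inferior_um": v(133.06, 22.63, *rnfl),
            "rnfl_nasal_um": v(74.82, 14.40, *rnfl),
            "rnfl_temporal_um": v(73.51, 11.82, *rnfl),
            "rim_height_um": v(494.86, 157.42, 50, 1200),
            "cup_area_mm2": v(0.56, 0.27, 0.01, 6.0),
            "disc_area_mm2": v(2.39, 0.43, 0.5, 6.0),
            "vertical_cdr": v(0.48, 0.15, 0.02, 0.98),
            "crve_mm": v(0.25, 0.03, 0.05, 0.6),
            "crae_mm": v(0.16, 0.12, 0.02, 0.6),
        },
    )
    healthy = GroupScenario(
        name=Group.HEALTHY_HA.value, n_subjects=50, n_onh=42, n_vessels=33,
        sex_male_prop=35 / 50,
        variables={
            "age_years": v(47.04, 10.30, 18, 65),
            "bmi": v(23.56, 2.08, 12, 45),
            "iop_mmHg": v(11.85, 1.83, 5, 40),
            "hgb_g_per_L": v(129.80, 17.52, 50, 300),
            "rnfl_mean_um": v(100.86, 10.10, *rnfl),
            "rnfl_superior_um": v(128.10, 19.12, *rnfl),
            "rnfl_inferior_um": v(132.56, 13.96, *rnfl),
            "rnfl_nasal_um": v(66.06, 13.71, *rnfl),
            "rnfl_temporal_um": v(76.72, 11.17, *rnfl),
            "rim_height_um": v(461.42, 137.36, 50, 1200),
            "cup_area_mm2": v(0.44, 0.23, 0.01, 6.0),
            "disc_area_mm2": v(2.12, 0.38, 0.5, 6.0),
            "vertical_cdr": v(0.42, 0.16, 0.02, 0.98),
            "crve_mm": v(0.20, 0.02, 0.05, 0.6),
            "crae_mm": v(0.12, 0.04, 0.02, 0.6),
        },
    )
    return ScenarioConfig(
        groups={hapc.name: hapc, healthy.name: healthy},
        hgb_crve_correlation=0.469,
        hgb_crve_pair_n=38,
    )


def null_scenario() -> ScenarioConfig:
    """Both groups drawn from the healthy-HA parameters; correlation zero.

    Used for type-I-error calibration of the group tests.
    """
    base = paper_default()
    healthy = base.groups[Group.HEALTHY_HA.value]
    hapc_null = GroupScenario(
        name=Group.HAPC.value, n_subjects=51, n_onh=43, n_vessels=47,
        sex_male_prop=healthy.sex_male_prop, variables=dict(healthy.variables),
    )
    return ScenarioConfig(
        groups={Group.HAPC.value: hapc_null, Group.HEALTHY_HA.value: healthy},
        hgb_crve_correlation=0.0,
        hgb_crve_pair_n=base.hgb_crve_pair_n,
    )


# --------------------------------------------------------------------------
# Moment-matched truncated normal sampling

@lru_cache(maxsize=512)
def _match_truncnorm(mean: float, sd: float, lower: float, upper: float) -> tuple[float, float]:
    """Underlying Gaussian (mu, sigma) whose [lower, upper]-truncation has the
    requested mean and SD.  Raises ConfigError when no such Gaussian exists
    (e.g. an SD larger than the bounds can support)."""

    def resid(x):
        mu, log_sig = x
        sig = math.exp(log_sig)
        a, b = (lower - mu) / sig, (upper - mu) / sig
        tm, tv = sps.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        tm, tv = float(tm), float(tv)
        if not (math.isfinite(tm) and math.isfinite(tv) and tv > 0):
            return [1e6, 1e6]  # push the solver away from degenerate regions
        return [tm - mean, math.sqrt(tv) - sd]

    starts = [(mean, math.log(sd)), (mean - sd, math.log(2 * sd)),
              (mean - 3 * sd, math.log(3 * sd)), (mean + sd, math.log(2 * sd))]
    for x0 in starts:
        with np.errstate(all="ignore"):
            sol = optimize.root(resid, x0, method="hybr")
        if sol.success:
            r = resid(sol.x)
            if abs(r[0]) < 1e-8 * max(1.0, abs(mean)) and abs(r[1]) < 1e-8 * max(1.0, sd):
                return float(sol.x[0]), float(math.exp(sol.x[1]))
    raise ConfigError(
        f"no truncated normal on [{lower}, {upper}] has mean {mean} and sd {sd}"
    )


def _sample_variable(rng: np.random.Generator, spec: VariableSpec, n: int) -> np.ndarray:
    mu, sig = _match_truncnorm(spec.mean, spec.sd, spec.lower, spec.upper)
    a, b = (spec.lower - mu) / sig, (spec.upper - mu) / sig
    return sps.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)


def _sample_hgb_crve(
    rng: np.random.Generator,
    hgb: VariableSpec,
    crve: VariableSpec,
    rho: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (HGB, CRVE) draws: bivariate Gaussian, redrawn on bound
    violation.  The underlying marginals are the moment-matched Gaussians;
    for the default scenario both truncations sit > 5 SD out, so the
    realized correlation equals the configured one to sampling precision."""
    mu_h, sig_h = _match_truncnorm(hgb.mean, hgb.sd, hgb.lower, hgb.upper)
    mu_c, sig_c = _match_truncnorm(crve.mean, crve.sd, crve.lower, crve.upper)
    cov = [[sig_h**2, rho * sig_h * sig_c], [rho * sig_h * sig_c, sig_c**2]]
    out_h = np.empty(n)
    out_c = np.empty(n)
    need = np.ones(n, dtype=bool)
    for _ in range(_REDRAW_CAP):
        k = int(need.sum())
        if k == 0:
            return out_h, out_c
        draw = rng.multivariate_normal([mu_h, mu_c], cov, size=k)
        ok = ((draw[:, 0] >= hgb.lower) & (draw[:, 0] <= hgb.upper)
              & (draw[:, 1] >= crve.lower) & (draw[:, 1] <= crve.upper))
        idx = np.flatnonzero(need)
        accepted = idx[ok]
        out_h[accepted] = draw[ok, 0]
        out_c[accepted] = draw[ok, 1]
        need[accepted] = False
    raise ConfigError("HGB-CRVE sampling exceeded the redraw cap; bounds too tight")


# --------------------------------------------------------------------------
# Branch decomposition and ONH polygon fixtures

_QUADRANTS = (Quadrant.SUPERIOR_NASAL, Quadrant.INFERIOR_NASAL,
              Quadrant.SUPERIOR_TEMPORAL, Quadrant.INFERIOR_TEMPORAL)


def decompose_to_branches(
    target_equivalent: float,
    vessel_type: VesselType,
    count: int = 4,
    rng: Optional[np.random.Generator] = None,
    log_sd: float = 0.3,
) -> list[float]:
    """Split a central-vessel-equivalent target into branch widths.

    Draws ``count`` raw widths from a log-normal spread model, then rescales
    all of them by target/equivalent(raw).  Because the trunk formula is
    degree-1 homogeneous, the rescaled widths re-summarize to the target
    (to 1e-12 relative; callers wanting bit-exact agreement should store the
    re-summarized value).
    """
    if not (target_equivalent > 0):
        raise ConfigError(f"target equivalent must be > 0, got {target_equivalent!r}")
    rng = np.random.default_rng() if rng is None else rng
    # base width 0.1 mm keeps raw draws inside the branch sanity bound;
    # the homogeneity rescale cancels the base exactly
    raw = 0.1 * np.exp(rng.normal(0.0, log_sd, size=count))
    eq = summarize_equivalent(list(raw), vessel_type)
    return [float(w) for w in raw * (target_equivalent / eq)]


def _polygon_shape_factor(n: int = _POLY_N) -> float:
    """Area of a regular n-gon inscribed in the unit circle: (n/2)·sin(2π/n)."""
    return 0.5 * n * math.sin(2 * math.pi / n)


def circle_polygon_vertices(
    cx: float, cy: float, semi_x: float, semi_y: float, n: int = _POLY_N
) -> list[list[float]]:
    """Vertices of an angle-sampled ellipse polygon (pixel units).

    With ``n`` divisible by 4 the polygon's vertical extent is exactly
    ``2*semi_y`` and its shoelace area is ``shape_factor(n)*semi_x*semi_y``.
    """
    theta = 2 * math.pi * np.arange(n) / n
    xs = cx + semi_x * np.cos(theta)
    ys = cy + semi_y * np.sin(theta)
    return [[float(x), float(y)] for x, y in zip(xs, ys)]


def _onh_annotation(
    eye_id: str,
    disc_area_mm2: float,
    cup_area_mm2: float,
    vertical_cdr: float,
    image_width_px: int,
    scan_width_mm: float,
) -> dict:
    """Disc/cup ROI polygons whose calibrated measurements hit the targets.

    The disc is a circle polygon with radius chosen so its *polygon* area is
    the target disc area; the cup is an ellipse polygon with vertical
    semi-axis ``vcdr * r_disc`` (so the extent ratio equals the target CDR)
    and horizontal semi-axis chosen to hit the target cup area.
    """
    mm_per_px = scan_width_mm / image_width_px
    C = _polygon_shape_factor()
    r_mm = math.sqrt(disc_area_mm2 / C)
    b_mm = vertical_cdr * r_mm
    a_mm = cup_area_mm2 / (C * b_mm)
    cx = cy = image_width_px / 2.0
    disc = circle_polygon_vertices(cx, cy, r_mm / mm_per_px, r_mm / mm_per_px)
    cup = circle_polygon_vertices(cx, cy, a_mm / mm_per_px, b_mm / mm_per_px)
    return {
        "eye_id": eye_id,
        "image_width_px": image_width_px,
        "scan_width_mm": scan_width_mm,
        "rois": [
            {"label": "disc", "vertices": disc},
            {"label": "cup", "vertices": cup},
        ],
        "lines": [],
    }


def _draw_onh_triples(
    rng: np.random.Generator, g: GroupScenario, n: int
) -> np.ndarray:
    """``n`` jointly admissible (disc area, cup area, vertical CDR) rows.

    Redraws until cup_area <= disc_area.  At the default moments this
    rejects ~1e-4 of draws, so marginal means are unaffected to well within
    sampling error.  A wide shallow cup may spill horizontally past the disc
    circle in the polygon fixture — containment is enforced on area and
    vertical extent only, matching the measurement contract."""
    out = np.empty((n, 3))
    need = np.ones(n, dtype=bool)
    for _ in range(_REDRAW_CAP):
        k = int(need.sum())
        if k == 0:
            return out
        disc = _sample_variable(rng, g.variables["disc_area_mm2"], k)
        cup = _sample_variable(rng, g.variables["cup_area_mm2"], k)
        vcdr = _sample_variable(rng, g.variables["vertical_cdr"], k)
        ok = cup <= disc
        idx = np.flatnonzero(need)[ok]
        out[idx, 0] = disc[ok]
        out[idx, 1] = cup[ok]
        out[idx, 2] = vcdr[ok]
        need[idx] = False
    raise ConfigError("ONH triple sampling exceeded the redraw cap")


# --------------------------------------------------------------------------
# Cohort generation

@dataclass
class SyntheticCohort:
    """A generated two-group cohort plus its raw measurement artifacts."""

    frame: pd.DataFrame
    branch_sets: list[BranchDiameterSet]
    annotations: list[dict]
    config: ScenarioConfig
    seed: int


def generate_cohort(config: ScenarioConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Draw one cohort under ``config``; deterministic given the seed.

    Every subject gets covariates and RNFL values; ONH and vessel values are
    present only for the per-block subsets (missingness masks drawn without
    replacement), reproducing the study's differing block Ns.  Stored CRVE /
    CRAE are the re-summarized branch equivalents, so re-running the vessel
    pipeline on ``branch_sets`` reproduces them bit for bit.
    """
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    branch_sets: list[BranchDiameterSet] = []
    annotations: list[dict] = []

    for gname in (Group.HAPC.value, Group.HEALTHY_HA.value):
        g = config.groups[gname]
        n = g.n_subjects
        tag = "HAPC" if gname == Group.HAPC.value else "HA"
        ids = [f"{tag}{i + 1:03d}" for i in range(n)]

        sex = np.where(rng.random(n) < g.sex_male_prop, "M", "F")
        age = _sample_variable(rng, g.variables["age_years"], n)
        bmi = _sample_variable(rng, g.variables["bmi"], n)
        iop = _sample_variable(rng, g.variables["iop_mmHg"], n)

        if gname == Group.HAPC.value and config.hgb_crve_correlation != 0.0:
            hgb, crve_t = _sample_hgb_crve(
                rng, g.variables["hgb_g_per_L"], g.variables["crve_mm"],
                config.hgb_crve_correlation, n,
            )
        else:
            hgb = _sample_variable(rng, g.variables["hgb_g_per_L"], n)
            crve_t = _sample_variable(rng, g.variables["crve_mm"], n)
        crae_t = _sample_variable(rng, g.variables["crae_mm"], n)

        rnfl = {k: _sample_variable(rng, g.variables[f"rnfl_{k}_um"], n)
                for k in ("mean", "superior", "inferior", "nasal", "temporal")}
        rim = _sample_variable(rng, g.variables["rim_height_um"], n)

        onh_idx = np.sort(rng.choice(n, size=g.n_onh, replace=False))
        ves_idx = set(np.sort(rng.choice(n, size=g.n_vessels, replace=False)).tolist())
        onh_triples = dict(zip(onh_idx.tolist(), _draw_onh_triples(rng, g, g.n_onh)))

        for i in range(n):
            row = {c: np.nan for c in COHORT_COLUMNS}
            row.update(
                eye_id=ids[i], group=gname, age_years=float(age[i]), sex=str(sex[i]),
                bmi=float(bmi[i]), iop_mmHg=float(iop[i]), hgb_g_per_L=float(hgb[i]),
                rnfl_mean_um=float(rnfl["mean"][i]),
                rnfl_superior_um=float(rnfl["superior"][i]),
                rnfl_inferior_um=float(rnfl["inferior"][i]),
                rnfl_nasal_um=float(rnfl["nasal"][i]),
                rnfl_temporal_um=float(rnfl["temporal"][i]),
            )

            if i in onh_triples:
                disc, cup, vcdr = (float(v) for v in onh_triples[i])
                annotations.append(_onh_annotation(
                    ids[i], disc, cup, vcdr, config.image_width_px, config.scan_width_mm))
                row.update(rim_height_um=float(rim[i]), cup_area_mm2=cup,
                           disc_area_mm2=disc, vertical_cdr=vcdr)

            if i in ves_idx:
                veins = decompose_to_branches(
                    float(crve_t[i]), VesselType.VEIN, config.branch_count, rng,
                    config.branch_log_sd)
                arteries = decompose_to_branches(
                    float(crae_t[i]), VesselType.ARTERY, config.branch_count, rng,
                    config.branch_log_sd)
                branches = [
                    BranchDiameter(w, VesselType.VEIN, q)
                    for w, q in zip(veins, _QUADRANTS)
                ] + [
                    BranchDiameter(w, VesselType.ARTERY, q)
                    for w, q in zip(arteries, _QUADRANTS)
                ]
                branch_sets.append(BranchDiameterSet(eye_id=ids[i], branches=branches))
                # store the re-summarized values so pipeline round trips are exact
                crve = summarize_equivalent(veins, VesselType.VEIN)
                crae = summarize_equivalent(arteries, VesselType.ARTERY)
                row.update(crve_mm=crve, crae_mm=crae, avr=crae / crve)

            rows.append(row)

    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return SyntheticCohort(frame=frame, branch_sets=branch_sets,
                           annotations=annotations, config=config, seed=seed)


def generate_hgb_crve_pairs(config: ScenarioConfig, seed: int, n: Optional[int] = None) -> pd.DataFrame:
    """HAPC-group (HGB, CRVE) pairs at the configured correlation.

    ``n`` defaults to ``config.hgb_crve_pair_n`` — the effective pair count
    used for correlation-recovery checks.  CRVE is recomputed through the
    branch decomposition + Knudtson re-summarization pipeline, not copied
    from the Gaussian draw.
    """
    n = config.hgb_crve_pair_n if n is None else int(n)
    rng = np.random.default_rng(seed)
    g = config.groups[Group.HAPC.value]
    hgb, crve_t = _sample_hgb_crve(
        rng, g.variables["hgb_g_per_L"], g.variables["crve_mm"],
        config.hgb_crve_correlation, n,
    )
    crve = np.empty(n)
    for i in range(n):
        veins = decompose_to_branches(
            float(crve_t[i]), VesselType.VEIN, config.branch_count, rng,
            config.branch_log_sd)
        crve[i] = summarize_equivalent(veins, VesselType.VEIN)
    return pd.DataFrame({"hgb_g_per_L": hgb, "crve_mm": crve})
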