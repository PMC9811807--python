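"""Two-group tests, correlations and report assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retina_quant import (
    build_report,
    compare_categorical,
    compare_groups,
    correlate_hgb,
)
from retina_quant.errors import InsufficientDataError, UndefinedCorrelationError
from retina_quant.stats import Group


def _frame(a_vals, b_vals, column="x"):
    rows = [{"eye_id": f"A{i}", "group": Group.HAPC.value, column: v,
             "hgb_g_per_L": np.nan} for i, v in enumerate(a_vals)]
    rows += [{"eye_id": f"B{i}", "group": Group.HEALTHY_HA.value, column: v,
              "hgb_g_per_L": np.nan} for i, v in enumerate(b_vals)]
    return pd.DataFrame(rows)


def pooled_t_oracle(a, b):
    """Hand-computed pooled-variance two-sample t statistic and p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestCompareGroups:
    def test_matches_pooled_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 23), rng.normal(11, 3, 31)
        c = compare_groups(_frame(a, b), "x", variant="student")
        t, p = pooled_t_oracle(a, b)
        assert c.statistic == pytest.approx(t, rel=1e-12)
        assert c.p_value == pytest.approx(p, rel=1e-12)
        assert (c.n_a, c.n_b) == (23, 31)

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(10, 1, 10), rng.normal(10.5, 6, 40)
        cs = compare_groups(_frame(a, b), "x", variant="student")
        cw = compare_groups(_frame(a, b), "x", variant="welch")
        assert cs.statistic != pytest.approx(cw.statistic)

    def test_identical_constant_groups(self):
        c = compare_groups(_frame([5.0] * 4, [5.0] * 4), "x")
        assert c.statistic == 0.0 and c.p_value == 1.0

    def test_sign_flips_with_group_labels(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(10, 2, 20), rng.normal(12, 2, 20)
        fwd = compare_groups(_frame(a, b), "x")
        rev = compare_groups(_frame(b, a), "x")
        assert fwd.statistic == pytest.approx(-rev.statistic, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_missing_values_dropped_per_variable(self):
        a = [1.0, 2.0, np.nan, 4.0]
        b = [2.0, np.nan, 3.0]
        c = compare_groups(_frame(a, b), "x")
        assert (c.n_a, c.n_b) == (3, 2)

    def test_insufficient_group_raises(self):
        with pytest.raises(InsufficientDataError):
            compare_groups(_frame([1.0], [2.0, 3.0]), "x")


class TestCompareCategorical:
    def test_study_gender_table_not_significant(self):
        # 40/11 vs 35/15 male/female split: consistent with no association
        sex = ["M"] * 40 + ["F"] * 11
        sex_b = ["M"] * 35 + ["F"] * 15
        c = compare_categorical(_frame(sex, sex_b, column="sex"), "sex")
        chi2, p = sps.chi2_contingency([[40, 35], [11, 15]], correction=False)[:2]
        assert c.statistic == pytest.approx(chi2, rel=1e-12)
        assert c.p_value == pytest.approx(p, rel=1e-12)
        assert c.p_value > 0.05

    def test_identical_distributions(self):
        sex = ["M"] * 10 + ["F"] * 10
        c = compare_categorical(_frame(sex, sex, column="sex"), "sex")
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_extreme_association(self):
        c = compare_categorical(
            _frame(["M"] * 10, ["F"] * 10, column="sex"), "sex")
        assert c.p_value < 0.01
        # exact-test oracle agrees on the direction of extremity
        _, p_exact = sps.fisher_exact([[10, 0], [0, 10]])
        assert p_exact < 0.01

    def test_yates_correction_flag(self):
        sex = ["M"] * 40 + ["F"] * 11
        sex_b = ["M"] * 35 + ["F"] * 15
        f = _frame(sex, sex_b, column="sex")
        plain = compare_categorical(f, "sex", correction=False)
        corrected = compare_categorical(f, "sex", correction=True)
        assert corrected.statistic < plain.statistic

    def test_degenerate_table_raises(self):
        with pytest.raises(InsufficientDataError):
            compare_categorical(_frame(["M"] * 5, ["M"] * 5, column="sex"), "sex")


def _hapc_pairs(x, y):
    return pd.DataFrame({
        "eye_id": [f"A{i}" for i in range(len(x))],
        "group": Group.HAPC.value,
        "hgb_g_per_L": x,
        "crve_mm": y,
    })


class TestCorrelateHgb:
    def test_perfect_linear(self):
        x = np.arange(10.0) + 100
        c = correlate_hgb(_hapc_pairs(x, 0.001 * x + 0.05), "crve_mm")
        assert c.r == pytest.approx(1.0)
        assert c.p_value == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(4)
        x = rng.normal(220, 9, 40)
        y = 0.001 * x + rng.normal(0, 0.01, 40)
        base = correlate_hgb(_hapc_pairs(x, y), "crve_mm").r
        assert correlate_hgb(_hapc_pairs(x, 3 * y + 1), "crve_mm").r == pytest.approx(
            base, rel=1e-12)
        assert correlate_hgb(_hapc_pairs(x, -y), "crve_mm").r == pytest.approx(
            -base, rel=1e-12)

    def test_r_squared_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(220, 9, 30)
        y = rng.normal(0.25, 0.03, 30)
        c = correlate_hgb(_hapc_pairs(x, y), "crve_mm")
        assert c.r_squared == pytest.approx(c.r * c.r, rel=1e-15)

    def test_matches_corrcoef_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(220, 9, 35)
        y = 0.002 * x + rng.normal(0, 0.02, 35)
        c = correlate_hgb(_hapc_pairs(x, y), "crve_mm")
        assert c.r == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_hgb(_hapc_pairs(np.full(5, 220.0), np.arange(5.0) + 1), "crve_mm")

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            correlate_hgb(_hapc_pairs([220, 221], [0.2, 0.21]), "crve_mm")


class TestEyeRecords:
    def test_records_flatten_and_duplicates_rejected(self):
        from retina_quant import EyeRecord, ONHMeasurement, VesselSummary
        from retina_quant.errors import ValidationError
        from retina_quant.stats import records_to_frame
        rec = EyeRecord(
            eye_id="E1", group="HAPC", age_years=50, sex="M", bmi=22.0,
            hgb_g_per_L=220.0, iop_mmHg=12.0,
            rnfl_um={"mean": 102.0, "nasal": 75.0},
            onh=ONHMeasurement(2.39, 0.56, 0.48, 494.0),
            vessels=VesselSummary(0.16, 0.25, 0.16 / 0.25))
        f = records_to_frame([rec])
        assert f.loc[0, "disc_area_mm2"] == 2.39
        assert f.loc[0, "crve_mm"] == 0.25
        assert np.isnan(f.loc[0, "rnfl_temporal_um"])
        with pytest.raises(ValidationError):
            records_to_frame([rec, rec])  # one record per subject

    def test_sanity_ranges_enforced(self):
        from retina_quant import EyeRecord
        from retina_quant.errors import ValidationError
        with pytest.raises(ValidationError):
            EyeRecord(eye_id="E", group="HAPC", age_years=50, sex="M", bmi=22,
                      hgb_g_per_L=400.0, iop_mmHg=12)
        with pytest.raises(ValidationError):
            EyeRecord(eye_id="E", group="HAPC", age_years=50, sex="M", bmi=22,
                      hgb_g_per_L=220.0, iop_mmHg=12, rnfl_um={"nasal": 10.0})


class TestBuildReport:
    def test_full_cohort_report_structure(self, small_cohort):
        bundle = build_report(small_cohort.frame)
        assert len(bundle.demographics) >= 5
        blocks = set(bundle.oct_comparisons["Block"])
        assert blocks == {"RNFL thickness", "ONH parameters", "Retinal vessel diameters"}
        assert len(bundle.correlations) == 11
        assert bundle.figure is not None
        # block Ns reflect the per-block missingness masks
        eyes = bundle.oct_comparisons[bundle.oct_comparisons["Variable"] == "Eyes (n)"]
        assert eyes["HAPC"].tolist() == ["51", "43", "47"]
        assert eyes["Healthy HA"].tolist() == ["50", "42", "33"]

    def test_missing_vessel_block_degrades_gracefully(self, small_cohort):
        frame = small_cohort.frame.copy()
        frame[["crae_mm", "crve_mm", "avr"]] = np.nan
        bundle = build_report(frame)
        vblock = bundle.oct_comparisons[
            bundle.oct_comparisons["Block"] == "Retinal vessel diameters"]
        assert (vblock[vblock["Variable"] != "Eyes (n)"]["HAPC"]
                == "insufficient data").all()
        assert bundle.figure is None
        # other blocks intact
        rblock = bundle.oct_comparisons[bundle.oct_comparisons["Block"] == "RNFL thickness"]
        assert not (rblock["HAPC"] == "insufficient data").any()
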