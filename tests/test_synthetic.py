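"""Synthetic cohort generator: determinism, moment matching, decomposition."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import retina_quant as rq
from retina_quant.errors import ConfigError
from retina_quant.synthetic import (
    ScenarioConfig,
    VariableSpec,
    _match_truncnorm,
    decompose_to_branches,
    generate_hgb_crve_pairs,
    null_scenario,
)
from retina_quant.vessels import VesselType, summarize_equivalent


class TestMomentMatching:
    @pytest.mark.parametrize("mean,sd,lo,hi", [
        (74.82, 14.4, 30, 300),    # mild truncation
        (0.56, 0.27, 0.01, 6.0),   # moderate
        (0.16, 0.12, 0.02, 0.6),   # severe: appreciable Gaussian mass below lb
        (0.48, 0.15, 0.02, 0.98),  # two-sided
    ])
    def test_truncated_moments_hit_targets(self, mean, sd, lo, hi):
        mu, sig = _match_truncnorm(mean, sd, lo, hi)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        assert float(m) == pytest.approx(mean, rel=1e-7)
        assert float(np.sqrt(v)) == pytest.approx(sd, rel=1e-7)

    def test_infeasible_sd_raises(self):
        # no truncated normal on [0, 1] has sd 0.4 (the uniform limit is ~0.289)
        with pytest.raises(ConfigError):
            _match_truncnorm(0.5, 0.4, 0.0, 1.0)


class TestVariableSpecValidation:
    @pytest.mark.parametrize("kw", [
        dict(mean=1.0, sd=0.0, lower=0, upper=2),
        dict(mean=1.0, sd=-1.0, lower=0, upper=2),
        dict(mean=1.0, sd=0.1, lower=2, upper=0),
        dict(mean=100.0, sd=1.0, lower=0, upper=10),  # mean > 6 SD outside bounds
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ConfigError):
            VariableSpec(**kw)


class TestScenarioConfig:
    def test_json_round_trip(self, default_config, tmp_path):
        p = tmp_path / "scenario.json"
        default_config.to_json(p)
        again = ScenarioConfig.from_json(p)
        assert again == default_config

    def test_invalid_json_raises(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ConfigError):
            ScenarioConfig.from_json(p)

    def test_missing_group_raises(self, default_config, tmp_path):
        d = default_config.to_dict()
        del d["groups"]["healthy_HA"]
        with pytest.raises(ConfigError):
            ScenarioConfig.from_dict(d)

    def test_correlation_bounds(self, default_config):
        d = default_config.to_dict()
        d["hgb_crve_correlation"] = 1.0
        with pytest.raises(ConfigError):
            ScenarioConfig.from_dict(d)


class TestDecomposeToBranches:
    @pytest.mark.parametrize("target,vt", [
        (0.301695, VesselType.VEIN),
        (0.2, VesselType.ARTERY),
    ])
    def test_resummarization_recovers_target(self, target, vt):
        rng = np.random.default_rng(9)
        for _ in range(20):
            ws = decompose_to_branches(target, vt, 4, rng)
            assert summarize_equivalent(ws, vt) == pytest.approx(target, rel=1e-12)

    def test_zero_spread_gives_equal_widths(self):
        rng = np.random.default_rng(0)
        k = 0.95
        ws = decompose_to_branches(0.3, VesselType.VEIN, 4, rng, log_sd=0.0)
        # 4 equal widths w have equivalent k^2 * 2 * w, so w = target / (2 k^2)
        assert np.allclose(ws, 0.3 / (2 * k**2), rtol=1e-12)

    def test_nonpositive_target_raises(self):
        with pytest.raises(ConfigError):
            decompose_to_branches(0.0, VesselType.VEIN)


class TestGenerateCohort:
    def test_group_and_block_sizes(self, small_cohort):
        f = small_cohort.frame
        assert (f["group"] == "HAPC").sum() == 51
        assert (f["group"] == "healthy_HA").sum() == 50
        hapc = f[f["group"] == "HAPC"]
        healthy = f[f["group"] == "healthy_HA"]
        assert hapc["disc_area_mm2"].notna().sum() == 43
        assert healthy["disc_area_mm2"].notna().sum() == 42
        assert hapc["crve_mm"].notna().sum() == 47
        assert healthy["crve_mm"].notna().sum() == 33
        assert len(small_cohort.branch_sets) == 80
        assert len(small_cohort.annotations) == 85

    def test_same_seed_is_byte_identical(self, default_config, tmp_path):
        from retina_quant.io import write_cohort_csv
        c1 = rq.generate_cohort(default_config, seed=7)
        c2 = rq.generate_cohort(default_config, seed=7)
        pd.testing.assert_frame_equal(c1.frame, c2.frame)
        write_cohort_csv(c1.frame, tmp_path / "a.csv")
        write_cohort_csv(c2.frame, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert json.dumps(c1.annotations) == json.dumps(c2.annotations)

    def test_different_seeds_differ(self, default_config):
        c1 = rq.generate_cohort(default_config, seed=7)
        c2 = rq.generate_cohort(default_config, seed=8)
        assert not c1.frame["hgb_g_per_L"].equals(c2.frame["hgb_g_per_L"])

    def test_stored_equivalents_are_resummarized_branches_bitwise(self, small_cohort):
        by_eye = {s.eye_id: s for s in small_cohort.branch_sets}
        sub = small_cohort.frame.dropna(subset=["crve_mm"])
        for _, row in sub.iterrows():
            s = by_eye[row["eye_id"]]
            assert summarize_equivalent(s.vein_widths, VesselType.VEIN) == row["crve_mm"]
            assert summarize_equivalent(s.artery_widths, VesselType.ARTERY) == row["crae_mm"]

    def test_values_respect_physiological_bounds(self, small_cohort, default_config):
        f = small_cohort.frame
        for col in ("rnfl_mean_um", "rnfl_nasal_um", "rnfl_temporal_um"):
            assert f[col].between(30, 300).all()
        sub = f.dropna(subset=["vertical_cdr"])
        assert sub["vertical_cdr"].between(0, 1).all()
        assert (sub["cup_area_mm2"] <= sub["disc_area_mm2"]).all()

    def test_single_cohort_hgb_mean_within_3se(self, small_cohort):
        hapc = small_cohort.frame[small_cohort.frame["group"] == "HAPC"]
        se = 9.32 / np.sqrt(51)
        assert abs(hapc["hgb_g_per_L"].mean() - 219.84) < 3 * se


class TestCorrelationStructure:
    def test_null_correlation_recovered(self, default_config):
        d = default_config.to_dict()
        d["hgb_crve_correlation"] = 0.0
        cfg = ScenarioConfig.from_dict(d)
        rs = []
        for seed in range(1, 101):
            p = generate_hgb_crve_pairs(cfg, seed=seed)
            rs.append(np.corrcoef(p["hgb_g_per_L"], p["crve_mm"])[0, 1])
        rs = np.asarray(rs)
        mc_se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 2 * mc_se + 1e-3

    def test_null_scenario_groups_share_parameters(self):
        cfg = null_scenario()
        assert (cfg.groups["HAPC"].variables["hgb_g_per_L"]
                == cfg.groups["healthy_HA"].variables["hgb_g_per_L"])
        assert cfg.hgb_crve_correlation == 0.0
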