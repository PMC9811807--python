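import numpy as np
import pytest
from hypothesis import settings

import retina_quant as rq
from retina_quant import io as rqio

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: The four printed branch-vein diameters of the worked summarization example.
WORKED_VEINS = [0.148, 0.101, 0.195, 0.204]


@pytest.fixture(scope="session")
def default_config():
    return rq.paper_default()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """One generated cohort shared by structural tests."""
    return rq.generate_cohort(default_config, seed=11)


@pytest.fixture(scope="session")
def study_batch(default_config):
    """200 replicate cohorts with pipeline-recomputed vessel and ONH values.

    Per replicate: HAPC/healthy group means of nasal RNFL and HGB from the
    cohort table, CRVE/CRAE group means re-summarized from the branch CSV
    dialect, disc area group means measured through the calibrated polygon
    path, and the per-variable group-test p-values.
    """
    rows = []
    for seed in range(1, 201):
        cohort = rq.generate_cohort(default_config, seed=seed)
        frame = cohort.frame.drop(columns=["crae_mm", "crve_mm", "avr",
                                           "disc_area_mm2", "cup_area_mm2",
                                           "vertical_cdr"])
        summary, _ = rqio.summarize_branches(cohort.branch_sets)
        measures, _ = rqio.measure_annotations(cohort.annotations)
        merged = rqio.merge_cohort(frame, vessels=summary, measures=measures)
        rec = {}
        for grp, tag in (("HAPC", "hapc"), ("healthy_HA", "healthy")):
            sub = merged[merged["group"] == grp]
            for col, name in (("rnfl_nasal_um", "nasal"), ("hgb_g_per_L", "hgb"),
                              ("crve_mm", "crve"), ("crae_mm", "crae"),
                              ("disc_area_mm2", "disc")):
                rec[f"{tag}_{name}"] = sub[col].mean()
        for col, name in (("crve_mm", "crve"), ("crae_mm", "crae")):
            rec[f"p_{name}"] = rq.compare_groups(merged, col).p_value
        rows.append(rec)
    import pandas as pd
    return pd.DataFrame(rows)
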