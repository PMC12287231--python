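"""Bootstrap-percentile shrinkage: determinism, recomputable CIs, report
layout, and attenuation of selection-inflated estimates."""

import numpy as np
import pandas as pd
import pytest

from sirsurv import (ShrinkageResult, SimulationConfig, add_biomarkers,
                     bootstrap_shrinkage, shrinkage_report, simulate_cohort)
from sirsurv.discrimination import ModelSpec, build_design


@pytest.fixture(scope="module")
def null_cohort():
    return add_biomarkers(simulate_cohort(SimulationConfig(
        seed=555, n_subjects=400, effect_mode="null")))


@pytest.fixture(scope="module")
def shrunk(null_cohort):
    return bootstrap_shrinkage(null_cohort["nlr"].to_numpy(),
                               null_cohort["os_time"].to_numpy(),
                               null_cohort["os_event"].to_numpy(),
                               n_bootstrap=200, seed=99)


def test_seeded_determinism(null_cohort, shrunk):
    again = bootstrap_shrinkage(null_cohort["nlr"].to_numpy(),
                                null_cohort["os_time"].to_numpy(),
                                null_cohort["os_event"].to_numpy(),
                                n_bootstrap=200, seed=99)
    assert again.shrunken_log_hr == shrunk.shrunken_log_hr
    assert again.shrunken_ci == shrunk.shrunken_ci
    assert again.per_replicate.equals(shrunk.per_replicate)


def test_percentile_ci_recomputable_from_replicates(shrunk):
    slopes = shrunk.per_replicate["calibration_slope"].dropna().to_numpy()
    draws = slopes * shrunk.naive_log_hr
    assert shrunk.shrinkage_factor == np.mean(slopes)
    assert shrunk.shrunken_ci == (np.percentile(draws, 2.5),
                                  np.percentile(draws, 97.5))


def test_shrinkage_attenuates_null_estimate(shrunk):
    assert abs(shrunk.shrunken_log_hr) < abs(shrunk.naive_log_hr)
    assert shrunk.shrinkage_factor < 1.0


def test_adjusted_variant_and_report(null_cohort, shrunk):
    clin = build_design(null_cohort, ModelSpec())
    adj = bootstrap_shrinkage(null_cohort["nlr"].to_numpy(),
                              null_cohort["os_time"].to_numpy(),
                              null_cohort["os_event"].to_numpy(),
                              adjust=clin, n_bootstrap=200, seed=100)
    assert adj.adjusted and not shrunk.adjusted
    report = shrinkage_report(shrunk, adj)
    assert list(report["model"].unique()) == ["Unadjusted model",
                                              "Adjusted model"]
    assert list(report["estimate"].unique()) == [
        "Original", "Shrunken coefficients Bootstrap CI"]
    # HRs are the exponentials of the stored log-HR fields
    assert report["hr"].iloc[0] == pytest.approx(
        np.exp(shrunk.naive_log_hr), rel=1e-12)
    assert report["hr"].iloc[3] == pytest.approx(
        np.exp(adj.shrunken_log_hr), rel=1e-12)


def _mk_result(**over):
    base = dict(biomarker="nlr", adjusted=False, cutoff=2.0,
                naive_log_hr=0.5, naive_se=0.1, naive_ci=(0.3, 0.7),
                naive_p=0.001, shrinkage_factor=1.0, shrunken_log_hr=0.5,
                shrunken_ci=(0.3, 0.7), shrunken_p=0.001, n_bootstrap=200,
                n_failed_replicates=0,
                per_replicate=pd.DataFrame({"cutoff": [2.0],
                                            "calibration_slope": [1.0],
                                            "log_hr": [0.5]}),
                seed=1, reselect=True, method="calibration_slope",
                ci_percentiles=(2.5, 97.5), n=100)
    base.update(over)
    return ShrinkageResult(**base)


def test_unit_shrinkage_factor_leaves_rows_identical():
    res = _mk_result()
    report = shrinkage_report(res, _mk_result(adjusted=True))
    unadj = report[report["model"] == "Unadjusted model"]
    assert unadj.iloc[0]["hr"] == unadj.iloc[1]["hr"]
    assert unadj.iloc[0][["ci_lower", "ci_upper"]].tolist() == \
        unadj.iloc[1][["ci_lower", "ci_upper"]].tolist()


def test_report_rejects_mismatched_cohorts():
    with pytest.raises(ValueError, match="mismatched"):
        shrinkage_report(_mk_result(), _mk_result(n=999))


def test_bias_subtraction_variant(null_cohort):
    res = bootstrap_shrinkage(null_cohort["nlr"].to_numpy(),
                              null_cohort["os_time"].to_numpy(),
                              null_cohort["os_event"].to_numpy(),
                              n_bootstrap=200, seed=7,
                              method="bias_subtraction")
    reps = res.per_replicate["log_hr"].dropna().to_numpy()
    expected = res.naive_log_hr - (reps.mean() - res.naive_log_hr)
    assert res.shrunken_log_hr == pytest.approx(expected)


def test_minimum_bootstrap_enforced(null_cohort):
    with pytest.raises(ValueError, match="200"):
        bootstrap_shrinkage(null_cohort["nlr"].to_numpy(),
                            null_cohort["os_time"].to_numpy(),
                            null_cohort["os_event"].to_numpy(),
                            n_bootstrap=50, seed=1)
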