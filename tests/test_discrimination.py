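"""Model specification, design encoding, IPCW discrimination slope and IDI."""

import numpy as np
import pandas as pd
import pytest

from sirsurv import ModelSpec, build_design, fit_model, idi
from sirsurv.discrimination import (censoring_weights, discrimination_slope,
                                    idi_from_risks, model_comparison_report)


def test_clinical_design_dummy_coding(small_cohort):
    X = build_design(small_cohort, ModelSpec())
    assert "age" in X and "afp_gt400" in X
    assert {"child_pugh_B", "child_pugh_C"} <= set(X.columns)
    assert {"bclc_A", "bclc_B", "bclc_C", "bclc_D"} <= set(X.columns)
    # reference levels carry no column
    assert "child_pugh_A" not in X and "bclc_0" not in X


def test_categorical_block_two_cnp_dummies(small_cohort):
    X = build_design(small_cohort, ModelSpec(biomarker_block="categorical"),
                     cutoffs={"nlr": 1.45, "plr": 188.0})
    assert {"cnp_1", "cnp_2"} <= set(X.columns)
    assert "cnp_0" not in X.columns


def test_categorical_block_requires_cutoffs(small_cohort):
    with pytest.raises(ValueError, match="cutoff"):
        build_design(small_cohort, ModelSpec(biomarker_block="categorical"))


def test_continuous_block_enters_log_nlr(small_cohort):
    X = build_design(small_cohort, ModelSpec(biomarker_block="continuous"))
    assert np.allclose(X["log_nlr"], np.log(small_cohort["nlr"]))
    assert np.allclose(X["plr_per_100"], small_cohort["plr"] / 100)


def test_empty_level_dropped_with_warning(small_cohort):
    c = small_cohort.copy()
    c.loc[c["child_pugh"] == "C", "child_pugh"] = "B"
    with pytest.warns(UserWarning, match="empty level"):
        X = build_design(c, ModelSpec())
    assert "child_pugh_C" not in X.columns


def test_italica_staging_option(small_cohort):
    X = build_design(small_cohort, ModelSpec(staging="ITA.LI.CA"))
    assert {"italica_A", "italica_B", "italica_C"} <= set(X.columns)
    assert "bclc_A" not in X.columns


def test_adding_covariates_never_decreases_loglik(small_cohort):
    base = fit_model(small_cohort, ModelSpec())
    ext = fit_model(small_cohort, ModelSpec(biomarker_block="continuous"))
    assert ext.loglik_fit >= base.loglik_fit - 1e-9


def test_zero_censoring_weights_are_one():
    t = np.array([3.0, 10, 20, 30, 50, 70])
    e = np.ones(6)
    w = censoring_weights(t, e, horizon=36.0)
    assert np.allclose(w[t <= 36], 1.0)
    assert np.allclose(w[t > 36], 1.0)


def test_idi_hand_oracle_uncensored():
    """Six uncensored subjects with hand-assigned risks."""
    t = np.array([10.0, 20, 30, 50, 60, 70])
    e = np.ones(6)
    horizon = 36.0
    base = np.array([0.50, 0.40, 0.30, 0.35, 0.20, 0.10])
    ext = np.array([0.70, 0.60, 0.40, 0.25, 0.10, 0.05])
    # events by 36: subjects 0-2; event-free: 3-5
    d_base = np.mean([0.50, 0.40, 0.30]) - np.mean([0.35, 0.20, 0.10])
    d_ext = np.mean([0.70, 0.60, 0.40]) - np.mean([0.25, 0.10, 0.05])
    expected = d_ext - d_base
    assert idi_from_risks(base, ext, t, e, horizon) == pytest.approx(expected)
    # with no censoring the IPCW estimator equals the plain difference
    assert idi_from_risks(base, ext, t, e, horizon, ipcw=False) == \
        pytest.approx(expected)


def test_idi_antisymmetry(medium_cohort, rng):
    t = medium_cohort["os_time"].to_numpy()
    e = medium_cohort["os_event"].to_numpy()
    a = rng.random(t.size)
    b = rng.random(t.size)
    ab = idi_from_risks(a, b, t, e, 36.0)
    ba = idi_from_risks(b, a, t, e, 36.0)
    assert ab == pytest.approx(-ba)


def test_ipcw_reduces_to_pencina_without_censoring(rng):
    n = 120
    t = rng.exponential(30, n)
    e = np.ones(n)
    risks = rng.random(n)
    with_w = discrimination_slope(risks, t, e, 20.0, ipcw=True)
    without = discrimination_slope(risks, t, e, 20.0, ipcw=False)
    assert with_w == pytest.approx(without)


def test_idi_self_comparison_is_zero(small_cohort):
    res = idi(small_cohort, ModelSpec(), ModelSpec(), horizon=36.0,
              n_bootstrap=50, seed=3)
    assert res.idi == 0.0
    assert res.idi_p == 1.0
    assert res.c_index_base == res.c_index_extended


def test_idi_result_recomputable_from_stored_risks(small_cohort):
    res = idi(small_cohort, ModelSpec(),
              ModelSpec(biomarker_block="continuous"), horizon=36.0,
              n_bootstrap=50, seed=3)
    ps = res.per_subject
    again = idi_from_risks(ps["risk_base"], ps["risk_extended"],
                           ps["os_time"], ps["os_event"], res.horizon)
    assert again == pytest.approx(res.idi)


def test_idi_requires_events_by_horizon(small_cohort):
    with pytest.raises(ValueError, match="horizon"):
        idi(small_cohort, ModelSpec(), ModelSpec(), horizon=1e-6,
            n_bootstrap=50, seed=1)


def test_model_comparison_report_layout(small_cohort):
    report = model_comparison_report(
        small_cohort, cutoffs={"nlr": 1.45, "plr": 188.0}, horizon=36.0,
        n_bootstrap=50, seed=11)
    terms = set(report.table["term"])
    assert "Log (NLR)" in terms
    assert "CNP 0" in terms and "CNP 1" in terms and "CNP 2" in terms
    refs = report.table[report.table["reference"]]
    assert (refs["hr"] == 1.0).all()
    assert set(report.discrimination.index) == {
        "Clinical", "Clinical + continuous biomarkers",
        "Clinical + categorical biomarkers"}
    wide = report.wide()
    assert wide.loc["CHILD score A (Ref.)"].eq("1").all()
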