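"""Cohort-generator tests: determinism, marginal calibration, copula
behaviour, censoring control and the exact linear predictor."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from sirsurv import (SimulationConfig, add_biomarkers, cox_fit, read_cohort,
                     simulate_cohort, true_linear_predictor, write_cohort)


def test_fixed_seed_bit_identical():
    a = simulate_cohort(SimulationConfig(seed=7, n_subjects=200))
    b = simulate_cohort(SimulationConfig(seed=7, n_subjects=200))
    assert a.equals(b)


def test_different_seed_differs():
    a = simulate_cohort(SimulationConfig(seed=7, n_subjects=200))
    b = simulate_cohort(SimulationConfig(seed=8, n_subjects=200))
    assert not a.equals(b)


def test_marginals_track_configured_medians():
    c = add_biomarkers(simulate_cohort(SimulationConfig(seed=3,
                                                        n_subjects=4000)))
    assert c["nlr"].median() == pytest.approx(2.22, abs=0.2)
    assert c["plr"].median() == pytest.approx(87.0, abs=8.0)
    rho = spearmanr(c["nlr"], c["plr"]).statistic
    assert rho == pytest.approx(0.56, abs=0.07)


def test_copula_monotone_in_target_rho():
    realized = []
    for target in (0.2, 0.56, 0.8):
        vals = []
        for seed in range(3):
            c = add_biomarkers(simulate_cohort(SimulationConfig(
                seed=100 + seed, n_subjects=4000,
                biomarker_rank_corr=target)))
            vals.append(spearmanr(c["nlr"], c["plr"]).statistic)
        realized.append(np.mean(vals))
    assert realized[0] < realized[1] < realized[2]


def test_censoring_fraction_near_target():
    for target in (0.2, 0.35, 0.5):
        c = simulate_cohort(SimulationConfig(seed=11, n_subjects=5000,
                                             censor_rate=target))
        assert 1 - c["os_event"].mean() == pytest.approx(target, abs=0.05)


def test_counts_consistent_with_ratios():
    c = add_biomarkers(simulate_cohort(SimulationConfig(seed=5,
                                                        n_subjects=100)))
    assert np.allclose(c["nlr"] * c["lymphocytes"], c["neutrophils"])
    assert np.allclose(c["plr"] * c["lymphocytes"], c["platelets"])
    assert (c["lymphocytes"] > 0).all()


def test_true_linear_predictor_zero_betas():
    cfg = SimulationConfig(seed=1, beta_log_nlr=0.0, beta_plr=0.0,
                           beta_covariates={})
    rec = {"neutrophils": 3.0, "lymphocytes": 1.5, "platelets": 120.0,
           "age": 70.0, "afp_gt400": 1, "child_pugh": "B", "bclc": "C"}
    assert true_linear_predictor(rec, cfg) == 0.0


def test_true_linear_predictor_unit_log_nlr():
    # NLR = e with only the log-NLR effect active gives exactly that log-HR
    cfg = SimulationConfig(seed=1, beta_log_nlr=math.log(1.61), beta_plr=0.0,
                           beta_covariates={})
    rec = {"neutrophils": math.e, "lymphocytes": 1.0, "platelets": 50.0}
    assert true_linear_predictor(rec, cfg) == pytest.approx(math.log(1.61))


def test_true_linear_predictor_matches_brute_force():
    cfg = SimulationConfig(seed=9, n_subjects=50)
    c = add_biomarkers(simulate_cohort(cfg))
    row = c.iloc[23]
    expected = (cfg.beta_log_nlr * math.log(row["nlr"])
                + cfg.beta_plr * row["plr"] / 100
                + cfg.beta_covariates["age"] * row["age"]
                + cfg.beta_covariates["afp_gt400"] * row["afp_gt400"]
                + cfg.beta_covariates.get(f"child_pugh:{row['child_pugh']}", 0)
                + cfg.beta_covariates.get(f"bclc:{row['bclc']}", 0))
    assert true_linear_predictor(row, cfg) == pytest.approx(expected)


def test_threshold_mode_uses_step_effect():
    cfg = SimulationConfig(seed=2, effect_mode="threshold",
                           beta_log_nlr=1.0, beta_plr=0.0,
                           true_cutoff_nlr=2.0, beta_covariates={})
    c = add_biomarkers(simulate_cohort(cfg))
    row_lo = c[c["nlr"] <= 2.0].iloc[0]
    row_hi = c[c["nlr"] > 2.0].iloc[0]
    assert true_linear_predictor(row_lo, cfg) == 0.0
    assert true_linear_predictor(row_hi, cfg) == 1.0


def test_null_mode_has_no_biomarker_association():
    """Cox z-statistic of log(NLR) on null-mode outcomes is typically small."""
    hits = 0
    for seed in range(10):
        c = add_biomarkers(simulate_cohort(SimulationConfig(
            seed=300 + seed, n_subjects=1000, effect_mode="null")))
        fit = cox_fit(np.log(c["nlr"].to_numpy())[:, None],
                      c["os_time"], c["os_event"])
        hits += abs(fit.z[0]) < 3
    assert hits >= 8


@pytest.mark.parametrize("field,value", [
    ("nlr_log_sd", -1.0),
    ("baseline_scale", 0.0),
    ("biomarker_rank_corr", 1.5),
    ("censor_rate", 1.0),
    ("effect_mode", "quadratic"),
    ("nlr_log_mean", float("nan")),
])
def test_config_validation_rejects_bad_parameters(field, value):
    with pytest.raises(ValueError):
        SimulationConfig(**{"seed": 1, field: value})


def test_config_rejects_unnormalised_frequencies():
    freqs = SimulationConfig(seed=1).covariate_freqs
    freqs["child_pugh"] = {"A": 0.5, "B": 0.5, "C": 0.5}
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(seed=1, covariate_freqs=freqs)


def test_cohort_csv_round_trip(tmp_path):
    c = simulate_cohort(SimulationConfig(seed=4, n_subjects=50))
    path = tmp_path / "cohort.csv"
    write_cohort(c, path)
    back = read_cohort(path)
    assert list(back.columns) == list(c.columns)
    assert np.allclose(back["os_time"], c["os_time"])
    assert (back["child_pugh"] == c["child_pugh"]).all()
    # optional RFS fields are empty for non-curative subjects
    noncur = back[~back["treatment"].isin(["LT", "LR", "ABL"])]
    assert noncur["rfs_time"].isna().all()


def test_config_from_file(tmp_path):
    (tmp_path / "sim.yaml").write_text(
        "seed: 12\nn_subjects: 40\ncensor_rate: 0.2\n")
    cfg = SimulationConfig.from_file(tmp_path / "sim.yaml")
    assert cfg.seed == 12 and cfg.n_subjects == 40
    (tmp_path / "bad.yaml").write_text("n_subjects: 40\n")
    with pytest.raises(ValueError, match="seed"):
        SimulationConfig.from_file(tmp_path / "bad.yaml")
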