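import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import sivar
from sivar.errors import FittingError, ValidationError
from sivar.mixed import MINUTES_PER_DAY, build_observations

from conftest import simulate_glmm_dataset, simulate_lme_dataset


# ---------------------------------------------------------------------------
# observation construction
# ---------------------------------------------------------------------------

def _records(p, t=None):
    n = len(p)
    return pd.DataFrame({
        "patient_id": "NOpC0000", "diagnosis": "NOpC",
        "time_min": t if t is not None else 60.0 * np.arange(1, n + 1),
        "percentile": np.asarray(p, dtype=float),
    })


def test_quadratic_response_clamps_at_ideal_percentile():
    obs = build_observations(_records([0.5]), "quadratic", eps=1e-6)
    assert obs["response"].iloc[0] == pytest.approx(logit(1e-6))
    # and it is the smallest attainable response
    other = build_observations(_records([0.6]), "quadratic", eps=1e-6)
    assert obs["response"].iloc[0] < other["response"].iloc[0]


def test_one_sided_response_strict_threshold():
    obs = build_observations(_records([0.95, 0.9, 0.5]), "one_sided")
    assert obs["response"].tolist() == [1.0, 0.0, 0.0]


def test_time_cap_matches_brute_force_count():
    rng = np.random.default_rng(2)
    t = rng.integers(60, 12_000, size=400) // 60 * 60
    recs = _records(rng.random(400), t=t.astype(float))
    obs = build_observations(recs, "quadratic", time_cap_min=8000)
    assert len(obs) == int((t <= 8000).sum())
    assert obs.attrs["n_dropped_time_cap"] == int((t > 8000).sum())
    assert (obs["time_min"] <= 8000).all()


def test_quadratic_response_maps_range_into_unit_interval():
    p = np.linspace(0, 1, 11)
    obs = build_observations(_records(p), "quadratic", eps=1e-6)
    from scipy.special import expit
    back = expit(obs["response"].to_numpy())
    assert np.all((back > 0) & (back < 1))
    # p = 0 and p = 1 map to the largest response
    assert obs["response"].iloc[0] == obs["response"].iloc[-1]
    assert obs["response"].iloc[0] == obs["response"].max()


# ---------------------------------------------------------------------------
# LME (quadratic route)
# ---------------------------------------------------------------------------

def test_lme_noiseless_cell_means_recovery():
    rng = np.random.default_rng(3)
    beta = {g: v for g, v in zip(sivar.GROUP_LABELS,
                                 [-0.5, -0.44, -1.05, -0.69, -0.74, -0.85])}
    obs = simulate_lme_dataset(rng, n_patients=36, n_obs=10, beta_groups=beta,
                               beta_t_per_day=-0.18, sd_intercept=0.0,
                               sd_slope=0.0, sd_resid=1e-8)
    res = sivar.fit_lme_quadratic(obs)
    for g in sivar.GROUP_LABELS:
        assert res.fe_params[g] == pytest.approx(beta[g], abs=1e-5)
    assert res.time_per_day == pytest.approx(-0.18, abs=1e-5)
    assert res.time_per_minute == pytest.approx(-0.18 / 1440, abs=1e-8)


def test_lme_patient_order_invariance():
    rng = np.random.default_rng(4)
    obs = simulate_lme_dataset(rng, n_patients=30, n_obs=8)
    res1 = sivar.fit_lme_quadratic(obs)
    perm = obs.sample(frac=1.0, random_state=5).reset_index(drop=True)
    perm.attrs["metric"] = "quadratic"
    res2 = sivar.fit_lme_quadratic(perm)
    np.testing.assert_allclose(res1.fe_params, res2.fe_params, atol=1e-6)


def test_lme_slope_ci_coverage():
    """beta_T lies inside its 95% CI in most replicates (parameter recovery)."""
    truth = -0.18
    hits = 0
    n_rep = 50
    for rep in range(n_rep):
        rng = np.random.default_rng(100 + rep)
        obs = simulate_lme_dataset(rng, n_patients=60, n_obs=12,
                                   beta_t_per_day=truth)
        res = sivar.fit_lme_quadratic(obs)
        se = np.sqrt(res.cov_fe.loc["t_day", "t_day"])
        lo, hi = res.time_per_day - 1.96 * se, res.time_per_day + 1.96 * se
        hits += int(lo <= truth <= hi)
    assert hits / n_rep >= 0.86


def test_lme_requires_two_patients_per_group():
    rng = np.random.default_rng(5)
    obs = simulate_lme_dataset(rng, n_patients=6, n_obs=5)  # 1 per group
    with pytest.raises(FittingError):
        sivar.fit_lme_quadratic(obs)


# ---------------------------------------------------------------------------
# GLMM (one-sided route)
# ---------------------------------------------------------------------------

def test_glmm_intercept_recovers_logit_of_event_rate():
    rng = np.random.default_rng(6)
    n = 4000
    obs = pd.DataFrame({
        "patient_id": np.repeat([f"p{i}" for i in range(200)], n // 200),
        "diagnosis": "NOpO",
        "time_min": 0.0, "t_day": 0.0,
        "response": (rng.random(n) < 0.10).astype(float),
    })
    obs.attrs["metric"] = "one_sided"
    from sivar.glmm import LogisticGLMM
    core = LogisticGLMM(obs["response"], np.ones((n, 1)), obs["patient_id"],
                        re_structure="intercept", exog_names=["const"])
    res = core.fit()
    assert res.fe_params["const"] == pytest.approx(np.log(0.1 / 0.9), abs=0.1)


def test_glmm_negative_slope_sign_recovery():
    signs = []
    for rep in range(12):
        rng = np.random.default_rng(300 + rep)
        obs = simulate_glmm_dataset(rng, n_patients=120, n_obs=24,
                                    beta_t_per_day=-0.12)
        res = sivar.fit_glme_onesided(obs)
        signs.append(res.time_per_day < 0)
    assert np.mean(signs) >= 0.95


def test_glmm_point_estimates_stable_under_duplication():
    rng = np.random.default_rng(7)
    obs = simulate_glmm_dataset(rng, n_patients=80, n_obs=20)
    res1 = sivar.fit_glme_onesided(obs)
    dup = pd.concat([obs, obs.assign(patient_id=obs["patient_id"] + "_b")],
                    ignore_index=True)
    dup.attrs["metric"] = "one_sided"
    res2 = sivar.fit_glme_onesided(dup)
    # doubling the cohort leaves estimates stable within Monte-Carlo error
    assert np.allclose(res1.fe_params, res2.fe_params, atol=0.12)


def test_glmm_requires_both_classes():
    obs = pd.DataFrame({
        "patient_id": ["a"] * 5 + ["b"] * 5, "diagnosis": "NOpC",
        "time_min": 60.0, "t_day": 1.0, "response": 0.0,
    })
    obs.attrs["metric"] = "one_sided"
    with pytest.raises(FittingError):
        sivar.fit_glme_onesided(obs)


def test_glmm_matches_r_lme4_glmer():
    """Dual-route check of the Laplace GLMM against lme4::glmer (nAGQ=1)."""
    rng = np.random.default_rng(8)
    obs = simulate_glmm_dataset(rng, n_patients=60, n_obs=30,
                                beta_t_per_day=-0.3, sd_intercept=0.8,
                                sd_slope=0.15)
    res = sivar.fit_glme_onesided(obs)
    csv = "/tmp/sivar_glmm_check.csv"
    obs.to_csv(csv, index=False)
    rscript = r"""
    d <- read.csv("%s")
    suppressMessages(library(lme4))
    m <- glmer(response ~ 0 + diagnosis + t_day + (1 + t_day | patient_id),
               data = d, family = binomial, nAGQ = 1)
    fe <- fixef(m)
    cat(sprintf("%%s %%.6f\n", names(fe), fe))
    cat(sprintf("logLik %%.4f\n", as.numeric(logLik(m))))
    """ % csv
    proc = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                          text=True, timeout=300)
    assert proc.returncode == 0, proc.stderr
    r_fe = {}
    r_llf = None
    for line in proc.stdout.splitlines():
        name, val = line.split()
        if name == "logLik":
            r_llf = float(val)
        else:
            r_fe[name.replace("diagnosis", "")] = float(val)
    for g in sivar.GROUP_LABELS:
        assert res.fe_params[g] == pytest.approx(r_fe[g], abs=0.05)
    assert res.fe_params["t_day"] == pytest.approx(r_fe["t_day"], abs=0.05)
    assert res.llf == pytest.approx(r_llf, abs=1.0)


# ---------------------------------------------------------------------------
# LR tests, AR(1) check, interaction test
# ---------------------------------------------------------------------------

def test_lr_statistics_nonnegative_and_structured():
    rng = np.random.default_rng(9)
    obs = simulate_lme_dataset(rng, n_patients=40, n_obs=10)
    out = sivar.lr_test_random_structure(obs)
    for key in ("random_intercept", "random_slope"):
        assert out[key]["statistic"] >= 0
        assert 0 <= out[key]["p_value"] <= 1
    assert "boundary" in out["boundary_note"]


def test_lr_random_slope_type1_and_power():
    null_rejects, alt_rejects = [], []
    for rep in range(15):
        rng = np.random.default_rng(520 + rep)
        obs0 = simulate_lme_dataset(rng, n_patients=40, n_obs=20, sd_slope=0.0)
        null_rejects.append(
            sivar.lr_test_random_structure(obs0)["random_slope"]["p_value"] < 0.05)
        obs1 = simulate_lme_dataset(rng, n_patients=40, n_obs=20, sd_slope=0.5)
        alt_rejects.append(
            sivar.lr_test_random_structure(obs1)["random_slope"]["p_value"] < 0.05)
    assert np.mean(null_rejects) <= 0.15  # conservative at the boundary
    assert np.mean(alt_rejects) >= 0.85


def test_glmm_lr_random_intercept_detected():
    rng = np.random.default_rng(10)
    obs = simulate_glmm_dataset(rng, n_patients=100, n_obs=25,
                                sd_intercept=1.0, sd_slope=0.0)
    out = sivar.lr_test_random_structure(obs, metric="one_sided")
    assert out["random_intercept"]["p_value"] < 0.01


def test_ar1_check_calibration_white_noise():
    rejections = []
    for rep in range(20):
        rng = np.random.default_rng(700 + rep)
        obs = simulate_lme_dataset(rng, n_patients=30, n_obs=15)
        out = sivar.test_ar1_necessity(obs, n_boot=200)
        rejections.append(out["p_value"] < 0.05)
    assert np.mean(rejections) <= 0.2


def test_ar1_check_detects_strong_autocorrelation():
    detected = []
    for rep in range(10):
        rng = np.random.default_rng(800 + rep)
        obs = simulate_lme_dataset(rng, n_patients=30, n_obs=15, sd_resid=0.0)
        # inject AR(1) residuals, rho = 0.8
        e = np.empty(len(obs))
        for pid, idx in obs.groupby("patient_id").indices.items():
            z = rng.standard_normal(len(idx))
            ar = np.empty(len(idx))
            ar[0] = z[0]
            for k in range(1, len(idx)):
                ar[k] = 0.8 * ar[k - 1] + np.sqrt(1 - 0.64) * z[k]
            e[idx] = ar
        obs = obs.assign(response=obs["response"] + e)
        obs.attrs["metric"] = "quadratic"
        detected.append(
            sivar.test_ar1_necessity(obs, n_boot=200)["p_value"] < 0.05)
    assert np.mean(detected) >= 0.9


def test_ar1_statistic_invariant_to_patient_relabeling():
    rng = np.random.default_rng(11)
    obs = simulate_lme_dataset(rng, n_patients=25, n_obs=12)
    out1 = sivar.test_ar1_necessity(obs)
    relabeled = obs.assign(patient_id="x" + obs["patient_id"])
    relabeled.attrs["metric"] = "quadratic"
    out2 = sivar.test_ar1_necessity(relabeled)
    assert out1["statistic"] == pytest.approx(out2["statistic"], abs=1e-8)


def test_interaction_test_null_and_alternative():
    rng = np.random.default_rng(12)
    obs = simulate_lme_dataset(rng, n_patients=48, n_obs=12)
    out = sivar.test_time_diagnosis_interaction(obs)
    assert out["df"] == 5
    assert 0 <= out["p_value"] <= 1
    # one group's slope doubled: the joint test should reject
    rejected = []
    for rep in range(8):
        rng = np.random.default_rng(900 + rep)
        obs_alt = simulate_lme_dataset(rng, n_patients=60, n_obs=15,
                                       sd_resid=0.4)
        extra = ((obs_alt["diagnosis"] == "OpC") * -0.5
                 * obs_alt["t_day"]).to_numpy()
        obs_alt = obs_alt.assign(response=obs_alt["response"] + extra)
        obs_alt.attrs["metric"] = "quadratic"
        rejected.append(
            sivar.test_time_diagnosis_interaction(obs_alt)["p_value"] < 0.05)
    assert np.mean(rejected) >= 0.85


# ---------------------------------------------------------------------------
# Tukey HSD and unit conversion
# ---------------------------------------------------------------------------

def test_tukey_emits_15_comparisons_for_6_groups():
    rng = np.random.default_rng(13)
    obs = simulate_lme_dataset(rng, n_patients=36, n_obs=10)
    res = sivar.fit_lme_quadratic(obs)
    tk = res.tukey_hsd()
    assert len(tk) == 15
    assert tk["comparison"].is_unique
    assert tk["p_adj"].between(0, 1).all()


def test_tukey_single_step_dominance():
    rng = np.random.default_rng(14)
    obs = simulate_lme_dataset(rng, n_patients=36, n_obs=10)
    tk = sivar.fit_lme_quadratic(obs).tukey_hsd()
    assert (tk["p_adj"] >= tk["p_raw"] - 1e-12).all()
    bonf = np.minimum(1.0, 15 * tk["p_raw"])
    assert (tk["p_adj"] <= bonf + 0.02).all()


def test_tukey_no_false_positives_under_equal_groups():
    alarms = []
    for rep in range(10):
        rng = np.random.default_rng(400 + rep)
        obs = simulate_lme_dataset(rng, n_patients=48, n_obs=10)
        tk = sivar.fit_lme_quadratic(obs).tukey_hsd()
        alarms.append(tk["p_adj"].min() <= 0.05)
    assert np.mean(alarms) <= 0.1  # familywise control


def test_tukey_estimates_are_coefficient_differences():
    rng = np.random.default_rng(15)
    obs = simulate_lme_dataset(rng, n_patients=36, n_obs=10)
    res = sivar.fit_lme_quadratic(obs)
    tk = res.tukey_hsd()
    for _, row in tk.iterrows():
        expect = res.fe_params[row["group_1"]] - res.fe_params[row["group_2"]]
        assert row["estimate"] == pytest.approx(expect, abs=1e-12)


def test_time_coefficient_per_day_conversion():
    assert sivar.time_coefficient_per_day(-0.00008571) == pytest.approx(
        -0.1234224, abs=1e-10)
    assert round(sivar.time_coefficient_per_day(-0.0001257), 4) == -0.1810
    assert sivar.time_coefficient_per_day(0.0) == 0.0
    assert MINUTES_PER_DAY == 1440.0
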