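import numpy as np
import pytest

import sivar


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient cohort used by most model-fitting tests."""
    cfg = sivar.CohortConfig(n_patients_per_group=10, seed=1)
    return sivar.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_model(small_cohort):
    return sivar.TransitionKDE.from_cohort(small_cohort).fit()


@pytest.fixture(scope="session")
def null_percentiles(fitted_model):
    """PIT records of a 10,000-transition cohort sampled from the model."""
    null = sivar.sample_null_cohort(fitted_model, n_patients=100,
                                    horizon_hours=101, seed=11)
    return null, sivar.percentile_table(fitted_model, null)


@pytest.fixture(scope="session")
def tiny_model():
    """Three-centre transition model with known structure."""
    pairs = [
        sivar.TransitionPair(si_from=1.0, si_to=1.2),
        sivar.TransitionPair(si_from=2.0, si_to=1.8),
        sivar.TransitionPair(si_from=4.0, si_to=4.5),
    ]
    return sivar.fit_stochastic_model(pairs)


def simulate_lme_dataset(rng, n_patients=120, n_obs=20, beta_groups=None,
                         beta_t_per_day=-0.18, sd_intercept=0.5,
                         sd_slope=0.05, sd_resid=1.0, max_t_day=5.5):
    """Direct simulation from the cell-means LME (continuous response).

    Returns an observations frame shaped like build_observations output
    with attrs['metric'] = 'quadratic'.
    """
    import pandas as pd

    labels = sivar.GROUP_LABELS
    if beta_groups is None:
        beta_groups = {g: -0.7 for g in labels}
    rows = []
    for i in range(n_patients):
        g = labels[i % 6]
        b0 = rng.normal(0, sd_intercept)
        b1 = rng.normal(0, sd_slope)
        t = np.sort(rng.uniform(0, max_t_day, size=n_obs))
        y = (beta_groups[g] + beta_t_per_day * t + b0 + b1 * t
             + rng.normal(0, sd_resid, size=n_obs))
        rows.append(pd.DataFrame({
            "patient_id": f"p{i:04d}", "diagnosis": g,
            "time_min": t * 1440.0, "t_day": t, "response": y}))
    obs = __import__("pandas").concat(rows, ignore_index=True)
    obs.attrs["metric"] = "quadratic"
    return obs


def simulate_glmm_dataset(rng, n_patients=150, n_obs=24, beta_groups=None,
                          beta_t_per_day=-0.12, sd_intercept=0.6,
                          sd_slope=0.05, max_t_day=5.5):
    """Direct simulation from the logistic GLMM (binary response)."""
    import pandas as pd
    from scipy.special import expit

    labels = sivar.GROUP_LABELS
    if beta_groups is None:
        beta_groups = {g: -2.0 for g in labels}
    rows = []
    for i in range(n_patients):
        g = labels[i % 6]
        b0 = rng.normal(0, sd_intercept)
        b1 = rng.normal(0, sd_slope)
        t = np.sort(rng.uniform(0, max_t_day, size=n_obs))
        eta = beta_groups[g] + beta_t_per_day * t + b0 + b1 * t
        y = (rng.random(n_obs) < expit(eta)).astype(float)
        rows.append(pd.DataFrame({
            "patient_id": f"p{i:04d}", "diagnosis": g,
            "time_min": t * 1440.0, "t_day": t, "response": y}))
    obs = pd.concat(rows, ignore_index=True)
    obs.attrs["metric"] = "one_sided"
    return obs
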