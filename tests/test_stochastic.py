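import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import sivar
from sivar.errors import FittingError, ValidationError
from sivar.stochastic import TransitionPair


def test_transition_counts_per_trajectory():
    cfg = sivar.CohortConfig(n_patients_per_group=1, seed=0,
                             allow_short_stays=True,
                             los_hours_log_mean=np.log(30.0))
    cohort = sivar.generate_cohort(cfg)
    pairs = sivar.extract_transitions(cohort)
    assert len(pairs) == cohort.n_hours_total - len(cohort)
    per_patient = {}
    for p in pairs:
        per_patient[p.patient_id] = per_patient.get(p.patient_id, 0) + 1
    for traj in cohort.trajectories:
        assert per_patient[traj.patient_id] == traj.n_hours - 1


def test_transition_count_brute_force(small_cohort):
    pairs = sivar.extract_transitions(small_cohort)
    brute = sum(len(t.si_values) - 1 for t in small_cohort.trajectories)
    assert len(pairs) == brute
    # no pair spans patients: every (from, to) is consecutive in one series
    assert all(p.si_from > 0 and p.si_to > 0 for p in pairs)


def test_fit_requires_two_pairs():
    with pytest.raises(FittingError):
        sivar.fit_stochastic_model([TransitionPair(1.0, 2.0)])


def test_nonpositive_si_rejected():
    with pytest.raises(ValidationError):
        TransitionPair(si_from=-1.0, si_to=2.0)


def test_degenerate_identical_pairs_get_fallback_bandwidth():
    pairs = [TransitionPair(2.0, 2.0), TransitionPair(2.0, 2.0)]
    model = sivar.fit_stochastic_model(pairs)
    assert np.all(model.h_u > 0) and np.all(model.h_v > 0)
    # CDF still proper
    assert model.conditional_cdf(2.0, 1e-6) < 1e-6
    assert model.conditional_cdf(2.0, 1e6) > 1 - 1e-6


def test_fit_order_invariance(small_cohort):
    pairs = sivar.extract_transitions(small_cohort)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(pairs))
    a = sivar.fit_stochastic_model(pairs)
    b = sivar.fit_stochastic_model([pairs[i] for i in perm])
    x = np.exp(rng.normal(1.0, 0.5, size=20))
    y = np.exp(rng.normal(1.0, 0.5, size=20))
    np.testing.assert_allclose(a.conditional_cdf(x, y),
                               b.conditional_cdf(x, y), atol=1e-12)


def test_single_centre_median_is_half():
    # duplicate centre => one effective component; CDF at its si_to mean = 0.5
    pairs = [TransitionPair(3.0, 2.5), TransitionPair(3.0, 2.5)]
    model = sivar.fit_stochastic_model(pairs)
    assert model.conditional_cdf(3.0, 2.5) == pytest.approx(0.5, abs=1e-12)


def test_cdf_tail_limits(fitted_model):
    assert fitted_model.conditional_cdf(3.0, 1e-9) <= 1e-6
    assert fitted_model.conditional_cdf(3.0, 1e9) >= 1 - 1e-6


def test_cdf_matches_quadrature_oracle(fitted_model):
    rng = np.random.default_rng(4)
    for _ in range(15):
        x = float(np.exp(rng.normal(1.0, 0.6)))
        y = float(np.exp(rng.normal(1.0, 0.6)))
        num, err = integrate.quad(
            lambda s: fitted_model.conditional_pdf(x, float(s)),
            1e-12, y, limit=400)
        assert abs(fitted_model.conditional_cdf(x, y) - num) < 1e-6 + err


@pytest.mark.parametrize("coordinates", ["change", "level"])
def test_joint_density_integrates_to_one(coordinates):
    pairs = [
        TransitionPair(si_from=1.0, si_to=1.2),
        TransitionPair(si_from=2.0, si_to=1.8),
        TransitionPair(si_from=4.0, si_to=4.5),
    ]
    m = sivar.TransitionKDE(pairs).fit(coordinates=coordinates)

    def marginal_u(lu):
        z = (lu - m.u) / m.h_u
        return float(np.mean(np.exp(-0.5 * z * z) / (m.h_u * np.sqrt(2 * np.pi))))

    def joint(lu, ly):
        # marginal of current level x conditional of the next (in log y)
        y = np.exp(ly)
        return marginal_u(lu) * m.conditional_pdf(float(np.exp(lu)), float(y)) * y

    lo_u = m.u.min() - 8 * m.h_u.max()
    hi_u = m.u.max() + 8 * m.h_u.max()
    span = abs(m.v - m.u).max() + 8 * (m.h_v.max() + m.h_u.max())
    total, err = integrate.dblquad(lambda lv, lu: joint(lu, lv),
                                   lo_u, hi_u, m.u.min() - span,
                                   m.u.max() + span, epsabs=1e-6)
    assert abs(total - 1.0) < 1e-3


def test_quantile_inverts_cdf(fitted_model):
    rng = np.random.default_rng(6)
    for _ in range(10):
        x = float(np.exp(rng.normal(1.0, 0.6)))
        q = float(rng.uniform(0.02, 0.98))
        y = fitted_model.conditional_quantile(x, q)
        assert fitted_model.conditional_cdf(x, y) == pytest.approx(q, abs=1e-6)


def test_quantiles_monotone_in_q(fitted_model):
    q25 = fitted_model.conditional_quantile(2.0, 0.25)
    q50 = fitted_model.conditional_quantile(2.0, 0.5)
    q75 = fitted_model.conditional_quantile(2.0, 0.75)
    assert q25 <= q50 <= q75


def test_quantile_matches_grid_inversion(tiny_model):
    x, q = 2.0, 0.8
    grid = np.exp(np.linspace(np.log(1e-3), np.log(1e3), 100_000))
    cdf = tiny_model.conditional_cdf(np.full_like(grid, x), grid)
    y_grid = grid[np.searchsorted(cdf, q)]
    y = tiny_model.conditional_quantile(x, q)
    spacing = np.log(grid[1]) - np.log(grid[0])
    assert abs(np.log(y) - np.log(y_grid)) <= 2 * spacing


def test_quantile_rejects_bad_q(fitted_model):
    with pytest.raises(ValidationError):
        fitted_model.conditional_quantile(2.0, 0.0)
    with pytest.raises(ValidationError):
        fitted_model.conditional_quantile(2.0, 1.2)


def test_cdf_rejects_nonpositive(fitted_model):
    with pytest.raises(ValidationError):
        fitted_model.conditional_cdf(-1.0, 2.0)
    with pytest.raises(ValidationError):
        fitted_model.conditional_cdf(2.0, 0.0)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(x=st.floats(0.05, 50.0),
       y1=st.floats(0.05, 50.0), y2=st.floats(0.05, 50.0))
def test_cdf_monotone_in_si_to(tiny_model, x, y1, y2):
    lo, hi = sorted([y1, y2])
    assert (tiny_model.conditional_cdf(x, lo)
            <= tiny_model.conditional_cdf(x, hi) + 1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(x=st.floats(0.01, 100.0))
def test_weights_sum_to_one(fitted_model, x):
    w = fitted_model.weights(x)
    assert np.all(w >= 0)
    assert abs(w.sum() - 1.0) < 1e-9


def test_sampler_matches_cdf_ks(small_cohort):
    # a leaner model keeps the 1e5-draw comparison quick
    sub = sivar.CohortTable(small_cohort.trajectories[:12])
    model = sivar.TransitionKDE.from_cohort(sub).fit()
    rng = np.random.default_rng(21)
    x = 3.0
    draws = model.sample_next_many(np.full(100_000, x), rng)
    assert np.all(draws > 0)
    cdf_vals = model.conditional_cdf(np.full_like(draws, x), draws)
    ks = stats.kstest(cdf_vals, "uniform").statistic
    assert ks < 0.01


def test_sampler_reproducible(fitted_model):
    a = fitted_model.sample_next(2.0, np.random.default_rng(77))
    b = fitted_model.sample_next(2.0, np.random.default_rng(77))
    assert a == b


def test_serialization_roundtrip(tmp_path, fitted_model):
    path = tmp_path / "model.csv"
    fitted_model.to_csv(path)
    back = sivar.TransitionKDEResults.read_csv(path)
    assert back.n_transitions == fitted_model.n_transitions
    assert back.bandwidth_rule == fitted_model.bandwidth_rule
    rng = np.random.default_rng(3)
    x = np.exp(rng.normal(1, 0.5, 10))
    y = np.exp(rng.normal(1, 0.5, 10))
    np.testing.assert_allclose(back.conditional_cdf(x, y),
                               fitted_model.conditional_cdf(x, y), atol=1e-9)


def test_knn_bandwidth_rule_fits_and_calibrates(small_cohort):
    model = sivar.TransitionKDE.from_cohort(small_cohort).fit(
        bandwidth_rule="knn")
    assert model.n_transitions > 0
    assert len(np.unique(model.h_v)) > 1  # genuinely adaptive
    # still a proper conditional CDF
    assert model.conditional_cdf(2.0, 1e-9) < 1e-6
    assert model.conditional_cdf(2.0, 1e9) > 1 - 1e-6
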