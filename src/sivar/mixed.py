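"""Mixed-effects inference on the variability penalties.

The inferential model regresses a per-hour response derived from the PIT
percentile p on time of stay (minutes, continuous) and diagnosis group
(6 levels, cell-means coding: one coefficient per group, no intercept),
with a per-patient random intercept and random slope in time:

    y_ij = sum_k beta_k d_k(i) + beta_T t_ij + b_0i + b_1i t_ij + e_ij

* quadratic route: y = logit(4 (p - 0.5)^2) (the squared deviation rescaled
  from [0, 0.25] onto (0, 1), then logit-mapped to the real line; clamped at
  eps before the logit) — fitted as an LME by REML.
* one-sided route: y = 1{p > 0.9} — fitted as a logistic-binomial GLMM by
  Laplace approximation.

Supporting tests: LR tests for the random structure (ML refits), a check of
AR(1) within-patient residual correlation, a joint test of Time x Diagnosis
interaction, and Tukey-HSD single-step pairwise contrasts of the six group
coefficients.

Observations are restricted to the first 8,000 minutes of stay (about the
first 5.5 days), the roughly linear region of the variability-time
relation.  Time enters the optimiser in days and the slope is reported on
both per-minute and per-day scales.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit
from scipy.stats import qmc

from .cohort import GROUP_LABELS
from .errors import FittingError, ValidationError
from .glmm import LogisticGLMM, LogisticGLMMResults, lr_test as _glmm_lr_test

MINUTES_PER_DAY = 1440.0
DEFAULT_TIME_CAP_MIN = 8000.0


# ---------------------------------------------------------------------------
# observation construction
# ---------------------------------------------------------------------------

def build_observations(records: pd.DataFrame, metric: str,
                       time_cap_min: float = DEFAULT_TIME_CAP_MIN,
                       eps: float = 1e-6,
                       threshold: float = 0.9) -> pd.DataFrame:
    """Per-hour model observations from (segmented) percentile records.

    Columns of the result: ``patient_id, diagnosis, time_min, t_day,
    response``; ``attrs['metric']`` records which response was built and
    ``attrs['n_dropped_time_cap']`` how many records exceeded the time cap.
    """
    if metric not in ("quadratic", "one_sided"):
        raise ValidationError("metric must be 'quadratic' or 'one_sided'")
    keep = records["time_min"].to_numpy(dtype=float) <= time_cap_min
    dropped = int((~keep).sum())
    df = records.loc[keep, ["patient_id", "diagnosis", "time_min"]].copy()
    p = records.loc[keep, "percentile"].to_numpy(dtype=float)
    if metric == "quadratic":
        dev = np.clip(4.0 * (p - 0.5) ** 2, eps, 1.0 - eps)
        df["response"] = logit(dev)
    else:
        df["response"] = (p > threshold).astype(float)
    df["t_day"] = df["time_min"].to_numpy(dtype=float) / MINUTES_PER_DAY
    df = df.reset_index(drop=True)
    df.attrs["metric"] = metric
    df.attrs["n_dropped_time_cap"] = dropped
    return df


def _design(obs: pd.DataFrame, interaction: bool = False
            ) -> tuple[np.ndarray, list[str]]:
    """Cell-means design: 6 group indicators plus time (or per-group time)."""
    labels = [g for g in GROUP_LABELS if g in set(obs["diagnosis"])]
    cols, names = [], []
    diag = obs["diagnosis"].to_numpy()
    t = obs["t_day"].to_numpy(dtype=float)
    for g in labels:
        cols.append((diag == g).astype(float))
        names.append(g)
    if interaction:
        for g in labels:
            cols.append(t * (diag == g))
            names.append(f"t_day:{g}")
    else:
        cols.append(t)
        names.append("t_day")
    return np.column_stack(cols), names


def _group_labels(names: list[str]) -> list[str]:
    return [n for n in names if n in GROUP_LABELS]


# ---------------------------------------------------------------------------
# LME for the (logit-transformed) quadratic penalty
# ---------------------------------------------------------------------------

class VariabilityLME:
    """LME of the logit-transformed quadratic deviation (model above)."""

    def __init__(self, obs: pd.DataFrame, interaction: bool = False):
        if obs.attrs.get("metric", "quadratic") != "quadratic":
            raise ValidationError("VariabilityLME expects the quadratic response")
        counts = obs.groupby("diagnosis")["patient_id"].nunique()
        if (counts < 2).any():
            raise FittingError(
                f"need >= 2 patients per group, got {counts.to_dict()}")
        if not np.all(np.isfinite(obs["response"])):
            raise ValidationError("responses must be finite")
        self.obs = obs
        self.exog, self.exog_names = _design(obs, interaction=interaction)
        self.endog = obs["response"].to_numpy(dtype=float)
        self.groups = obs["patient_id"].to_numpy()
        t = obs["t_day"].to_numpy(dtype=float)
        self.exog_re = np.column_stack([np.ones(len(t)), t])
        self.interaction = interaction

    def fit(self, reml: bool = True, random_structure: str = "full"
            ) -> "VariabilityLMEResults":
        """REML (default) or ML fit; random_structure in
        {"full", "intercept", "none"}."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if random_structure == "none":
                ols = sm.OLS(self.endog, self.exog).fit()
                return VariabilityLMEResults(self, ols, reml=False,
                                             random_structure="none")
            exog_re = (self.exog_re if random_structure == "full"
                       else self.exog_re[:, :1])
            model = sm.MixedLM(self.endog, self.exog, groups=self.groups,
                               exog_re=exog_re)
            res = None
            err: Exception | None = None
            # fall back across optimizers; variance estimates on the boundary
            # can leave the default one unconverged or its Hessian singular
            for method in ("lbfgs", "bfgs", "powell", "cg"):
                try:
                    cand = model.fit(reml=reml, method=method)
                except np.linalg.LinAlgError as exc:
                    err = exc
                    continue
                if res is None or (cand.converged and not res.converged) or (
                        cand.converged == res.converged
                        and cand.llf > res.llf + 1e-8):
                    res = cand
                if res.converged:
                    break
            if res is None:
                raise FittingError(f"MixedLM estimation failed: {err}")
        return VariabilityLMEResults(self, res, reml=reml,
                                     random_structure=random_structure)


class VariabilityLMEResults:
    """Coefficients, variance components and tests of a fitted LME."""

    def __init__(self, model: VariabilityLME, sm_results, reml: bool,
                 random_structure: str):
        self.model = model
        self._res = sm_results
        self.reml = reml
        self.random_structure = random_structure
        self.method = "REML" if reml else "ML"
        self.exog_names = model.exog_names

    @property
    def converged(self) -> bool:
        return bool(getattr(self._res, "converged", True))

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def fe_params(self) -> pd.Series:
        params = np.asarray(self._res.params)[: len(self.exog_names)]
        return pd.Series(params, index=self.exog_names)

    @property
    def group_coeffs(self) -> pd.Series:
        return self.fe_params[_group_labels(self.exog_names)]

    @property
    def cov_fe(self) -> pd.DataFrame:
        k = len(self.exog_names)
        cov = np.asarray(self._res.cov_params())[:k, :k]
        return pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names)

    @property
    def cov_groups(self) -> pd.DataFrame:
        labels = _group_labels(self.exog_names)
        return self.cov_fe.loc[labels, labels]

    @property
    def time_per_day(self) -> float:
        return float(self.fe_params["t_day"])

    @property
    def time_per_minute(self) -> float:
        return self.time_per_day / MINUTES_PER_DAY

    @property
    def random_components(self) -> dict:
        if self.random_structure == "none":
            return {"residual_var": float(self._res.scale)
                    if hasattr(self._res, "scale") else float(np.var(self._res.resid))}
        cov_re = np.asarray(self._res.cov_re)
        out = {"var_intercept": float(cov_re[0, 0]),
               "residual_var": float(self._res.scale)}
        if cov_re.shape[0] > 1:
            out["var_slope"] = float(cov_re[1, 1])
            out["cov_intercept_slope"] = float(cov_re[0, 1])
        return out

    def tukey_hsd(self) -> pd.DataFrame:
        return tukey_hsd(self)

    def summary(self) -> str:
        lines = [
            "LME: logit-transformed quadratic penalty "
            f"({self.method}, random: {self.random_structure})",
            f"  patients: {pd.unique(self.model.groups).size}   "
            f"obs: {len(self.model.endog)}   converged: {self.converged}",
            f"  logLik: {self.llf:.3f}",
            "",
            f"  {'term':<16}{'coef':>12}",
        ]
        for name, val in self.fe_params.items():
            lines.append(f"  {name:<16}{val:>12.5f}")
        lines.append(f"  time per minute: {self.time_per_minute:.6g}")
        lines.append(f"  time per day:    {self.time_per_day:.6g}")
        for k, v in self.random_components.items():
            lines.append(f"  {k}: {v:.5g}")
        return "\n".join(lines)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_fe))
        est = self.fe_params.to_numpy()
        z = est / se
        return pd.DataFrame(
            {"term": self.exog_names, "estimate": est, "se": se, "z": z,
             "p_value": 2 * stats.norm.sf(np.abs(z))}
        )


def fit_lme_quadratic(obs: pd.DataFrame, reml: bool = True
                      ) -> VariabilityLMEResults:
    """REML fit of the quadratic-penalty LME (cell means + common slope)."""
    return VariabilityLME(obs).fit(reml=reml)


# ---------------------------------------------------------------------------
# GLMM for the one-sided (exceedance) penalty
# ---------------------------------------------------------------------------

class ExceedanceGLMM:
    """Logistic-binomial GLMM of the per-hour exceedance indicator."""

    def __init__(self, obs: pd.DataFrame, interaction: bool = False):
        if obs.attrs.get("metric", "one_sided") != "one_sided":
            raise ValidationError("ExceedanceGLMM expects the one_sided response")
        y = obs["response"].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise FittingError("both outcome classes must be present")
        self.obs = obs
        self.exog, self.exog_names = _design(obs, interaction=interaction)
        t = obs["t_day"].to_numpy(dtype=float)
        self.exog_re = np.column_stack([np.ones(len(t)), t])
        self.endog = y
        self.groups = obs["patient_id"].to_numpy()
        self.interaction = interaction

    def fit(self, random_structure: str = "full") -> "ExceedanceGLMMResults":
        core = LogisticGLMM(self.endog, self.exog, self.groups,
                            exog_re=self.exog_re,
                            re_structure=random_structure,
                            exog_names=self.exog_names)
        return ExceedanceGLMMResults(self, core.fit())


class ExceedanceGLMMResults:
    """Laplace-GLMM estimates with the same reporting surface as the LME."""

    def __init__(self, model: ExceedanceGLMM, core: LogisticGLMMResults):
        self.model = model
        self._core = core
        self.exog_names = model.exog_names
        self.method = core.method

    @property
    def converged(self) -> bool:
        return self._core.converged

    @property
    def llf(self) -> float:
        return self._core.llf

    @property
    def fe_params(self) -> pd.Series:
        return self._core.fe_params

    @property
    def group_coeffs(self) -> pd.Series:
        return self.fe_params[_group_labels(self.exog_names)]

    @property
    def cov_fe(self) -> pd.DataFrame:
        return self._core.cov_fe

    @property
    def cov_groups(self) -> pd.DataFrame:
        labels = _group_labels(self.exog_names)
        return self.cov_fe.loc[labels, labels]

    @property
    def time_per_day(self) -> float:
        return float(self.fe_params["t_day"])

    @property
    def time_per_minute(self) -> float:
        return self.time_per_day / MINUTES_PER_DAY

    @property
    def random_components(self) -> dict:
        return self._core.vc

    def tukey_hsd(self) -> pd.DataFrame:
        return tukey_hsd(self)

    def summary(self) -> str:
        extra = [f"  time per minute: {self.time_per_minute:.6g}",
                 f"  time per day:    {self.time_per_day:.6g}"]
        return self._core.summary() + "\n" + "\n".join(extra)

    def coef_table(self) -> pd.DataFrame:
        se = self._core.bse_fe.to_numpy()
        est = self.fe_params.to_numpy()
        z = est / se
        return pd.DataFrame(
            {"term": self.exog_names, "estimate": est, "se": se, "z": z,
             "p_value": 2 * stats.norm.sf(np.abs(z))}
        )


def fit_glme_onesided(obs: pd.DataFrame) -> ExceedanceGLMMResults:
    """Laplace fit of the exceedance GLMM (cell means + common slope)."""
    return ExceedanceGLMM(obs).fit()


# ---------------------------------------------------------------------------
# model-selection tests
# ---------------------------------------------------------------------------

def _lme_ml_llf(obs: pd.DataFrame, random_structure: str) -> float:
    res = VariabilityLME(obs).fit(reml=False, random_structure=random_structure)
    return res.llf


def lr_test_random_structure(obs: pd.DataFrame, metric: str | None = None
                             ) -> dict:
    """LR tests for adding a random intercept, then a random slope.

    ML refits are compared (REML log-likelihoods are not comparable across
    fixed-effect-identical but random-effect-different models in this
    nested-variance setting).  The naive chi-square reference is reported
    with a boundary caveat: true null distributions are chi-square mixtures,
    making these p-values conservative.
    """
    metric = metric or obs.attrs.get("metric")
    if metric == "quadratic":
        ll0 = _lme_ml_llf(obs, "none")
        ll1 = _lme_ml_llf(obs, "intercept")
        ll2 = _lme_ml_llf(obs, "full")
        dfs = (1, 2)  # +var(b0); +var(b1) and cov(b0, b1)
    elif metric == "one_sided":
        model = ExceedanceGLMM(obs)
        fits = {}
        for struct in ("none", "intercept", "full"):
            core = LogisticGLMM(model.endog, model.exog, model.groups,
                                exog_re=model.exog_re, re_structure=struct,
                                exog_names=model.exog_names)
            fits[struct] = core.fit()
        ll0, ll1, ll2 = (fits[s].llf for s in ("none", "intercept", "full"))
        dfs = (1, 2)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    out = {}
    for name, (lla, llb, df) in {
        "random_intercept": (ll0, ll1, dfs[0]),
        "random_slope": (ll1, ll2, dfs[1]),
    }.items():
        stat = max(0.0, 2.0 * (llb - lla))
        out[name] = {"statistic": stat, "df": df,
                     "p_value": float(stats.chi2.sf(stat, df))}
    out["estimation"] = "ML" if metric == "quadratic" else "Laplace"
    out["boundary_note"] = ("variance parameters lie on the null boundary; "
                            "naive chi-square p-values are conservative")
    return out


def _pooled_lag1(resids_by_patient: list[np.ndarray]) -> tuple[float, int]:
    """Pooled lag-1 autocorrelation over within-patient residual series."""
    num = sq_sum = 0.0
    n_pairs = n_obs = 0
    for e in resids_by_patient:
        num += float(np.dot(e[:-1], e[1:]))
        n_pairs += len(e) - 1
        sq_sum += float(np.dot(e, e))
        n_obs += len(e)
    if n_pairs < 2:
        raise FittingError("not enough consecutive records for the AR(1) check")
    return num / (n_pairs * (sq_sum / n_obs)), n_pairs


def test_ar1_necessity(obs: pd.DataFrame,
                       lme_results: VariabilityLMEResults | None = None,
                       n_boot: int = 300, seed: int = 0) -> dict:
    """Check whether within-patient residuals need an AR(1) term.

    The LME backend cannot estimate an AR(1) residual process jointly, so
    the documented fallback is a pooled lag-1 autocorrelation
    (Box-Pierce/Ljung-Box-type) of the conditional residuals (fixed effects
    and BLUP random effects removed).  Removing per-patient BLUPs induces a
    small negative autocorrelation even under independent errors, so the
    null distribution of the statistic is calibrated by a parametric
    bootstrap under the fitted model: variance components are held at their
    estimates, responses are resimulated with independent errors, fixed
    effects are re-estimated by GLS and random effects re-BLUPed — all
    linear operations.  Patients with fewer than 3 observations are
    excluded from the statistic.
    """
    res = lme_results if lme_results is not None else fit_lme_quadratic(obs)
    fe = res.fe_params.to_numpy()
    df = res.model.obs
    X = res.model.exog
    y = res.model.endog
    t = df["t_day"].to_numpy(dtype=float)
    resid = y - X @ fe
    re = res._res.random_effects if res.random_structure != "none" else {}
    # per-patient pieces, time-ordered
    per_patient = []
    excluded = []
    for pid, g in df.groupby("patient_id", sort=False):
        order = g.sort_values("time_min").index.to_numpy()
        if len(order) < 3:
            excluded.append(pid)
            continue
        Z = np.column_stack([np.ones(len(order)), t[order]])
        if res.random_structure == "intercept":
            Z = Z[:, :1]
        per_patient.append((pid, order, Z))
    if res.random_structure != "none":
        for pid, order, Z in per_patient:
            resid[order] -= Z[:, : len(np.atleast_1d(re[pid]))] @ np.atleast_1d(
                re[pid])
    obs_resids = [resid[order] for _, order, _ in per_patient]
    r1_obs, n_pairs = _pooled_lag1(obs_resids)

    # parametric bootstrap null of the statistic
    rc = res.random_components
    sigma2 = rc["residual_var"]
    q = 2 if "var_slope" in rc else (1 if "var_intercept" in rc else 0)
    if q == 2:
        Sigma = np.array([[rc["var_intercept"], rc["cov_intercept_slope"]],
                          [rc["cov_intercept_slope"], rc["var_slope"]]])
    elif q == 1:
        Sigma = np.array([[rc["var_intercept"]]])
    else:
        Sigma = np.zeros((0, 0))
    # precompute GLS pieces per patient with fixed variance components
    pre = []
    M = np.zeros((X.shape[1], X.shape[1]))
    for pid, order, Z in per_patient:
        Zq = Z[:, :q] if q else np.zeros((len(order), 0))
        V = sigma2 * np.eye(len(order))
        if q:
            V = V + Zq @ Sigma @ Zq.T
        Vinv = np.linalg.inv(V)
        Xi = X[order]
        XtVinv = Xi.T @ Vinv
        blup = Sigma @ Zq.T @ Vinv if q else None
        pre.append((order, Xi, Zq, XtVinv, blup))
        M += XtVinv @ Xi
    Minv = np.linalg.inv(M)
    rng = np.random.default_rng(seed)
    # jitter the Cholesky if the RE covariance sits on the boundary
    if q:
        Lre = np.linalg.cholesky(Sigma + 1e-12 * np.eye(q))
    r1_null = np.empty(n_boot)
    for b in range(n_boot):
        ys = []
        for order, Xi, Zq, _, _ in pre:
            mean = Xi @ fe
            if q:
                mean = mean + Zq @ (Lre @ rng.standard_normal(q))
            ys.append(mean + rng.normal(0, np.sqrt(sigma2), len(order)))
        rhs = sum(XtVinv @ yi for (_, _, _, XtVinv, _), yi in zip(pre, ys))
        beta_s = Minv @ rhs
        boots = []
        for (order, Xi, Zq, _, blup), yi in zip(pre, ys):
            e = yi - Xi @ beta_s
            if q:
                e = e - Zq @ (blup @ e)
            boots.append(e)
        r1_null[b], _ = _pooled_lag1(boots)
    lo = (1 + np.sum(r1_null <= r1_obs)) / (n_boot + 1)
    hi = (1 + np.sum(r1_null >= r1_obs)) / (n_boot + 1)
    return {
        "p_value": float(min(1.0, 2 * min(lo, hi))),
        "statistic": float(r1_obs),
        "lag1_autocorr": float(r1_obs),
        "null_mean": float(r1_null.mean()),
        "n_pairs": int(n_pairs),
        "n_boot": int(n_boot),
        "excluded_patients": excluded,
        "method": "pooled lag-1 autocorrelation of conditional residuals, "
                  "parametric-bootstrap calibrated (AR(1) not jointly "
                  "estimable with the LME backend)",
    }


def test_time_diagnosis_interaction(obs: pd.DataFrame,
                                    metric: str | None = None) -> dict:
    """Joint 5-df LR test of Time x Diagnosis fixed-effect interactions.

    Compares the cell-means model with a common time slope against one with
    a separate slope per diagnosis group; non-rejection justifies dropping
    the interaction, as in the headline model.
    """
    metric = metric or obs.attrs.get("metric")
    if metric == "quadratic":
        ll_red = VariabilityLME(obs, interaction=False).fit(reml=False).llf
        ll_full = VariabilityLME(obs, interaction=True).fit(reml=False).llf
    elif metric == "one_sided":
        red = ExceedanceGLMM(obs, interaction=False)
        full = ExceedanceGLMM(obs, interaction=True)
        ll_red = red.fit().llf
        ll_full = full.fit().llf
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    n_groups = obs["diagnosis"].nunique()
    df = n_groups - 1
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    return {"statistic": stat, "df": df,
            "p_value": float(stats.chi2.sf(stat, df))}


# ---------------------------------------------------------------------------
# Tukey HSD post-hoc contrasts
# ---------------------------------------------------------------------------

def tukey_hsd(result, n_qmc_log2: int = 15) -> pd.DataFrame:
    """All pairwise group contrasts with single-step (Tukey-HSD) adjustment.

    Adjusted p-values are computed from the joint normal distribution of the
    standardised contrasts: p_adj(k) = P(max_m |Z_m| >= |z_k|), evaluated by
    deterministic scrambled-Sobol quasi-Monte-Carlo on the coefficient
    normal (2^*n_qmc_log2* points, fixed scramble seed).  Six groups yield
    15 comparisons.
    """
    coeffs = result.group_coeffs
    labels = list(coeffs.index)
    cov = result.cov_groups.to_numpy(dtype=float)
    k = len(labels)
    if k < 2:
        raise ValidationError("need at least two group coefficients")
    pairs = [(j, i) for i in range(k) for j in range(i + 1, k)]
    C = np.zeros((len(pairs), k))
    for m, (j, i) in enumerate(pairs):
        C[m, j] = 1.0
        C[m, i] = -1.0
    est = C @ coeffs.to_numpy()
    var = np.einsum("mi,ij,mj->m", C, cov, C)
    if np.any(var <= 0):
        raise FittingError("singular coefficient covariance in tukey_hsd")
    se = np.sqrt(var)
    z = est / se
    p_raw = 2 * stats.norm.sf(np.abs(z))
    # joint-normal max-|Z| reference via deterministic QMC
    jitter = 1e-12 * max(np.trace(cov) / k, 1e-30)
    L = np.linalg.cholesky(cov + jitter * np.eye(k))
    sob = qmc.Sobol(d=k, scramble=True, seed=20130221)
    u = sob.random_base2(m=n_qmc_log2)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    draws = stats.norm.ppf(u) @ L.T
    zmax = np.max(np.abs(draws @ C.T) / se, axis=1)
    p_adj = np.array([np.mean(zmax >= abs(zk)) for zk in z])
    p_adj = np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)
    rows = []
    for m, (j, i) in enumerate(pairs):
        rows.append(
            {"comparison": f"{labels[j]} - {labels[i]}",
             "group_1": labels[j], "group_2": labels[i],
             "estimate": est[m], "se": se[m], "z": z[m],
             "p_raw": p_raw[m], "p_adj": p_adj[m]}
        )
    return pd.DataFrame(rows)


def time_coefficient_per_day(result) -> float:
    """Per-day time slope: the per-minute coefficient times 1440."""
    if isinstance(result, (int, float, np.floating)):
        return float(result) * MINUTES_PER_DAY
    return result.time_per_minute * MINUTES_PER_DAY
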