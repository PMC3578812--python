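"""Logistic generalized linear mixed model via the Laplace approximation.

Fits Bernoulli responses with logit link, fixed effects X*beta and per-group
random effects Z*b_g, b_g ~ N(0, Sigma), by maximising the Laplace
approximation to the marginal log-likelihood:

    log L(beta, Sigma) ~= pll(b_hat) - (G/2) log det Sigma
                          - (1/2) sum_g log det H_g,

where pll is the penalised log-likelihood, b_hat its per-group mode (found
by a Newton iteration vectorised across groups) and H_g the per-group
negative Hessian of pll at the mode.  This is the same approximation lme4's
``glmer`` uses at its default nAGQ = 1.

Random-effect structures: "full" (intercept + slope with correlation,
q = 2), "intercept" (q = 1) and "none" (plain GLM; the log-likelihoods are
nested and comparable, enabling LR tests of the random structure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .errors import FittingError, ValidationError

_LOG2PI = np.log(2.0 * np.pi)


def _softplus(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


class LogisticGLMM:
    """Logit-link Bernoulli mixed model with per-group random effects.

    Parameters
    ----------
    endog : (n,) 0/1 array
    exog : (n, p) fixed-effects design
    groups : (n,) group labels (any hashable; factorised internally)
    exog_re : (n, q) random-effects design within group (q = 1 or 2);
        defaults to an intercept column.
    re_structure : {"full", "intercept", "none"}
        "full" uses all columns of exog_re with a free correlation;
        "intercept" keeps only the first column; "none" drops the random
        effects entirely (plain logistic GLM).
    exog_names : optional fixed-effect column names for reporting.
    """

    def __init__(self, endog, exog, groups, exog_re=None,
                 re_structure: str = "full",
                 exog_names: list[str] | None = None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValidationError("endog must be binary 0/1")
        if len(y) != len(X):
            raise ValidationError("endog and exog lengths differ")
        codes, uniques = pd.factorize(np.asarray(groups), sort=False)
        if re_structure not in ("full", "intercept", "none"):
            raise ValidationError(f"unknown re_structure {re_structure!r}")
        if exog_re is None:
            Z = np.ones((len(y), 1))
        else:
            Z = np.asarray(exog_re, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
        if re_structure == "intercept":
            Z = Z[:, :1]
        self.y, self.X, self.Z = y, X, Z
        self.group_codes = codes
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.re_structure = re_structure
        self.q = 0 if re_structure == "none" else Z.shape[1]
        if self.q > 2:
            raise ValidationError("at most 2 random-effect columns supported")
        self.k_fe = X.shape[1]
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.k_fe)])
        self._b_warm = np.zeros((self.n_groups, max(self.q, 1)))

    # -- variance parameterisation ------------------------------------------

    @property
    def k_vc(self) -> int:
        return {0: 0, 1: 1, 2: 3}[self.q]

    def _sigma(self, theta: np.ndarray) -> np.ndarray:
        if self.q == 1:
            return np.array([[np.exp(2.0 * theta[0])]])
        s0, s1 = np.exp(theta[0]), np.exp(theta[1])
        rho = np.tanh(theta[2])
        return np.array([[s0 * s0, rho * s0 * s1],
                         [rho * s0 * s1, s1 * s1]])

    # -- Laplace objective ---------------------------------------------------

    def _penalised_ll(self, eta: np.ndarray, b: np.ndarray,
                      sigma_inv: np.ndarray) -> float:
        ll = float(np.dot(self.y, eta) - _softplus(eta).sum())
        pen = 0.5 * float(np.einsum("gi,ij,gj->", b, sigma_inv, b))
        return ll - pen

    def _inner_mode(self, beta: np.ndarray, sigma_inv: np.ndarray,
                    b0: np.ndarray, tol: float = 1e-10, maxiter: int = 100
                    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Per-group Newton for the mode of the penalised log-likelihood.

        Returns (b_hat, pll at mode, per-group negative Hessians (G,q,q)).
        """
        y, Z, g = self.y, self.Z, self.group_codes
        G, q = self.n_groups, self.q
        Xb = self.X @ beta
        b = b0.copy()
        eta = Xb + np.einsum("nj,nj->n", Z, b[g])
        pll = self._penalised_ll(eta, b, sigma_inv)
        H = np.empty((G, q, q))
        for _ in range(maxiter):
            mu = expit(eta)
            resid = y - mu
            w = mu * (1.0 - mu)
            grad = np.stack(
                [np.bincount(g, Z[:, j] * resid, minlength=G) for j in range(q)],
                axis=1,
            ) - b @ sigma_inv
            for i in range(q):
                for j in range(i, q):
                    H[:, i, j] = np.bincount(g, w * Z[:, i] * Z[:, j],
                                             minlength=G) + sigma_inv[i, j]
                    H[:, j, i] = H[:, i, j]
            if q == 1:
                step = grad / H[:, 0, 0, None]
            else:
                det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
                step = np.empty_like(grad)
                step[:, 0] = (H[:, 1, 1] * grad[:, 0] - H[:, 0, 1] * grad[:, 1]) / det
                step[:, 1] = (H[:, 0, 0] * grad[:, 1] - H[:, 0, 1] * grad[:, 0]) / det
            # damped update
            lam = 1.0
            for _half in range(30):
                b_new = b + lam * step
                eta_new = Xb + np.einsum("nj,nj->n", Z, b_new[g])
                pll_new = self._penalised_ll(eta_new, b_new, sigma_inv)
                if pll_new >= pll - 1e-12:
                    break
                lam *= 0.5
            improved = pll_new - pll
            b, eta, pll = b_new, eta_new, pll_new
            if np.max(np.abs(grad)) < tol and improved < 1e-10:
                break
        # refresh Hessian at the final mode
        mu = expit(eta)
        w = mu * (1.0 - mu)
        for i in range(q):
            for j in range(i, q):
                H[:, i, j] = np.bincount(g, w * Z[:, i] * Z[:, j],
                                         minlength=G) + sigma_inv[i, j]
                H[:, j, i] = H[:, i, j]
        return b, pll, H

    def loglike(self, params: np.ndarray) -> float:
        """Laplace-approximated marginal log-likelihood at *params*."""
        beta = params[: self.k_fe]
        if self.q == 0:
            eta = self.X @ beta
            return float(np.dot(self.y, eta) - _softplus(eta).sum())
        theta = params[self.k_fe:]
        sigma = self._sigma(theta)
        sign, logdet_sigma = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf
        sigma_inv = np.linalg.inv(sigma)
        b, pll, H = self._inner_mode(beta, sigma_inv, self._b_warm)
        self._b_warm = b
        if self.q == 1:
            logdet_H = np.log(H[:, 0, 0])
        else:
            logdet_H = np.log(H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2)
        return pll - 0.5 * self.n_groups * logdet_sigma - 0.5 * float(logdet_H.sum())

    # -- fitting ---------------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        import statsmodels.api as sm

        glm = sm.GLM(self.y, self.X, family=sm.families.Binomial())
        try:
            beta0 = glm.fit(maxiter=200).params
        except Exception:
            beta0 = np.zeros(self.k_fe)
        beta0 = np.clip(beta0, -10, 10)
        if self.q == 0:
            return np.asarray(beta0, float)
        theta0 = {1: [np.log(0.5)], 2: [np.log(0.5), np.log(0.5), 0.0]}[self.q]
        return np.concatenate([beta0, theta0])

    def fit(self, start_params: np.ndarray | None = None, maxiter: int = 500
            ) -> "LogisticGLMMResults":
        x0 = self._start_params() if start_params is None else np.asarray(
            start_params, float)
        bounds = [(None, None)] * self.k_fe
        if self.q >= 1:
            bounds += [(-6.0, 3.0)]
        if self.q == 2:
            bounds += [(-6.0, 3.0), (-4.0, 4.0)]

        def neg(params: np.ndarray) -> float:
            val = self.loglike(params)
            return np.inf if not np.isfinite(val) else -val

        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-11,
                                         "gtol": 1e-7})
        params = res.x
        llf = -res.fun
        separation = bool(np.max(np.abs(params[: self.k_fe])) > 30)
        cov, cov_ok = self._param_cov(params)
        converged = bool(res.success) and cov_ok and not separation
        return LogisticGLMMResults(self, params, llf, cov,
                                   converged=converged,
                                   separation=separation)

    def _param_cov(self, params: np.ndarray) -> tuple[np.ndarray, bool]:
        """Covariance of all parameters from a central-difference Hessian."""
        k = len(params)
        h = 1e-4 * np.maximum(1.0, np.abs(params))
        H = np.empty((k, k))
        f = self.loglike
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fij = (f(params + ei + ej) - f(params + ei - ej)
                       - f(params - ei + ej) + f(params - ei - ej))
                H[i, j] = H[j, i] = fij / (4.0 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            ok = bool(np.all(np.isfinite(cov)) and
                      np.all(np.diag(cov)[: self.k_fe] > 0))
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
            ok = False
        return cov, ok


class LogisticGLMMResults:
    """Estimates, covariance and diagnostics of a fitted LogisticGLMM."""

    def __init__(self, model: LogisticGLMM, params: np.ndarray, llf: float,
                 cov_params: np.ndarray, converged: bool, separation: bool):
        self.model = model
        self.params = np.asarray(params, float)
        self.llf = float(llf)
        self._cov = np.asarray(cov_params, float)
        self.converged = converged
        self.separation = separation
        self.method = "Laplace"
        if separation:
            # flagged, never silently dropped
            import logging
            logging.getLogger(__name__).warning(
                "LogisticGLMM: possible complete separation (|beta| > 30)")

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self.params[: self.model.k_fe],
                         index=self.model.exog_names)

    @property
    def cov_fe(self) -> pd.DataFrame:
        k = self.model.k_fe
        return pd.DataFrame(self._cov[:k, :k], index=self.model.exog_names,
                            columns=self.model.exog_names)

    @property
    def bse_fe(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_fe)),
                         index=self.model.exog_names)

    @property
    def vc(self) -> dict:
        """Random-effect variance components on the natural scale."""
        q = self.model.q
        if q == 0:
            return {}
        theta = self.params[self.model.k_fe:]
        sigma = self.model._sigma(theta)
        out = {"var_intercept": float(sigma[0, 0])}
        if q == 2:
            out["var_slope"] = float(sigma[1, 1])
            out["cov_intercept_slope"] = float(sigma[0, 1])
            out["corr"] = float(np.tanh(theta[2]))
        return out

    @property
    def df_model(self) -> int:
        return self.model.k_fe + self.model.k_vc

    def summary(self) -> str:
        lines = [
            "Logistic GLMM (Laplace approximation)",
            f"  groups: {self.model.n_groups}   obs: {len(self.model.y)}   "
            f"re: {self.model.re_structure}   converged: {self.converged}",
            f"  logLik: {self.llf:.3f}",
            "",
            f"  {'term':<16}{'coef':>12}{'se':>10}{'z':>8}",
        ]
        for name in self.model.exog_names:
            c = self.fe_params[name]
            se = self.bse_fe[name]
            z = c / se if se > 0 else np.nan
            lines.append(f"  {name:<16}{c:>12.5f}{se:>10.4f}{z:>8.2f}")
        for k, v in self.vc.items():
            lines.append(f"  {k}: {v:.5g}")
        return "\n".join(lines)


def lr_test(res_restricted: "LogisticGLMMResults",
            res_full: "LogisticGLMMResults") -> dict:
    """Likelihood-ratio test of nested Laplace fits (naive chi-square p).

    The statistic is clipped at 0; with variance parameters on the boundary
    the naive chi-square reference is conservative.
    """
    if res_full.df_model <= res_restricted.df_model:
        raise ValidationError("fits are not nested (df must increase)")
    stat = max(0.0, 2.0 * (res_full.llf - res_restricted.llf))
    df = res_full.df_model - res_restricted.df_model
    from scipy import stats as _st

    return {"statistic": stat, "df": df, "p_value": float(_st.chi2.sf(stat, df)),
            "boundary_note": "variance components on the boundary make the "
                             "naive chi-square p conservative"}
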