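"""Conditional kernel-density model of hourly SI transitions.

The stochastic model underlying the variability analysis is the conditional
distribution of next-hour insulin sensitivity given the current value,
estimated by bivariate kernel density estimation over every observed
hour-to-hour transition of the cohort, pooled across all patients, days and
diagnosis groups ("whole-cohort model").

Estimation operates on the log of SI: SI is positive and right-skewed, and
Gaussian kernels on the log scale respect the support.  Two coordinate
systems are supported for the second kernel dimension:

* "change" (default): kernels sit on (u_i, r_i) = (log SI_n,
  log SI_n+1 - log SI_n).  Hourly transitions hug the diagonal of the
  (level, level) plane, so smoothing the *change* keeps the conditional
  spread at the scale of real hour-to-hour variability instead of inflating
  it with the much larger between-patient spread of SI levels; the model is
  then approximately self-calibrated (near-uniform percentiles on its own
  training data).
* "level": kernels on (u_i, v_i) = (log SI_n, log SI_n+1), the plain
  bivariate form.

In both cases the conditional CDF is an exact normal-mixture form

    F(y | x) = sum_i w_i(x) * Phi((log y - m_i(x)) / h_v_i),
    w_i(x) proportional to phi((log x - u_i) / h_u_i) / h_u_i,

with component means m_i(x) = log x + r_i ("change") or v_i ("level");
no grid interpolation is involved.

Usage follows the Model/Results convention::

    model = TransitionKDE.from_cohort(cohort)
    res = model.fit()                 # TransitionKDEResults
    p = res.conditional_cdf(si_now, si_next)
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, logsumexp

from .cohort import CohortTable
from .errors import FittingError, NotFittedError, ValidationError

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class TransitionPair:
    """One observed hourly transition (SI_n -> SI_n+1) within a patient."""

    si_from: float
    si_to: float
    patient_id: str = ""
    time_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.si_from > 0 and self.si_to > 0):
            raise ValidationError("transition SI values must be strictly positive")


def extract_transitions(cohort: CohortTable) -> list[TransitionPair]:
    """All consecutive-hour (SI_n, SI_n+1) pairs; none span patients.

    A trajectory of L hourly points yields L - 1 pairs, so a cohort with H
    hourly observations over P patients yields H - P pairs.
    """
    pairs: list[TransitionPair] = []
    for traj in cohort.trajectories:
        s = traj.si_values
        t = traj.times_min
        for k in range(len(s) - 1):
            pairs.append(
                TransitionPair(
                    si_from=float(s[k]),
                    si_to=float(s[k + 1]),
                    patient_id=traj.patient_id,
                    time_min=float(t[k]),
                )
            )
    return pairs


def _fallback_bandwidth(centres: np.ndarray) -> float:
    # degenerate spread: keep the CDF proper with a small positive width
    return max(1e-3, 1e-2 * abs(float(np.mean(centres))))


def _silverman_2d(x: np.ndarray) -> float:
    """Per-dimension Silverman/Scott factor for a bivariate Gaussian KDE.

    In d = 2 the normal-reference constant (4 / (d + 2))^(1 / (d + 4)) is 1,
    so h = sigma * n^(-1/6).
    """
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if sd <= 0:
        return _fallback_bandwidth(x)
    return sd * n ** (-1.0 / 6.0)


class TransitionKDE:
    """Conditional-KDE transition model of hourly SI (unfitted).

    Parameters
    ----------
    pairs : sequence of TransitionPair
        Observed transitions; at least 2 are required to fit.
    """

    def __init__(self, pairs: Sequence[TransitionPair]):
        self.pairs = list(pairs)

    @classmethod
    def from_cohort(cls, cohort: CohortTable) -> "TransitionKDE":
        return cls(extract_transitions(cohort))

    def fit(self, bandwidth_rule: str = "silverman", knn_k: int | None = None,
            coordinates: str = "change") -> "TransitionKDEResults":
        """Fit kernel centres and bandwidths.

        bandwidth_rule : {"silverman", "knn"}
            "silverman" uses one global normal-reference bandwidth per
            dimension; "knn" additionally scales both bandwidths per centre
            by the (standardised) distance to the k-th nearest neighbour,
            normalised to geometric mean 1 (adaptive widths in sparse tails).
        coordinates : {"change", "level"}
            Second kernel dimension: the hourly log-change (default) or the
            raw next-hour log-level (see module docstring).
        """
        if len(self.pairs) < 2:
            raise FittingError("need at least 2 transition pairs to fit")
        if coordinates not in ("change", "level"):
            raise ValidationError(
                f"unknown coordinates {coordinates!r} "
                "(expected 'change' or 'level')")
        u = np.log([p.si_from for p in self.pairs])
        v = np.log([p.si_to for p in self.pairs])
        second = (v - u) if coordinates == "change" else v
        n = len(u)
        hu = _silverman_2d(u)
        hv = _silverman_2d(second)
        h_u = np.full(n, hu)
        h_v = np.full(n, hv)
        if bandwidth_rule == "knn":
            k = knn_k if knn_k is not None else max(2, int(round(np.sqrt(n))))
            k = min(k, n - 1)
            pts = np.column_stack([u / hu, second / hv])
            from scipy.spatial import cKDTree

            dist, _ = cKDTree(pts).query(pts, k=k + 1)
            dk = np.maximum(dist[:, -1], 1e-12)
            lam = dk / np.exp(np.mean(np.log(dk)))
            h_u = h_u * lam
            h_v = h_v * lam
        elif bandwidth_rule != "silverman":
            raise ValidationError(
                f"unknown bandwidth_rule {bandwidth_rule!r} "
                "(expected 'silverman' or 'knn')"
            )
        return TransitionKDEResults(
            u=u, v=v, h_u=h_u, h_v=h_v, bandwidth_rule=bandwidth_rule,
            coordinates=coordinates,
        )


def fit_stochastic_model(pairs: Sequence[TransitionPair],
                         bandwidth_rule: str = "silverman"
                         ) -> "TransitionKDEResults":
    """Convenience wrapper: ``TransitionKDE(pairs).fit(bandwidth_rule)``."""
    return TransitionKDE(pairs).fit(bandwidth_rule=bandwidth_rule)


class TransitionKDEResults:
    """A fitted conditional-KDE transition model.

    Holds kernel centres on the log scale and per-centre bandwidths, and
    exposes the conditional CDF / quantile / density / sampler for next-hour
    SI given current SI.
    """

    #: max elements of a (queries x centres) block evaluated at once
    _CHUNK_ELEMENTS = 4_000_000

    def __init__(self, u: np.ndarray, v: np.ndarray,
                 h_u: np.ndarray, h_v: np.ndarray,
                 bandwidth_rule: str = "silverman",
                 coordinates: str = "change"):
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        h_u = np.asarray(h_u, float)
        h_v = np.asarray(h_v, float)
        if not (len(u) == len(v) == len(h_u) == len(h_v) >= 2):
            raise ValidationError("need >= 2 centres with matching bandwidths")
        if not (np.all(h_u > 0) and np.all(h_v > 0)):
            raise ValidationError("all bandwidths must be positive")
        if coordinates not in ("change", "level"):
            raise ValidationError("coordinates must be 'change' or 'level'")
        self.u, self.v, self.h_u, self.h_v = u, v, h_u, h_v
        self.bandwidth_rule = bandwidth_rule
        self.coordinates = coordinates
        self.transform = "log"
        # second kernel coordinate: hourly log-change or next-hour log-level
        self._r = v - u if coordinates == "change" else v

    def _component_means(self, log_si_from: np.ndarray) -> np.ndarray:
        """Component means of log si_to for queries (m,) -> (m, n_centres)."""
        if self.coordinates == "change":
            return log_si_from[:, None] + self._r[None, :]
        return np.broadcast_to(self._r[None, :],
                               (len(log_si_from), self.n_transitions))

    @property
    def n_transitions(self) -> int:
        return len(self.u)

    # -- weights ----------------------------------------------------------

    def _log_weights(self, si_from: np.ndarray) -> np.ndarray:
        """Log mixture weights, shape (m, n_centres); rows normalised."""
        lx = np.log(si_from)[:, None]
        z = (lx - self.u[None, :]) / self.h_u[None, :]
        lw = -0.5 * z * z - np.log(self.h_u)[None, :]
        return lw - logsumexp(lw, axis=1, keepdims=True)

    def weights(self, si_from: float) -> np.ndarray:
        """Mixture weights w_i(si_from); nonnegative, summing to 1."""
        self._check_positive(si_from=si_from)
        return np.exp(self._log_weights(np.atleast_1d(float(si_from))))[0]

    @staticmethod
    def _check_positive(**kwargs: float) -> None:
        for name, val in kwargs.items():
            if not np.all(np.asarray(val) > 0):
                raise ValidationError(f"{name} must be strictly positive")

    # -- conditional distribution -----------------------------------------

    def conditional_cdf(self, si_from, si_to):
        """F(si_to | si_from); scalar or elementwise on equal-length arrays."""
        scalar = np.isscalar(si_from) and np.isscalar(si_to)
        x = np.atleast_1d(np.asarray(si_from, float))
        y = np.atleast_1d(np.asarray(si_to, float))
        self._check_positive(si_from=x, si_to=y)
        x, y = np.broadcast_arrays(x, y)
        out = np.empty(len(x))
        step = max(1, self._CHUNK_ELEMENTS // self.n_transitions)
        for lo in range(0, len(x), step):
            hi = lo + step
            lx = np.log(x[lo:hi])
            lw = self._log_weights(x[lo:hi])
            means = self._component_means(lx)
            z = (np.log(y[lo:hi])[:, None] - means) / self.h_v[None, :]
            out[lo:hi] = np.exp(logsumexp(lw + log_ndtr(z), axis=1))
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def conditional_pdf(self, si_from: float, si_to) -> np.ndarray | float:
        """Density of next-hour SI at si_to given si_from (on the SI scale)."""
        scalar = np.isscalar(si_to)
        y = np.atleast_1d(np.asarray(si_to, float))
        self._check_positive(si_from=si_from, si_to=y)
        w = self.weights(si_from)
        means = self._component_means(np.atleast_1d(np.log(float(si_from))))[0]
        z = (np.log(y)[:, None] - means[None, :]) / self.h_v[None, :]
        comp = np.exp(-0.5 * z * z) / (self.h_v[None, :] * _SQRT2PI)
        dens = (comp * w[None, :]).sum(axis=1) / y
        return float(dens[0]) if scalar else dens

    def conditional_quantile(self, si_from: float, q: float,
                             tol: float = 1e-8) -> float:
        """Inverse conditional CDF by expanding bracket + bisection on log SI."""
        self._check_positive(si_from=si_from)
        if not (0.0 < q < 1.0):
            raise ValidationError("q must lie strictly inside (0, 1)")
        w = self.weights(si_from)
        means = self._component_means(np.atleast_1d(np.log(float(si_from))))[0]

        def cdf_logy(ly: float) -> float:
            z = (ly - means) / self.h_v
            return float(np.dot(w, ndtr(z)))

        lo = float(np.min(means - 8.0 * self.h_v))
        hi = float(np.max(means + 8.0 * self.h_v))
        while cdf_logy(lo) > q:
            lo -= 8.0
        while cdf_logy(hi) < q:
            hi += 8.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            f = cdf_logy(mid)
            if abs(f - q) < tol * 1e-2 or (hi - lo) < 1e-14:
                break
            if f < q:
                lo = mid
            else:
                hi = mid
        return float(np.exp(0.5 * (lo + hi)))

    # -- sampling ----------------------------------------------------------

    def sample_next(self, si_from: float, rng: np.random.Generator) -> float:
        """One draw of next-hour SI given si_from (component then lognormal)."""
        return float(self.sample_next_many(np.atleast_1d(float(si_from)), rng)[0])

    def sample_next_many(self, si_from: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
        """Vectorised conditional draws, one per element of si_from."""
        x = np.asarray(si_from, float)
        self._check_positive(si_from=x)
        out = np.empty(len(x))
        step = max(1, self._CHUNK_ELEMENTS // self.n_transitions)
        for lo in range(0, len(x), step):
            hi = lo + step
            w = np.exp(self._log_weights(x[lo:hi]))
            cum = np.cumsum(w, axis=1)
            r = rng.random((len(w), 1))
            idx = (r > cum).sum(axis=1)
            idx = np.minimum(idx, self.n_transitions - 1)
            base = (np.log(x[lo:hi]) + self._r[idx]
                    if self.coordinates == "change" else self._r[idx])
            ly = base + self.h_v[idx] * rng.standard_normal(len(idx))
            out[lo:hi] = np.exp(ly)
        return out

    def sample_marginal_start(self, n: int, rng: np.random.Generator
                              ) -> np.ndarray:
        """Draws from the marginal KDE of current SI (the si_from coordinate)."""
        idx = rng.integers(0, self.n_transitions, size=n)
        return np.exp(self.u[idx] + self.h_u[idx] * rng.standard_normal(n))

    # -- serialization -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Self-describing CSV: '#'-prefixed metadata header, then centres."""
        buf = io.StringIO()
        buf.write("# sivar TransitionKDEResults\n")
        buf.write(f"# transform={self.transform}\n")
        buf.write(f"# coordinates={self.coordinates}\n")
        buf.write(f"# bandwidth_rule={self.bandwidth_rule}\n")
        buf.write(f"# n_transitions={self.n_transitions}\n")
        pd.DataFrame(
            {"u": self.u, "v": self.v, "h_u": self.h_u, "h_v": self.h_v}
        ).to_csv(buf, index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def read_csv(cls, path: str | Path) -> "TransitionKDEResults":
        text = Path(path).read_text().splitlines()
        meta = {}
        body_start = 0
        for i, line in enumerate(text):
            if line.startswith("#"):
                if "=" in line:
                    k, _, val = line.lstrip("# ").partition("=")
                    meta[k.strip()] = val.strip()
            else:
                body_start = i
                break
        df = pd.read_csv(io.StringIO("\n".join(text[body_start:])))
        res = cls(
            u=df["u"].to_numpy(), v=df["v"].to_numpy(),
            h_u=df["h_u"].to_numpy(), h_v=df["h_v"].to_numpy(),
            bandwidth_rule=meta.get("bandwidth_rule", "silverman"),
            coordinates=meta.get("coordinates", "change"),
        )
        n_meta = meta.get("n_transitions")
        if n_meta is not None and int(n_meta) != res.n_transitions:
            raise ValidationError("serialized n_transitions does not match body")
        return res

    def summary(self) -> str:
        lines = [
            "Conditional KDE transition model (hourly SI)",
            f"  transform:       {self.transform}",
            f"  coordinates:     {self.coordinates}",
            f"  bandwidth rule:  {self.bandwidth_rule}",
            f"  n transitions:   {self.n_transitions}",
            f"  median h_u, h_v: {np.median(self.h_u):.4f}, "
            f"{np.median(self.h_v):.4f} (log scale)",
        ]
        return "\n".join(lines)


def require_fitted(model) -> TransitionKDEResults:
    """Raise NotFittedError unless *model* is a fitted transition model."""
    if isinstance(model, TransitionKDE):
        raise NotFittedError("call .fit() on the TransitionKDE first")
    if not isinstance(model, TransitionKDEResults):
        raise NotFittedError("a fitted TransitionKDEResults is required")
    return model
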