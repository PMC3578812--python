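"""Synthetic ICU cohorts of hourly insulin-sensitivity trajectories.

Model-based insulin sensitivity (SI) is identified hourly at the bedside and
is strictly positive and right-skewed.  The generator emulates the features
the downstream variability analysis relies on: a per-patient lognormal
baseline, a per-patient random linear drift on the log scale, hour-to-hour
innovations whose standard deviation is largest at admission and decays
geometrically per day of stay, diagnosis-group-specific scaling of that
innovation SD (gastric patients calmest, cardiac patients most variable),
and lognormal lengths of stay truncated so every patient contributes at
least one complete day.

The trajectory process is a log-scale random walk with drift:

    log SI(t+1h) = log SI(t) + s_i + eta_t,
    eta_t ~ N(0, sigma_g(t)),
    sigma_g(t) = innovation_sd_day1 * decay^(t / 1440 min) * multiplier(g),

which guarantees positivity and right skew by construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, NotFittedError, ValidationError

#: Diagnosis groups derived from APACHE III codes: operative / non-operative
#: crossed with cardiac, gastric and "all other".
GROUP_LABELS: tuple[str, ...] = ("NOpC", "OpC", "NOpG", "OpG", "NOpO", "OpO")

#: Minutes between consecutive SI identifications.
HOUR_MIN = 60

_DEFAULT_MULTIPLIERS: dict[str, float] = {
    "NOpG": 0.60,
    "OpG": 0.80,
    "NOpO": 0.90,
    "OpO": 0.95,
    "NOpC": 1.25,
    "OpC": 1.35,
}


@dataclass(frozen=True)
class SITrajectory:
    """One patient's hourly SI series with its diagnosis label.

    SI values are in nominal units of 1e-4 L/(mU * min); times are minutes
    from admission on a strict 60-minute grid starting at 0.
    """

    patient_id: str
    diagnosis: str
    times_min: np.ndarray
    si_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        s = np.asarray(self.si_values, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "si_values", s)
        if self.diagnosis not in GROUP_LABELS:
            raise ValidationError(
                f"diagnosis {self.diagnosis!r} not one of {GROUP_LABELS}"
            )
        if t.shape != s.shape or t.ndim != 1:
            raise ValidationError("times_min and si_values must be equal-length 1-d")
        if len(t) < 2:
            raise ValidationError("a trajectory needs at least 2 hourly points")
        if t[0] != 0 or np.any(np.diff(t) != HOUR_MIN):
            raise ValidationError("times must start at 0 with 60-minute spacing")
        if not np.all(s > 0):
            raise ValidationError("SI values must be strictly positive")

    @property
    def n_hours(self) -> int:
        return len(self.times_min)

    @property
    def los_min(self) -> float:
        """Length of stay in minutes (time of the last SI identification)."""
        return float(self.times_min[-1])


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    All SD parameters act on the log-SI scale.  ``innovation_decay_per_day``
    multiplies the innovation SD once per 24 h of stay and must lie in
    (0, 1]; ``group_variability_multiplier`` scales the innovation SD per
    diagnosis group.
    """

    n_patients_per_group: int = 20
    group_labels: tuple[str, ...] = GROUP_LABELS
    los_hours_log_mean: float = math.log(60.0)
    los_hours_log_sd: float = 0.5
    si_baseline_log_mean: float = math.log(3.0)
    si_baseline_log_sd: float = 0.6
    innovation_sd_day1: float = 0.25
    innovation_decay_per_day: float = 0.7
    group_variability_multiplier: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MULTIPLIERS)
    )
    trend_sd: float = 0.002
    seed: int = 0
    #: emit stays shorter than 24 h instead of re-drawing (exclusion-path testing)
    allow_short_stays: bool = False
    min_los_hours: float = 24.0

    def validate(self) -> None:
        if not (isinstance(self.n_patients_per_group, (int, np.integer))
                and self.n_patients_per_group > 0):
            raise ConfigurationError("n_patients_per_group must be a positive integer")
        if tuple(self.group_labels) != GROUP_LABELS and (
            len(set(self.group_labels)) != 6
        ):
            raise ConfigurationError("group_labels must be exactly 6 distinct labels")
        for name in ("los_hours_log_sd", "si_baseline_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.innovation_sd_day1 < 0:
            raise ConfigurationError("innovation_sd_day1 must be >= 0")
        if not (0 < self.innovation_decay_per_day <= 1):
            raise ConfigurationError("innovation_decay_per_day must be in (0, 1]")
        if self.trend_sd < 0:
            raise ConfigurationError("trend_sd must be >= 0")
        missing = [g for g in self.group_labels
                   if g not in self.group_variability_multiplier]
        if missing:
            raise ConfigurationError(
                f"group_variability_multiplier missing labels: {missing}"
            )
        bad = [g for g, m in self.group_variability_multiplier.items() if m < 0]
        if bad:
            raise ConfigurationError(
                f"group_variability_multiplier must be >= 0, offending: {bad}"
            )
        if self.min_los_hours < 2:
            raise ConfigurationError("min_los_hours must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["group_labels"] = list(self.group_labels)
        d["group_variability_multiplier"] = dict(self.group_variability_multiplier)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("cohort config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
        if "group_labels" in raw:
            raw["group_labels"] = tuple(raw["group_labels"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class CohortTable:
    """A collection of trajectories plus the provenance that produced it."""

    trajectories: list[SITrajectory]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.patient_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValidationError("patient_id values must be unique in a cohort")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def n_hours_total(self) -> int:
        return sum(t.n_hours for t in self.trajectories)

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "patient_id": t.patient_id,
                    "diagnosis": t.diagnosis,
                    "time_min": t.times_min.astype(int),
                    "si_value": t.si_values,
                }
            )
            for t in self.trajectories
        ]
        if not frames:
            return pd.DataFrame(
                columns=["patient_id", "diagnosis", "time_min", "si_value"]
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: dict | None = None
                       ) -> "CohortTable":
        required = {"patient_id", "diagnosis", "time_min", "si_value"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns {sorted(missing)}")
        trajs = []
        for pid, g in df.groupby("patient_id", sort=False):
            g = g.sort_values("time_min")
            trajs.append(
                SITrajectory(
                    patient_id=str(pid),
                    diagnosis=str(g["diagnosis"].iloc[0]),
                    times_min=g["time_min"].to_numpy(dtype=float),
                    si_values=g["si_value"].to_numpy(dtype=float),
                )
            )
        return cls(trajectories=trajs, provenance=provenance or {})

    @classmethod
    def read_csv(cls, path: str | Path) -> "CohortTable":
        return cls.from_dataframe(pd.read_csv(path), provenance={"source": str(path)})


def _patient_rng(seed: int, group_index: int, patient_index: int
                 ) -> np.random.Generator:
    # per-patient substream: reproducible regardless of generation order
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_index, patient_index))
    return np.random.default_rng(ss)


def _draw_los_hours(rng: np.random.Generator, cfg: CohortConfig) -> float:
    if cfg.allow_short_stays:
        return max(2.0, float(rng.lognormal(cfg.los_hours_log_mean,
                                            cfg.los_hours_log_sd)))
    for _ in range(1000):
        los = float(rng.lognormal(cfg.los_hours_log_mean, cfg.los_hours_log_sd))
        if los >= cfg.min_los_hours:
            return los
    return cfg.min_los_hours  # pathological config; degrade gracefully


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a seeded synthetic cohort under the log-random-walk process.

    Deterministic for a fixed ``config.seed``; each patient draws from an
    independent substream keyed by (group, patient index).
    """
    config.validate()
    trajectories: list[SITrajectory] = []
    for gi, label in enumerate(config.group_labels):
        mult = float(config.group_variability_multiplier[label])
        for pi in range(config.n_patients_per_group):
            rng = _patient_rng(config.seed, gi, pi)
            los_hours = _draw_los_hours(rng, config)
            n_points = max(2, int(math.floor(los_hours)) + 1)
            times = np.arange(n_points, dtype=float) * HOUR_MIN
            log_b = rng.normal(config.si_baseline_log_mean,
                               config.si_baseline_log_sd)
            slope = rng.normal(0.0, config.trend_sd) if config.trend_sd > 0 else 0.0
            # innovation SD evaluated at the origin hour of each transition
            sig = (config.innovation_sd_day1
                   * config.innovation_decay_per_day ** (times[:-1] / 1440.0)
                   * mult)
            eta = rng.standard_normal(n_points - 1) * sig
            log_si = log_b + np.concatenate(([0.0], np.cumsum(slope + eta)))
            trajectories.append(
                SITrajectory(
                    patient_id=f"{label}{pi:04d}",
                    diagnosis=label,
                    times_min=times,
                    si_values=np.exp(log_si),
                )
            )
    return CohortTable(
        trajectories=trajectories,
        provenance={"generator": "sivar.cohort.generate_cohort",
                    "config": dataclasses.asdict(config)},
    )


def sample_null_cohort(model, n_patients: int, horizon_hours: int, seed: int
                       ) -> CohortTable:
    """Sample a self-consistent ("null") cohort from a fitted transition model.

    Each trajectory starts from a draw of the model's marginal distribution of
    current SI and evolves by repeated draws from the fitted conditional
    distribution of next-hour SI.  Scoring such a cohort with the same model
    must yield uniform percentiles — the calibration reference for the
    coverage histograms.

    Parameters
    ----------
    model : TransitionKDEResults
        A fitted conditional-KDE transition model.
    n_patients, horizon_hours : int
        Cohort size and (identical) trajectory length in hours.
    seed : int
        Seed for the sampling stream; output is deterministic given it.
    """
    if not hasattr(model, "sample_marginal_start"):
        raise NotFittedError("sample_null_cohort requires a fitted "
                             "TransitionKDEResults (call .fit() first)")
    if horizon_hours < 2:
        raise ValidationError("horizon_hours must be >= 2")
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    si = model.sample_marginal_start(n_patients, rng)
    values = np.empty((n_patients, horizon_hours), dtype=float)
    values[:, 0] = si
    for k in range(1, horizon_hours):
        values[:, k] = model.sample_next_many(values[:, k - 1], rng)
    times = np.arange(horizon_hours, dtype=float) * HOUR_MIN
    trajectories = [
        SITrajectory(
            patient_id=f"{GROUP_LABELS[i % 6]}-null{i:04d}",
            diagnosis=GROUP_LABELS[i % 6],
            times_min=times,
            si_values=values[i],
        )
        for i in range(n_patients)
    ]
    return CohortTable(
        trajectories=trajectories,
        provenance={"generator": "sivar.cohort.sample_null_cohort",
                    "seed": seed, "n_patients": n_patients,
                    "horizon_hours": horizon_hours},
    )


def hourly_log_changes(cohort: CohortTable,
                       groups: Iterable[str] | None = None) -> np.ndarray:
    """All within-patient hour-to-hour log-SI increments, optionally by group."""
    keep = set(groups) if groups is not None else None
    out = [
        np.diff(np.log(t.si_values))
        for t in cohort.trajectories
        if keep is None or t.diagnosis in keep
    ]
    return np.concatenate(out) if out else np.empty(0)
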