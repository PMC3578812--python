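"""Percentile (PIT) series and per-patient, per-day variability penalties.

For each observed transition the percentile of the actual next-hour SI on
its model-predicted distribution is p = F(SI_n+1 | SI_n), the probability
integral transform of the observation.  Under a perfectly calibrated model
the p values are uniform on [0, 1].

Two per-patient penalties aggregate the percentiles over a day of stay:

* quadratic: mean of (p - 0.5)^2, in [0, 0.25] — overall intra-patient
  variability relative to the whole-cohort model (1/12 under uniformity);
* one-sided: fraction of p strictly above 0.9 — the rate of large upward
  SI swings, which drive hypoglycaemic risk under insulin dosing (0.10
  under uniformity).

Days of stay segment the observed-hour timestamps into the blocks
day1 = (0, 1440], day2 = (1440, 2880], day3 = (2880, 4320] minutes and
day4plus = (4320, inf): the k-th day holds the 24 observations made during
hours 24(k-1)+1 ... 24k (percentile records are timestamped at the observed
hour, so the first possible record sits at 60 min).  To avoid unequal
weighting near discharge, day1-3 are retained only when the stay covers the
complete block; day4plus keeps whatever remains; stays under 24 h are
excluded entirely.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, SITrajectory
from .errors import AggregationError, ValidationError
from .stochastic import require_fitted

#: Day blocks in minutes from admission; membership is start < t <= end
#: (records are stamped at the observed hour, so day1 holds 60 ... 1440).
DAY_BLOCKS: "OrderedDict[str, tuple[float, float]]" = OrderedDict(
    [
        ("day1", (0.0, 1440.0)),
        ("day2", (1440.0, 2880.0)),
        ("day3", (2880.0, 4320.0)),
        ("day4plus", (4320.0, np.inf)),
    ]
)

#: Minimum length of stay (minutes) for inclusion in daily statistics.
MIN_LOS_MIN = 1440.0

PERCENTILE_COLUMNS = ["patient_id", "diagnosis", "time_min", "percentile"]
PENALTY_COLUMNS = ["patient_id", "diagnosis", "day", "quadratic",
                   "one_sided", "n_hours"]


def percentile_series(model, trajectory: SITrajectory) -> pd.DataFrame:
    """Per-hour PIT values of one trajectory under a fitted transition model.

    Each consecutive pair (SI_n, SI_n+1) yields p = F(SI_n+1 | SI_n),
    timestamped at the observed (n+1)-th hour; a trajectory of L points
    yields L - 1 records.
    """
    model = require_fitted(model)
    s = trajectory.si_values
    t = trajectory.times_min
    if len(s) < 2:
        return pd.DataFrame(columns=PERCENTILE_COLUMNS)
    p = model.conditional_cdf(s[:-1], s[1:])
    return pd.DataFrame(
        {
            "patient_id": trajectory.patient_id,
            "diagnosis": trajectory.diagnosis,
            "time_min": t[1:].astype(int),
            "percentile": np.atleast_1d(p),
        }
    )


def percentile_table(model, cohort: CohortTable) -> pd.DataFrame:
    """PIT records for a whole cohort (vectorised across all transitions)."""
    model = require_fitted(model)
    frames = [percentile_series(model, traj) for traj in cohort.trajectories]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=PERCENTILE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _as_clean_percentiles(percentiles: Sequence[float]) -> np.ndarray:
    p = np.asarray(percentiles, dtype=float)
    if p.size == 0:
        raise AggregationError("cannot aggregate an empty percentile list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("percentiles must lie in [0, 1]")
    return p


def quadratic_penalty(percentiles: Sequence[float]) -> float:
    """Mean squared deviation of PIT values from the ideal 50th percentile."""
    p = _as_clean_percentiles(percentiles)
    return float(np.mean((p - 0.5) ** 2))


def one_sided_penalty(percentiles: Sequence[float], threshold: float = 0.9
                      ) -> float:
    """Fraction of PIT values strictly exceeding the cohort-model threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0, 1)")
    p = _as_clean_percentiles(percentiles)
    return float(np.mean(p > threshold))


def segment_days(records: pd.DataFrame, los_min: float
                 ) -> "OrderedDict[str, pd.DataFrame]":
    """Assign one patient's percentile records to day blocks.

    Membership is ``start < time_min <= end`` so the k-th day holds the 24
    records observed during its hours.  day1-3 are kept only when the stay
    covers the whole block (``los_min >= block end``); day4plus keeps all
    records past 4320 min; a stay under 1440 min returns an empty mapping
    (patient excluded).
    """
    if len(records) and records["patient_id"].nunique() > 1:
        raise ValidationError("segment_days expects records of a single patient")
    out: "OrderedDict[str, pd.DataFrame]" = OrderedDict()
    if los_min < MIN_LOS_MIN:
        return out
    t = records["time_min"].to_numpy(dtype=float) if len(records) else np.empty(0)
    for label, (start, end) in DAY_BLOCKS.items():
        complete = np.isinf(end) or los_min >= end
        if not complete:
            continue
        mask = (t > start) & (t <= end)
        block = records.iloc[np.flatnonzero(mask)]
        if len(block):
            out[label] = block.reset_index(drop=True)
    return out


def segment_cohort(records: pd.DataFrame, cohort: CohortTable) -> pd.DataFrame:
    """Cohort-wide segmentation: percentile records plus a ``day`` column.

    Applies the same completeness and 24-h-minimum rules as
    :func:`segment_days`; records from dropped blocks or excluded patients
    are absent from the output.
    """
    los = {t.patient_id: t.los_min for t in cohort.trajectories}
    frames = []
    for pid, g in records.groupby("patient_id", sort=False):
        if pid not in los:
            raise ValidationError(f"records contain unknown patient {pid!r}")
        for label, block in segment_days(g, los[pid]).items():
            block = block.copy()
            block["day"] = label
            frames.append(block)
    if not frames:
        return pd.DataFrame(columns=PERCENTILE_COLUMNS + ["day"])
    return pd.concat(frames, ignore_index=True)


def per_patient_day_scores(cohort: CohortTable, model,
                           threshold: float = 0.9) -> pd.DataFrame:
    """One penalty row per (patient, populated day block).

    Columns: ``patient_id, diagnosis, day, quadratic, one_sided, n_hours``.
    """
    model = require_fitted(model)
    rows = []
    for traj in cohort.trajectories:
        recs = percentile_series(model, traj)
        for label, block in segment_days(recs, traj.los_min).items():
            p = block["percentile"].to_numpy()
            rows.append(
                {
                    "patient_id": traj.patient_id,
                    "diagnosis": traj.diagnosis,
                    "day": label,
                    "quadratic": quadratic_penalty(p),
                    "one_sided": one_sided_penalty(p, threshold=threshold),
                    "n_hours": len(p),
                }
            )
    return pd.DataFrame(rows, columns=PENALTY_COLUMNS)


def group_day_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Group-level variability: mean per-patient penalty by (day, diagnosis)."""
    return (
        scores.groupby(["day", "diagnosis"], sort=False)
        .agg(
            quadratic=("quadratic", "mean"),
            one_sided=("one_sided", "mean"),
            n_patients=("patient_id", "nunique"),
        )
        .reset_index()
    )
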