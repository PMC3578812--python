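"""Descriptive surfaces: coverage histograms, time trends, score summaries.

These are the tabular counterparts of the usual presentation of the
variability analysis — decile coverage histograms of the PIT values by day
of stay and diagnosis group (flat = perfectly calibrated, U-shaped = more
variable than predicted, peaked = less), a LOWESS trend of the per-hour
quadratic deviation against minutes of stay, and violin-plot-ready
summaries (quartiles, mean, kernel density) of the per-patient penalties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

logger = logging.getLogger(__name__)

HIST_COLUMNS = ["day", "diagnosis", "bin_low", "bin_high", "count", "fraction", "n"]


@dataclass
class DecileHistogram:
    """Counts of PIT values in the ten bins [0,0.1), ..., [0.9,1.0]."""

    counts: np.ndarray
    day_label: str | None = None
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (10,) or np.any(self.counts < 0):
            raise ValueError("counts must be 10 nonnegative integers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n if self.n else np.zeros(10)

    def to_frame(self) -> pd.DataFrame:
        edges = np.linspace(0, 1, 11)
        return pd.DataFrame(
            {
                "day": self.day_label,
                "diagnosis": self.diagnosis,
                "bin_low": edges[:-1],
                "bin_high": edges[1:],
                "count": self.counts,
                "fraction": self.fractions,
                "n": self.n,
            }
        )


def decile_histogram(percentiles, day_label: str | None = None,
                     diagnosis: str | None = None) -> DecileHistogram:
    """Decile-bin counts of PIT values; p = 1.0 falls in the last bin."""
    p = np.asarray(percentiles, dtype=float)
    if p.size == 0:
        return DecileHistogram(np.zeros(10, int), day_label, diagnosis)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("percentiles must lie in [0, 1]")
    idx = np.minimum((p * 10).astype(int), 9)
    return DecileHistogram(np.bincount(idx, minlength=10), day_label, diagnosis)


def decile_histograms_by_cell(segmented: pd.DataFrame) -> list[DecileHistogram]:
    """One histogram per (day, diagnosis) cell of a segmented PIT table."""
    return [
        decile_histogram(g["percentile"].to_numpy(), day_label=day,
                         diagnosis=diag)
        for (day, diag), g in segmented.groupby(["day", "diagnosis"], sort=False)
    ]


def uniformity_statistic(hist: DecileHistogram) -> dict:
    """Pearson chi-square (9 df) of a decile histogram against uniformity.

    Quantifies the visual flatness of a coverage histogram.  Below n = 50
    the chi-square approximation is shaky; the statistic is still returned
    with ``small_sample`` flagged.
    """
    n = hist.n
    small = n < 50
    if small:
        logger.warning("uniformity_statistic: n=%d < 50, chi-square unreliable", n)
    if n == 0:
        return {"statistic": float("nan"), "p_value": float("nan"),
                "df": 9, "small_sample": True}
    stat, p = stats.chisquare(hist.counts, f_exp=np.full(10, n / 10.0))
    return {"statistic": float(stat), "p_value": float(p), "df": 9,
            "small_sample": small}


def lowess_trend(observations: pd.DataFrame, value_col: str = "value",
                 frac: float = 2.0 / 3.0, it: int = 3,
                 grid_points: int = 50, min_points: int = 20) -> pd.DataFrame:
    """LOWESS trend of a per-hour score vs minutes of stay, per group.

    Expects columns ``diagnosis, time_min`` and *value_col*.  Groups with
    fewer than *min_points* observations are skipped with a log entry.
    Returns a tidy frame ``diagnosis, time_min, smoothed, frac``.
    """
    frames = []
    for diag, g in observations.groupby("diagnosis", sort=False):
        if len(g) < min_points:
            logger.info("lowess_trend: skipping %s (%d < %d points)",
                        diag, len(g), min_points)
            continue
        t = g["time_min"].to_numpy(dtype=float)
        y = g[value_col].to_numpy(dtype=float)
        fitted = sm_lowess(y, t, frac=frac, it=it, return_sorted=True)
        grid = np.linspace(t.min(), t.max(), grid_points)
        sm = np.interp(grid, fitted[:, 0], fitted[:, 1])
        frames.append(pd.DataFrame({"diagnosis": diag, "time_min": grid,
                                    "smoothed": sm, "frac": frac}))
    if not frames:
        return pd.DataFrame(columns=["diagnosis", "time_min", "smoothed", "frac"])
    return pd.concat(frames, ignore_index=True)


METRIC_SUPPORT = {"quadratic": (0.0, 0.25), "one_sided": (0.0, 1.0)}


def _density_on_grid(values: np.ndarray, support: tuple[float, float],
                     grid_points: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density over a grid padded past the data range."""
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    degenerate = sd <= 1e-9 * max(1.0, float(np.abs(values).max()))
    if not degenerate:
        kde = stats.gaussian_kde(values)
        bw = kde.factor * sd
        lo = min(values.min(), support[0]) - 3 * bw
        hi = max(values.max(), support[1]) + 3 * bw
        grid = np.linspace(lo, hi, grid_points)
        heights = kde(grid)
    else:
        # all scores identical: represent a narrow spike so the density
        # still integrates to ~1 on the grid
        centre = float(values[0])
        bw = max(1e-3, 1e-2 * abs(centre))
        grid = np.linspace(centre - 6 * bw, centre + 6 * bw, grid_points)
        heights = stats.norm.pdf(grid, loc=centre, scale=bw)
    return grid, heights


def distribution_summary(penalties: pd.DataFrame,
                         metrics: tuple[str, ...] = ("quadratic", "one_sided"),
                         min_cell: int = 3,
                         grid_points: int = 256
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Violin-plot-ready summaries of per-patient scores by (day, group).

    Returns ``(summary, density)``: *summary* has one row per
    (day, diagnosis, metric) with n, mean, median, q25, q75 (linear
    interpolation between order statistics) and a ``small_cell`` flag for
    cells under *min_cell* patients; *density* is the tidy KDE table
    ``day, diagnosis, metric, x, density``.  Empty cells are omitted with a
    log entry.
    """
    summary_rows = []
    density_frames = []
    for (day, diag), g in penalties.groupby(["day", "diagnosis"], sort=False):
        for metric in metrics:
            vals = g[metric].to_numpy(dtype=float)
            if vals.size == 0:
                logger.info("distribution_summary: empty cell (%s, %s, %s)",
                            day, diag, metric)
                continue
            small = vals.size < min_cell
            if small:
                logger.info("distribution_summary: small cell (%s, %s, %s): n=%d",
                            day, diag, metric, vals.size)
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            summary_rows.append(
                {"day": day, "diagnosis": diag, "metric": metric,
                 "n": vals.size, "mean": float(np.mean(vals)),
                 "median": float(med), "q25": float(q25), "q75": float(q75),
                 "small_cell": small}
            )
            grid, heights = _density_on_grid(vals, METRIC_SUPPORT[metric],
                                             grid_points)
            density_frames.append(
                pd.DataFrame({"day": day, "diagnosis": diag, "metric": metric,
                              "x": grid, "density": heights})
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=["day", "diagnosis", "metric", "n", "mean", "median",
                 "q25", "q75", "small_cell"],
    )
    density = (
        pd.concat(density_frames, ignore_index=True)
        if density_frames
        else pd.DataFrame(columns=["day", "diagnosis", "metric", "x", "density"])
    )
    return summary, density
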