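"""Optional PNG rendering of the tidy output tables (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def render_all(outdir: str | Path) -> dict[str, Path]:
    """Render coverage histograms, LOWESS trends and score densities.

    Reads the pipeline's CSV outputs from *outdir* and writes PNGs next to
    them.  Returns {artifact name: path}.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: dict[str, Path] = {}

    hist_csv = outdir / "decile_histograms.csv"
    if hist_csv.exists():
        df = pd.read_csv(hist_csv)
        days = list(pd.unique(df["day"]))
        groups = list(pd.unique(df["diagnosis"]))
        fig, axes = plt.subplots(len(days), len(groups),
                                 figsize=(2.2 * len(groups), 2.0 * len(days)),
                                 squeeze=False, sharex=True)
        for i, day in enumerate(days):
            for j, g in enumerate(groups):
                ax = axes[i][j]
                cell = df[(df["day"] == day) & (df["diagnosis"] == g)]
                if len(cell):
                    ax.bar(cell["bin_low"], cell["fraction"], width=0.1,
                           align="edge", edgecolor="k", linewidth=0.3)
                    ax.axhline(0.1, ls="--", c="grey", lw=0.8)
                    ax.set_title(f"{g} {day} (n={int(cell['n'].iloc[0])})",
                                 fontsize=7)
                ax.tick_params(labelsize=6)
        fig.tight_layout()
        path = outdir / "decile_histograms.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["decile_histograms_png"] = path

    trend_csv = outdir / "lowess_trend.csv"
    if trend_csv.exists():
        df = pd.read_csv(trend_csv)
        fig, ax = plt.subplots(figsize=(6, 4))
        for g, sub in df.groupby("diagnosis"):
            ax.plot(sub["time_min"], sub["smoothed"], label=g)
        for d in (1440, 2880, 4320, 5760):
            ax.axvline(d, ls="--", c="grey", lw=0.6)
        ax.set_xlabel("time since admission (min)")
        ax.set_ylabel("smoothed squared PIT deviation")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "lowess_trend.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["lowess_trend_png"] = path

    dens_csv = outdir / "score_density.csv"
    if dens_csv.exists():
        df = pd.read_csv(dens_csv)
        for metric, sub in df.groupby("metric"):
            days = list(pd.unique(sub["day"]))
            fig, axes = plt.subplots(1, len(days),
                                     figsize=(3.0 * len(days), 3.0),
                                     squeeze=False, sharey=True)
            for i, day in enumerate(days):
                ax = axes[0][i]
                for g, cell in sub[sub["day"] == day].groupby("diagnosis"):
                    ax.plot(cell["x"], cell["density"], label=g, lw=0.9)
                ax.set_title(f"{metric} {day}", fontsize=8)
                ax.tick_params(labelsize=6)
            axes[0][-1].legend(fontsize=6)
            fig.tight_layout()
            path = outdir / f"score_density_{metric}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[f"score_density_{metric}_png"] = path

    return written
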