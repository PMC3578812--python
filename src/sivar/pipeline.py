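"""One-call orchestration: cohort -> model -> percentiles -> penalties -> inference.

``run_pipeline`` executes the full analysis on either a synthetic cohort
(seeded generator) or an ingested trajectory CSV, writing tidy CSV tables
for every stage plus a manifest with SHA-256 checksums, so a fixed seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, metrics, mixed
from .cohort import CohortConfig, CohortTable, generate_cohort
from .errors import ConfigurationError
from .stochastic import TransitionKDE, extract_transitions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis."""

    outdir: Path = Path("sivar_output")
    seed: int = 0
    synthetic: CohortConfig | None = None
    input_cohort_csv: Path | None = None
    bandwidth_rule: str = "silverman"
    exceedance_threshold: float = 0.9
    time_cap_min: float = 8000.0
    metric: str = "both"
    lowess_frac: float = 2.0 / 3.0
    render_png: bool = False
    verbosity: str = "INFO"

    def validate(self) -> None:
        if not (0.0 < self.exceedance_threshold < 1.0):
            raise ConfigurationError(
                "exceedance_threshold must lie in (0, 1), got "
                f"{self.exceedance_threshold}")
        if self.time_cap_min <= 0:
            raise ConfigurationError("time_cap_min must be positive")
        if self.metric not in ("quadratic", "one_sided", "both"):
            raise ConfigurationError(
                "metric must be 'quadratic', 'one_sided' or 'both'")
        if not (0.0 < self.lowess_frac <= 1.0):
            raise ConfigurationError("lowess_frac must lie in (0, 1]")
        if self.bandwidth_rule not in ("silverman", "knn"):
            raise ConfigurationError("bandwidth_rule must be 'silverman' or 'knn'")
        if self.synthetic is None and self.input_cohort_csv is None:
            raise ConfigurationError(
                "either a synthetic block or input_cohort_csv is required")
        if self.synthetic is not None:
            self.synthetic.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("pipeline config must hold a mapping")
        synth = raw.pop("synthetic", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**{**raw,
                     "outdir": Path(raw.get("outdir", "sivar_output")),
                     "input_cohort_csv": (Path(raw["input_cohort_csv"])
                                          if raw.get("input_cohort_csv") else None)})
        if synth is not None:
            if "seed" not in synth:
                synth["seed"] = cfg.seed
            if "group_labels" in synth:
                synth["group_labels"] = tuple(synth["group_labels"])
            cfg.synthetic = CohortConfig(**synth)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest.

    Raises a stage-tagged :class:`SivarError` on failure after writing a
    partial manifest; idempotent for a fixed seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}}
    manifest_path = outdir / "manifest.json"

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": path.name,
                                       "sha256": _sha256(path)}

    stage = "ingest"
    try:
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
        else:
            cohort = CohortTable.read_csv(config.input_cohort_csv)
        path = outdir / "cohort.csv"
        cohort.to_csv(path)
        record("cohort", path)
        manifest["stages"].append(stage)

        stage = "fit_model"
        pairs = extract_transitions(cohort)
        model = TransitionKDE(pairs).fit(bandwidth_rule=config.bandwidth_rule)
        path = outdir / "stochastic_model.csv"
        model.to_csv(path)
        record("stochastic_model", path)
        manifest["n_transitions"] = model.n_transitions
        manifest["stages"].append(stage)

        stage = "percentiles"
        pit = metrics.percentile_table(model, cohort)
        path = outdir / "percentiles.csv"
        _write_csv(pit, path)
        record("percentiles", path)
        manifest["stages"].append(stage)

        stage = "segmentation"
        segmented = metrics.segment_cohort(pit, cohort)
        path = outdir / "percentiles_by_day.csv"
        _write_csv(segmented, path)
        record("percentiles_by_day", path)
        manifest["stages"].append(stage)

        stage = "penalties"
        scores = metrics.per_patient_day_scores(
            cohort, model, threshold=config.exceedance_threshold)
        path = outdir / "penalties.csv"
        _write_csv(scores, path)
        record("penalties", path)
        path = outdir / "group_day_means.csv"
        _write_csv(metrics.group_day_means(scores), path)
        record("group_day_means", path)
        manifest["stages"].append(stage)

        stage = "descriptive"
        hists = analysis.decile_histograms_by_cell(segmented)
        hist_df = (pd.concat([h.to_frame() for h in hists], ignore_index=True)
                   if hists else pd.DataFrame(columns=analysis.HIST_COLUMNS))
        path = outdir / "decile_histograms.csv"
        _write_csv(hist_df, path)
        record("decile_histograms", path)
        unif = pd.DataFrame(
            [{"day": h.day_label, "diagnosis": h.diagnosis,
              **analysis.uniformity_statistic(h)} for h in hists]
        )
        path = outdir / "uniformity.csv"
        _write_csv(unif, path)
        record("uniformity", path)
        hourly = segmented.copy()
        hourly["value"] = (hourly["percentile"] - 0.5) ** 2
        trend = analysis.lowess_trend(hourly, value_col="value",
                                      frac=config.lowess_frac)
        path = outdir / "lowess_trend.csv"
        _write_csv(trend, path)
        record("lowess_trend", path)
        summary, density = analysis.distribution_summary(scores)
        path = outdir / "score_summary.csv"
        _write_csv(summary, path)
        record("score_summary", path)
        path = outdir / "score_density.csv"
        _write_csv(density, path)
        record("score_density", path)
        manifest["stages"].append(stage)

        stage = "mixed_models"
        model_info: dict = {}
        text_blocks: list[str] = [model.summary()]
        metrics_to_fit = (("quadratic", "one_sided") if config.metric == "both"
                          else (config.metric,))
        for metric_name in metrics_to_fit:
            obs = mixed.build_observations(
                segmented, metric_name, time_cap_min=config.time_cap_min,
                threshold=config.exceedance_threshold)
            if metric_name == "quadratic":
                res = mixed.fit_lme_quadratic(obs)
                ar1 = mixed.test_ar1_necessity(obs, lme_results=res)
                model_info["ar1_check"] = {
                    k: v for k, v in ar1.items() if k != "excluded_patients"}
            else:
                res = mixed.fit_glme_onesided(obs)
            _write_csv(res.coef_table(), outdir / f"coeffs_{metric_name}.csv")
            record(f"coeffs_{metric_name}", outdir / f"coeffs_{metric_name}.csv")
            model_info[metric_name] = {
                "converged": res.converged,
                "time_per_minute": res.time_per_minute,
                "time_per_day": res.time_per_day,
                "random_components": res.random_components,
                "interaction_test": mixed.test_time_diagnosis_interaction(
                    obs, metric_name),
                "lr_random_structure": mixed.lr_test_random_structure(
                    obs, metric_name),
            }
            text_blocks.append(res.summary())

            stage = "posthoc"
            tukey = res.tukey_hsd()
            path = outdir / f"tukey_{metric_name}.csv"
            _write_csv(tukey, path)
            record(f"tukey_{metric_name}", path)
            stage = "mixed_models"
        path = outdir / "model_tests.json"
        path.write_text(json.dumps(model_info, indent=2, default=float))
        record("model_tests", path)
        path = outdir / "summary.txt"
        path.write_text("\n\n".join(text_blocks) + "\n")
        record("summary", path)
        manifest["stages"].append("mixed_models")
        manifest["stages"].append("posthoc")

        if config.render_png:
            stage = "render"
            from . import plots
            for name, fig_path in plots.render_all(outdir).items():
                record(name, fig_path)
            manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Deterministic miniature cohort plus its percentile/penalty tables.

    Used as golden files by the test suite: 12 patients (2 per group),
    stays around two days, the whole bundle a few tens of kilobytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(n_patients_per_group=2,
                       los_hours_log_mean=float(np.log(40.0)),
                       los_hours_log_sd=0.35, seed=seed)
    cohort = generate_cohort(cfg)
    model = TransitionKDE.from_cohort(cohort).fit()
    pit = metrics.percentile_table(model, cohort)
    scores = metrics.per_patient_day_scores(cohort, model)
    paths = {
        "cohort": outdir / "mini_cohort.csv",
        "percentiles": outdir / "mini_percentiles.csv",
        "penalties": outdir / "mini_penalties.csv",
    }
    cohort.to_csv(paths["cohort"])
    _write_csv(pit, paths["percentiles"])
    _write_csv(scores, paths["penalties"])
    return paths
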