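"""End-to-end orchestration: two datasets -> forecasts -> comparisons.

``run`` reads the consultation and population extracts, builds the
pre-pandemic (inclusion 2017, follow 2018-2019) and pandemic (inclusion
2019, follow 2020-2021) datasets, and for every diagnosis x stratum
estimates the bootstrap correlations, scales the forecasts, runs the
smoothed comparison, and writes tables, figures and a reproducibility
manifest.  Identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    build_dataset,
    dataset_manifest,
    dataset_summary,
)
from .forecast import ForecastConfig, fit_forecasts, forecast_frame
from .loess import DEFAULT_LEVEL, DEFAULT_SPAN, DEFAULT_WINDOW_START, ComparisonResult, compare
from .registry_io import CodeSet, read_consultations_frame, read_population_frame
from .weekly import Stratifier, default_strata, slice_years, weekly_counts

logger = logging.getLogger(__name__)

#: Illustrative approximation of Norway's strict social-distancing periods
#: (spring 2020 and January-spring 2021); real analyses should supply the
#: officially documented dates in the run config.
EXAMPLE_RESTRICTION_PERIODS = (
    ((2020, 11), (2020, 20)),
    ((2021, 1), (2021, 16)),
)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one analysis run; defaults are the standard
    surveillance configuration (10,000 bootstrap resamples, loess span 17%,
    99.9% pointwise band, window from 2020-W11)."""

    consultations: str = "consultations.csv"
    population: str = "population.csv"
    pre_inclusion_year: int = 2017
    pan_inclusion_year: int = 2019
    codes: CodeSet = field(default_factory=CodeSet)
    diagnoses: tuple[str, ...] = ()  # empty -> all analysis codes
    strata: tuple[Stratifier, ...] = field(default_factory=lambda: tuple(default_strata()))
    n_boot: int = 10_000
    bootstrap_mode: str = "weeks"
    span: float = DEFAULT_SPAN
    ci_level: float = DEFAULT_LEVEL
    window_start: tuple[int, int] = DEFAULT_WINDOW_START
    seed: int = 0
    restriction_periods: tuple = EXAMPLE_RESTRICTION_PERIODS
    outdir: str = "results"
    make_figures: bool = True

    @property
    def pre_spec(self) -> CohortSpec:
        y = self.pre_inclusion_year
        return CohortSpec(inclusion_year=y, follow_years=(y + 1, y + 2), codes=self.codes)

    @property
    def pan_spec(self) -> CohortSpec:
        y = self.pan_inclusion_year
        return CohortSpec(inclusion_year=y, follow_years=(y + 1, y + 2), codes=self.codes)

    @property
    def analysis_diagnoses(self) -> tuple[str, ...]:
        return self.diagnoses or tuple(sorted(self.codes.analysis_codes))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "strata" in raw:
            raw["strata"] = tuple(Stratifier.parse(s) for s in raw["strata"])
        if "codes" in raw:
            raw["codes"] = CodeSet(
                inclusion_codes=frozenset(raw["codes"]["inclusion_codes"]),
                analysis_codes=frozenset(raw["codes"]["analysis_codes"]),
            )
        if "window_start" in raw:
            raw["window_start"] = tuple(raw["window_start"])
        if "restriction_periods" in raw:
            raw["restriction_periods"] = tuple(
                (tuple(a), tuple(b)) for a, b in raw["restriction_periods"]
            )
        if "diagnoses" in raw:
            raw["diagnoses"] = tuple(raw["diagnoses"])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["codes"] = {
            "inclusion_codes": sorted(self.codes.inclusion_codes),
            "analysis_codes": sorted(self.codes.analysis_codes),
        }
        d["strata"] = [str(s) for s in self.strata]
        blob = json.dumps(d, sort_keys=True, default=str)
        return {
            "config": d,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "version": __version__,
        }


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle.

    The bundle maps (diagnosis, stratum string) -> ComparisonResult and
    carries the summary table.  On any stage error, partial outputs are
    removed and the error is re-raised naming the stage and stratum.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    current = "-"
    try:
        consultations = read_consultations_frame(config.consultations)
        population = read_population_frame(config.population)

        stage = "build datasets"
        pre_ds = build_dataset(consultations, population, config.pre_spec, "pre_pandemic")
        pan_ds = build_dataset(consultations, population, config.pan_spec, "pandemic")
        for ds in (pre_ds, pan_ds):
            logger.info(
                "%s dataset: cohort %d, retained consultations %d",
                ds.label, len(ds.cohort_ids), ds.n_consultations,
            )

        fconfig = ForecastConfig(
            n_boot=config.n_boot, bootstrap_mode=config.bootstrap_mode, seed=config.seed
        )
        results: dict[tuple[str, str], ComparisonResult] = {}
        summary_rows = []
        comparison_frames = []
        period_frames = []
        forecast_frames = []
        for diagnosis in config.analysis_diagnoses:
            for stratum in config.strata:
                current = f"{diagnosis}/{stratum}"
                stage = "forecast"
                f1, f2 = fit_forecasts(pre_ds, pan_ds, diagnosis, stratum, fconfig)
                stage = "compare"
                observed = slice_years(
                    weekly_counts(pan_ds, diagnosis, stratum),
                    [f1.target_year, f2.target_year],
                )
                result = compare(
                    observed, (f1, f2),
                    window_start=config.window_start,
                    span=config.span, level=config.ci_level,
                )
                results[(diagnosis, str(stratum))] = result
                summary_rows.append(
                    {
                        "diagnosis": diagnosis,
                        "stratum": str(stratum),
                        "mean_deviation_pct": result.mean_deviation_pct,
                        "r_mean_y1": f1.estimate.r_mean,
                        "r_mean_y2": f2.estimate.r_mean,
                    }
                )
                comparison_frames.append(result.to_frame())
                period_frames.append(result.periods_frame())
                forecast_frames.append(forecast_frame(f1, f2))
                if config.make_figures:
                    stage = "plot"
                    fig_path = outdir / f"panel_{diagnosis}_{stratum}".replace(":", "_")
                    plot_panel(result, config.restriction_periods, fig_path.with_suffix(".svg"))

        stage = "write outputs"
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(outdir / "summary.csv", index=False)
        pd.concat(comparison_frames, ignore_index=True).to_csv(
            outdir / "comparison.csv", index=False
        )
        pd.concat(period_frames, ignore_index=True).to_csv(
            outdir / "periods.csv", index=False
        )
        pd.concat(forecast_frames, ignore_index=True).to_csv(
            outdir / "forecast.csv", index=False
        )
        manifest = config.to_manifest()
        manifest["datasets"] = [dataset_manifest(pre_ds), dataset_manifest(pan_ds)]
        manifest["summaries"] = [dataset_summary(pre_ds), dataset_summary(pan_ds)]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"stage {stage!r} failed for {current}: {exc}") from exc
    return {
        "results": results,
        "summary": summary,
        "pre_dataset": pre_ds,
        "pan_dataset": pan_ds,
        "manifest": manifest,
    }


def _week_to_index(window, week: tuple[int, int]) -> float | None:
    lookup = {wk: i for i, wk in enumerate(window)}
    return lookup.get(tuple(week))


def plot_panel(result: ComparisonResult, restriction_periods=(), path=None):
    """One time-series panel: observed trend (solid), forecast (dashed),
    99.9% band (grey) and shaded restriction periods; vector output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(result.window) == 0:
        raise ValueError("empty comparison result")
    x = np.arange(len(result.window))
    fig, ax = plt.subplots(figsize=(9, 4))
    for start, end in restriction_periods:
        i0 = _week_to_index(result.window, start)
        i1 = _week_to_index(result.window, end)
        if i0 is None and i1 is None:
            continue
        i0 = 0 if i0 is None else i0
        i1 = len(x) - 1 if i1 is None else i1
        ax.axvspan(i0, i1, color="#c6dbef", alpha=0.6, zorder=0, label="_restriction")
    ax.fill_between(
        x, result.ci_lower, result.ci_upper, color="0.8", zorder=1, label="99.9% CI"
    )
    ax.plot(x, result.predicted_smooth, "b--", zorder=2, label="forecast")
    ax.plot(x, result.observed_smooth, "r-", zorder=3, label="observed")
    ticks = [i for i, (y, w) in enumerate(result.window) if w in (11, 24, 37, 50)]
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{y}-W{w:02d}" for y, w in np.array(result.window)[ticks]], rotation=45)
    ax.set_ylabel("consultations per week")
    ax.set_title(f"{result.diagnosis} - {result.stratum}")
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return Path(path)
    return fig
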