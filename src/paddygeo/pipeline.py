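"""Per-dataset analysis pipeline and cross-dataset study summaries.

``run_dataset`` chains the stages the study applies to every dataset:
descriptive statistics → sample semivariogram → model fitting with
leave-one-out cross-validated selection → nugget-ratio classification →
(optionally) an ordinary-kriging map.  ``summarize_study`` aggregates
either full reports or a bare parameter table into the per-nutrient
CV/sill/range extremes and the nugget-ratio histogram used to describe
the study as a whole.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .descriptive import DescriptiveStats, cv_percent, describe
from .exceptions import PipelineError, ValidationError
from .fitting import (
    CrossValidation,
    FitResult,
    loo_cross_validate,
    select_model,
)
from .kriging import GridSpec, KrigingGrid, grid_from_samples, krige_grid, \
    write_ascii_grid
from .sample_io import SampleSet
from .variogram import (
    EmpiricalVariogram,
    ModelFamily,
    SpatialDependence,
    classify_dependence,
    empirical_variogram,
    nugget_sill_ratio,
)

__all__ = ["AnalysisOptions", "DatasetReport", "StudySummary",
           "run_dataset", "summarize_study", "render_report"]

RATIO_BINS = ("zero", "below_25", "25_to_50", "50_to_75", "above_75")


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the per-dataset pipeline (defaults mirror the package
    conventions: 12 m lags, half-max-distance cutoff, 5 m map cells)."""

    lag_width: float | None = None
    max_lag: float | None = None
    families: Sequence[str | ModelFamily] = (
        ModelFamily.SPHERICAL, ModelFamily.EXPONENTIAL, ModelFamily.GAUSSIAN)
    weighting: str = "cressie"
    make_map: bool = False
    map_cell: float = 5.0


@dataclass
class DatasetReport:
    """Everything the pipeline derives from one dataset."""

    dataset_code: str
    stats: DescriptiveStats
    variogram: EmpiricalVariogram
    fit: FitResult
    cv: CrossValidation
    dependence_class: SpatialDependence
    map: KrigingGrid | None = None

    def __post_init__(self):
        expected = classify_dependence(nugget_sill_ratio(self.fit.model))
        if self.dependence_class is not expected:
            raise ValidationError(
                "dependence_class inconsistent with the fitted model")


@dataclass
class StudySummary:
    """Study-level aggregation across datasets.

    ``cv_range`` / ``sill_range`` / ``range_a_range`` map nutrient label
    to (min, max); ``ratio_histogram`` counts datasets with nugget
    ratio exactly 0, in (0, 25), in [25, 50], in (50, 75] and above 75
    percent.
    """

    n_datasets: int
    cv_range: dict[str, tuple[float, float]]
    sill_range: dict[str, tuple[float, float]]
    range_a_range: dict[str, tuple[float, float]]
    ratio_histogram: dict[str, int]
    ratio_max: float

    def __post_init__(self):
        if sum(self.ratio_histogram.values()) != self.n_datasets:
            raise ValidationError("ratio histogram must sum to n_datasets")
        for d in (self.cv_range, self.sill_range, self.range_a_range):
            for lo, hi in d.values():
                if lo > hi:
                    raise ValidationError("every min must be <= its max")

    def to_dict(self) -> dict:
        return {
            "n_datasets": self.n_datasets,
            "cv_range": {k: list(v) for k, v in self.cv_range.items()},
            "sill_range": {k: list(v) for k, v in self.sill_range.items()},
            "range_a_range": {k: list(v)
                              for k, v in self.range_a_range.items()},
            "ratio_histogram": dict(self.ratio_histogram),
            "ratio_max": self.ratio_max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudySummary":
        return cls(n_datasets=int(d["n_datasets"]),
                   cv_range={k: tuple(v) for k, v in d["cv_range"].items()},
                   sill_range={k: tuple(v)
                               for k, v in d["sill_range"].items()},
                   range_a_range={k: tuple(v)
                                  for k, v in d["range_a_range"].items()},
                   ratio_histogram=dict(d["ratio_histogram"]),
                   ratio_max=float(d["ratio_max"]))


def run_dataset(samples: SampleSet,
                options: AnalysisOptions = AnalysisOptions()) -> DatasetReport:
    """Full per-dataset analysis; stage failures carry the stage name."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    stats = stage("describe", describe, samples.values)
    emp = stage("empirical_variogram", empirical_variogram, samples,
                options.lag_width, options.max_lag)
    fit, cv = stage("select_model", select_model, emp, samples,
                    options.families, options.weighting)
    dependence = classify_dependence(nugget_sill_ratio(fit.model))
    grid = None
    if options.make_map:
        spec = grid_from_samples(samples, cell=options.map_cell)
        grid = stage("krige_grid", krige_grid, samples, fit.model, spec)
    return DatasetReport(dataset_code=samples.dataset_code, stats=stats,
                         variogram=emp, fit=fit, cv=cv,
                         dependence_class=dependence, map=grid)


def _ratio_bin(ratio: float) -> str:
    if ratio == 0.0:
        return "zero"
    if ratio < 25.0:
        return "below_25"
    if ratio <= 50.0:
        return "25_to_50"
    if ratio <= 75.0:
        return "50_to_75"
    return "above_75"


def summarize_study(reports: "Iterable[DatasetReport] | pd.DataFrame"
                    ) -> StudySummary:
    """Aggregate dataset reports (or a bare parameter table) study-wide.

    A DataFrame input needs columns ``nutrient, c0, c1, range_a, mean,
    variance`` — the printed per-dataset moments and variogram
    parameters — so a published summary table can be summarized without
    re-running any analysis.  CVs are recomputed as
    ``100 sqrt(variance) / mean`` and sills as ``c0 + c1`` at full
    precision; rounding happens only at display.
    """
    rows = []
    if isinstance(reports, pd.DataFrame):
        if reports.empty:
            raise ValidationError("summarize_study requires >= 1 row")
        for _, r in reports.iterrows():
            sill = float(r["c0"]) + float(r["c1"])
            if sill <= 0:
                raise ValidationError(f"non-positive sill in row {r!r}")
            rows.append({
                "nutrient": str(r["nutrient"]),
                "cv": cv_percent(float(r["mean"]), float(r["variance"])),
                "sill": sill,
                "range_a": float(r["range_a"]),
                "ratio": 100.0 * float(r["c0"]) / sill,
            })
    else:
        for rep in reports:
            m = rep.fit.model
            rows.append({
                "nutrient": _nutrient_of(rep),
                "cv": rep.stats.cv_percent,
                "sill": m.sill,
                "range_a": m.range_a,
                "ratio": nugget_sill_ratio(m),
            })
        if not rows:
            raise ValidationError("summarize_study requires >= 1 report")
    df = pd.DataFrame(rows)
    histogram = {b: 0 for b in RATIO_BINS}
    for ratio in df["ratio"]:
        histogram[_ratio_bin(float(ratio))] += 1

    def _minmax(col):
        return {str(nut): (float(g[col].min()), float(g[col].max()))
                for nut, g in df.groupby("nutrient", sort=False)}

    return StudySummary(n_datasets=len(df),
                        cv_range=_minmax("cv"),
                        sill_range=_minmax("sill"),
                        range_a_range=_minmax("range_a"),
                        ratio_histogram=histogram,
                        ratio_max=float(df["ratio"].max()))


def _nutrient_of(report: DatasetReport) -> str:
    # Dataset codes are "<nutrient>-<dose><event>"; everything before the
    # final dash identifies the nutrient.
    code = report.dataset_code
    return code.rsplit("-", 1)[0] if "-" in code else code


def render_report(reports: Sequence[DatasetReport], summary: StudySummary,
                  out_dir: str | Path, seed: int | None = None,
                  config: Mapping | None = None) -> list[Path]:
    """Write the study artefacts: stats table, variogram-fit table,
    JSON summary, ASCII grids for any kriged maps, and a run log.

    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    stats_rows, fit_rows = [], []
    for rep in reports:
        s = rep.stats
        stats_rows.append({
            "dataset_code": rep.dataset_code, "n": s.n, "mean": s.mean,
            "variance": s.variance, "cv": s.cv_percent,
            "minimum": s.minimum, "maximum": s.maximum,
            "skewness": s.skewness, "kurtosis": s.kurtosis,
            "ks_stat": s.ks_stat, "ks_p": s.ks_p,
        })
        m = rep.fit.model
        fit_rows.append({
            "dataset_code": rep.dataset_code, "family": m.family.value,
            "c0": m.c0, "c1": m.c1, "ratio": nugget_sill_ratio(m),
            "range_a": m.range_a, "r2": rep.cv.r2, "me": rep.cv.me,
            "nmse": rep.cv.nmse, "class": rep.dependence_class.value,
        })
    stats_path = out / "dataset_statistics.csv"
    pd.DataFrame(stats_rows).to_csv(stats_path, index=False)
    written.append(stats_path)
    fits_path = out / "variogram_fits.csv"
    pd.DataFrame(fit_rows).to_csv(fits_path, index=False)
    written.append(fits_path)

    summary_path = out / "study_summary.json"
    summary_path.write_text(json.dumps(summary.to_dict(), indent=2,
                                       sort_keys=True) + "\n",
                            encoding="utf-8")
    written.append(summary_path)

    for rep in reports:
        if rep.map is not None:
            for which in ("values", "variances"):
                p = out / f"{rep.dataset_code}_{which}.asc"
                write_ascii_grid(rep.map, p, which=which)
                written.append(p)

    config_yaml = yaml.safe_dump(dict(config) if config else {},
                                 sort_keys=True)
    log_path = out / "run_log.txt"
    log_path.write_text(
        f"paddygeo version: {__version__}\n"
        f"seed: {seed}\n"
        f"config hash: {hashlib.sha256(config_yaml.encode()).hexdigest()}\n"
        f"config:\n{config_yaml}",
        encoding="utf-8")
    written.append(log_path)
    return written
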