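"""End-to-end orchestration: generate -> measure -> analyse.

Ties the synthetic generator, the measurement stage and the statistics
stage into reproducible runs, either in memory (:func:`compute_metrics_table`,
:func:`run_pipeline`) or on disk via a dataset directory of PNGs +
stroke JSONs + manifest (:func:`generate_dataset`,
:func:`measure_dataset`, :func:`analyse_metrics`).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .generator import default_counts, make_dataset
from .gridmetrics import METRIC_COLUMNS, MetricConfig, extract_metrics
from .palette import Sheet, default_palette
from .raster import rasterize
from .stats import AnalysisConfig, AnalysisReport, run_full_analysis
from .strokes import GroundTruth, VectorDrawing

__all__ = [
    "RunConfig",
    "compute_metrics_table",
    "generate_dataset",
    "measure_dataset",
    "analyse_metrics",
    "run_pipeline",
]

log = logging.getLogger("apedraw")


@dataclass(frozen=True)
class RunConfig:
    """Settings of one reproducible pipeline run.

    Serialized verbatim into every output directory as an audit trail.
    """

    seed: int = 0
    counts: dict[str, int] = field(default_factory=default_counts)
    px_per_mm: float = 2.0
    longitudinal: str = "Molly"
    metric: MetricConfig = field(default_factory=MetricConfig)
    stats: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "metric" in d:
            shape = d["metric"].pop("shape", None)
            if shape is not None:
                from .shapes import ShapeConfig

                d["metric"]["shape"] = ShapeConfig(**shape)
            d["metric"] = MetricConfig(**d["metric"])
        if "stats" in d:
            d["stats"] = AnalysisConfig(**d["stats"])
        return cls(**d)

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, stats=dataclasses.replace(self.stats, seed=seed)
        )


def compute_metrics_table(
    pairs: list[tuple[VectorDrawing, GroundTruth]],
    px_per_mm: float = 2.0,
    config: MetricConfig = MetricConfig(),
) -> pd.DataFrame:
    """Metrics table (one row per drawing) from in-memory drawings."""
    rows = []
    for drawing, _gt in pairs:
        raster = rasterize(drawing, px_per_mm)
        rows.append(extract_metrics(raster, drawing, config=config).as_row())
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def generate_dataset(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a synthetic dataset (PNGs, stroke/truth JSONs, manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    _, manifest = make_dataset(
        counts=config.counts,
        seed=config.seed,
        out_dir=out,
        px_per_mm=config.px_per_mm,
        longitudinal=config.longitudinal,
    )
    log.info("generated %d drawings into %s", len(manifest), out)
    return pd.DataFrame(manifest)


def measure_dataset(
    dataset_dir: str | Path,
    config: RunConfig | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Measure every non-damaged drawing of a dataset directory.

    Reads the manifest, the PNG rasters and the stroke JSONs; drawings
    carrying a truthy ``damaged`` manifest flag are excluded from the
    table (torn or stained sheets cannot be measured reliably).  A
    missing stroke file leaves the shape counts missing and logs a
    warning.
    """
    from PIL import Image

    config = config or RunConfig()
    ds = Path(dataset_dir)
    manifest = pd.read_csv(ds / "manifest.csv")
    sheet = Sheet()
    rows = []
    skipped = 0
    for rec in manifest.to_dict("records"):
        if bool(rec.get("damaged", False)):
            skipped += 1
            continue
        did = rec["drawing_id"]
        image = np.asarray(Image.open(ds / f"{did}.png").convert("RGB"))
        stroke_file = ds / f"{did}.strokes.json"
        px_per_mm = image.shape[1] / sheet.width_mm
        if stroke_file.exists():
            drawing = VectorDrawing.load(stroke_file)
            row = extract_metrics(
                image, drawing, default_palette(), drawing.sheet,
                config.metric, px_per_mm=px_per_mm,
            ).as_row()
        else:
            log.warning("missing stroke file for %s; shape counts unavailable", did)
            from .gridmetrics import (
                build_label_map, colour_spectrum_stats, count_colours,
                distance_to_centre, main_colour, summarize_cells,
                coverage_rate, overlap_rate, solid_colour_rate,
            )
            labels = build_label_map(image, default_palette(), config.metric, px_per_mm)
            cells = summarize_cells(labels, sheet)
            mean, sd = colour_spectrum_stats(labels)
            row = {
                "drawing_id": did, "individual": rec["individual"],
                "season": rec["season"], "period": rec["period"],
                "coverage_rate": coverage_rate(cells),
                "overlap_rate": overlap_rate(cells),
                "n_colours": count_colours(labels, config.metric.min_pixels),
                "fan": np.nan, "circle": np.nan, "triangle": np.nan, "loop": np.nan,
                "colour_mean": mean, "colour_sd": sd,
                "dist_centre_mm": distance_to_centre(labels, sheet),
                "solid_colour_rate": solid_colour_rate(cells),
                "main_colour": main_colour(labels),
            }
        rows.append(row)
    if skipped:
        log.info("excluded %d damaged drawing(s)", skipped)
    table = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def analyse_metrics(
    metrics: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run the statistics stage; optionally write the report bundle."""
    config = config or RunConfig()
    report = run_full_analysis(metrics, config.stats)
    if out_dir is not None:
        out = Path(out_dir)
        report.write(out)
        (out / "config.json").write_text(config.to_json())
    return report


def run_pipeline(config: RunConfig | None = None) -> tuple[pd.DataFrame, AnalysisReport]:
    """Generate, measure and analyse in memory; returns (metrics, report)."""
    config = config or RunConfig()
    pairs, _ = make_dataset(
        counts=config.counts,
        seed=config.seed,
        render=False,
        longitudinal=config.longitudinal,
    )
    metrics = compute_metrics_table(pairs, config.px_per_mm, config.metric)
    report = run_full_analysis(metrics, config.stats)
    return metrics, report
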