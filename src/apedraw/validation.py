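"""Validation experiments against planted ground truth.

Every routine here builds its own synthetic inputs, runs the package's
measurement or statistics stage on them, and scores the result against
the known truth — the package's substitute for the human inter-observer
agreement that a study on real drawings would report.  The routines are
deliberately independent of the implementation paths they check: grid
rates are compared against a plain per-cell/per-pixel tally, shape
recovery against the generator's planted-shape records, and the
permutation model against its nominal error rate under a true null.

Problem sizes default to desk-scale versions of the study conditions
(the full 790-drawing corpus remains the generator default); see the
methods note for the sizes chosen and why.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generator import default_profiles, make_dataset, sample_drawing
from .gridmetrics import (
    build_label_map,
    coverage_rate,
    overlap_rate,
    solid_colour_rate,
    summarize_cells,
)
from .palette import Sheet
from .pipeline import compute_metrics_table
from .raster import rasterize
from .shapes import ShapeConfig, classify_stroke
from .stats import AnalysisConfig, pca_fit, permutation_lm, run_full_analysis

__all__ = [
    "grid_rate_oracle",
    "oracle_agreement",
    "shape_recovery",
    "type1_calibration",
    "EndToEndRun",
    "end_to_end_recovery",
    "factor_retention",
    "SCALED_COUNTS",
]

#: Desk-scale study conditions for repeated end-to-end runs: the four
#: occasional drawers contribute 8 drawings each and the longitudinal
#: individual 114 (6 per 3-month period over the 19 periods).
SCALED_COUNTS = {"Gypsy": 8, "Julie": 8, "Yuki": 8, "Kiki": 8, "Molly": 114}


# ---------------------------------------------------------------------------
# grid-rate oracle equivalence
# ---------------------------------------------------------------------------

def grid_rate_oracle(labels, sheet: Sheet) -> tuple[float, float, float]:
    """Brute-force (coverage, overlap, solid) rates from a label map.

    Loops over grid cells and tallies each cell's pixel block directly —
    a deliberately different route from the vectorised bincount path in
    :func:`apedraw.gridmetrics.summarize_cells`.
    """
    h, w = labels.labels.shape
    s = labels.px_per_mm
    xs = (np.arange(w) + 0.5) / s
    ys = (np.arange(h) + 0.5) / s
    col_of = np.minimum((xs / sheet.width_mm * sheet.grid_cols).astype(int), sheet.grid_cols - 1)
    row_of = np.minimum((ys / sheet.height_mm * sheet.grid_rows).astype(int), sheet.grid_rows - 1)
    covered = multi = solid = 0
    for r in range(sheet.grid_rows):
        for c in range(sheet.grid_cols):
            block = labels.labels[np.ix_(row_of == r, col_of == c)]
            marked = block >= 0
            if marked.any():
                covered += 1
                if len(np.unique(block[marked])) >= 2:
                    multi += 1
                if marked.sum() / block.size >= 0.5:
                    solid += 1
    n_cells = sheet.grid_rows * sheet.grid_cols
    cov = covered / n_cells
    ovl = 100.0 * multi / covered if covered else 0.0
    sol = solid / n_cells
    return cov, ovl, sol


def oracle_agreement(n_drawings: int = 100, seed: int = 0, px_per_mm: float = 2.0) -> float:
    """Fraction of seeded drawings whose coverage/overlap/solid rates
    equal the brute-force oracle exactly (expected: 1.0)."""
    profiles = default_profiles()
    names = sorted(profiles)
    rng = np.random.default_rng(seed)
    sheet = Sheet()
    agree = 0
    for i in range(n_drawings):
        prof = profiles[names[i % len(names)]]
        d, _ = sample_drawing(prof, _dt.date(2008, 1 + i % 12, 15), rng)
        labels = build_label_map(rasterize(d, px_per_mm))
        cells = summarize_cells(labels, sheet)
        got = (coverage_rate(cells), overlap_rate(cells), solid_colour_rate(cells))
        agree += got == grid_rate_oracle(labels, sheet)
    return agree / n_drawings


# ---------------------------------------------------------------------------
# shape recovery
# ---------------------------------------------------------------------------

def shape_recovery(
    n_drawings: int = 500, seed: int = 0, config: ShapeConfig = ShapeConfig()
) -> dict[str, float]:
    """Planted-shape recovery under full generator conditions.

    Classifies every stroke of ``n_drawings`` drawings (all profiles
    mixed) and scores against the planted ground truth.  Returns the
    fraction of planted shapes recovered with the correct class and the
    fraction of plain meander strokes spuriously assigned any class.
    """
    profiles = default_profiles()
    names = sorted(profiles)
    rng = np.random.default_rng(seed)
    planted_total = recovered = 0
    meander_total = spurious = 0
    confusion: dict[tuple[str, str], int] = {}
    for i in range(n_drawings):
        prof = profiles[names[i % len(names)]]
        d, gt = sample_drawing(prof, _dt.date(2007 + i % 4, 1 + i % 12, 10), rng)
        planted = {idx: kind for kind, idx in gt.planted_shapes}
        for idx, stroke in enumerate(d.strokes):
            fan, closed = classify_stroke(stroke, config)
            pred = "fan" if fan else closed
            truth = planted.get(idx, "meander")
            confusion[(truth, pred)] = confusion.get((truth, pred), 0) + 1
            if truth == "meander":
                meander_total += 1
                spurious += pred != "none"
            else:
                planted_total += 1
                recovered += pred == truth
    return {
        "recovery": recovered / planted_total if planted_total else float("nan"),
        "spurious": spurious / meander_total if meander_total else 0.0,
        "n_planted": planted_total,
        "n_meander": meander_total,
        "confusion": confusion,
    }


def isolated_shape_accuracy(n_per_kind: int = 100, seed: int = 0) -> float:
    """Classification accuracy on isolated planted shapes (no meander
    context): fans, circles, loops and triangles drawn one per stroke."""
    from .generator import make_closed_shape, make_fan_stroke

    rng = np.random.default_rng(seed)
    ok = total = 0
    for _ in range(n_per_kind):
        for kind in ("fan", "circle", "loop", "triangle"):
            anchor = (136 + rng.uniform(-50, 50), 121 + rng.uniform(-45, 45))
            if kind == "fan":
                s = make_fan_stroke(anchor, rng.uniform(18, 45), int(rng.integers(3, 6)),
                                    rng.uniform(20, 42), rng)
            else:
                s = make_closed_shape(kind, anchor, rng.uniform(18, 40), rng)
            fan, closed = classify_stroke(s)
            pred = "fan" if fan else closed
            ok += pred == kind
            total += 1
    return ok / total


# ---------------------------------------------------------------------------
# permutation-model calibration
# ---------------------------------------------------------------------------

def type1_calibration(
    n_replicates: int = 1000, B: int = 999, n: int = 60, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Type-I error of the permutation LM under a true null.

    A balanced season x period design is fixed; each replicate draws an
    independent standard-normal response and the fraction of replicates
    with p < alpha is reported per term (nominal: alpha).
    """
    seasons = pd.Series(np.tile(["winter", "spring", "summer", "autumn"], n // 4 + 1)[:n])
    periods = pd.Series(np.tile(np.arange(1.0, 20.0), n // 19 + 1)[:n])
    rng = np.random.default_rng(seed)
    rejections = {"season": 0, "period": 0}
    for i in range(n_replicates):
        y = rng.normal(size=n)
        res = permutation_lm(y, seasons, periods, B=B, seed=int(rng.integers(2**31)))
        for t in rejections:
            rejections[t] += res.p_perm[t] < alpha
    return {t: r / n_replicates for t, r in rejections.items()}


# ---------------------------------------------------------------------------
# end-to-end planted-effect recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndToEndRun:
    """Outcome of one generate -> measure -> analyse run."""

    kw_dim1_p: float
    season_p: float
    period_p: float
    period_slope_filling: float       # slope on the filling-oriented dimension
    winter_lowest: bool               # winter mean below every other season
    retained_inter: int
    retained_long: int
    metrics: pd.DataFrame

    @property
    def individual_effect(self) -> bool:
        return self.kw_dim1_p < 1e-3

    @property
    def winter_deficit(self) -> bool:
        return self.season_p < 0.05 and self.winter_lowest

    @property
    def declining_trend(self) -> bool:
        return self.period_p < 0.05 and self.period_slope_filling < 0


def _filling_dimension(model) -> tuple[str, float]:
    """The retained dimension carrying the filling block, and the sign
    that orients it so more filling means higher scores."""
    row = model.loadings.loc["coverage_rate"]
    dim = row.abs().idxmax()
    return dim, float(np.sign(row[dim]) or 1.0)


def end_to_end_run(seed: int, B: int = 299, px_per_mm: float = 1.0) -> EndToEndRun:
    """One full pipeline run at the desk-scale study conditions."""
    pairs, _ = make_dataset(counts=SCALED_COUNTS, seed=seed, render=False)
    metrics = compute_metrics_table(pairs, px_per_mm=px_per_mm)
    report = run_full_analysis(metrics, AnalysisConfig(B=B, seed=seed))
    kw_p = report.kruskal_dims["Dim1"].p_value
    dim, orient = _filling_dimension(report.pca_long)
    lm = report.perm_lm_dims[dim]
    sub = metrics[metrics["individual"] == report.longitudinal_individual]
    scores = report.pca_long.scores[dim].to_numpy() * orient
    by_season = pd.Series(scores).groupby(sub["season"].to_numpy()).mean()
    winter_lowest = bool(
        "winter" in by_season.index and by_season["winter"] == by_season.min()
    )
    return EndToEndRun(
        kw_dim1_p=kw_p,
        season_p=lm.p_perm["season"],
        period_p=lm.p_perm["period"],
        period_slope_filling=orient * lm.coefficients["period"],
        winter_lowest=winter_lowest,
        retained_inter=report.pca_inter.retained,
        retained_long=report.pca_long.retained,
        metrics=metrics,
    )


def end_to_end_recovery(n_runs: int = 20, seed: int = 0, B: int = 299) -> list[EndToEndRun]:
    """Repeat the full pipeline over ``n_runs`` seeds."""
    return [end_to_end_run(seed * 1000 + i, B=B) for i in range(n_runs)]


# ---------------------------------------------------------------------------
# factor retention
# ---------------------------------------------------------------------------

def planted_factor_data(
    rng: np.random.Generator, n: int = 600, loading: float = 0.75
) -> pd.DataFrame:
    """11 variables driven by 3 latent factors in blocks of 6 + 2 + 3,
    mirroring the filling / colour / shape structure of the metrics."""
    blocks = [6, 2, 3]
    f = rng.normal(size=(n, 3))
    cols = []
    for b, k in enumerate(blocks):
        for _ in range(k):
            cols.append(loading * f[:, b] + np.sqrt(1 - loading**2) * rng.normal(size=n))
    return pd.DataFrame(np.column_stack(cols), columns=[f"v{i}" for i in range(11)])


def factor_retention(n_runs: int = 100, n: int = 600, seed: int = 0) -> dict[str, float]:
    """How often the eigenvalue-above-1 rule retains exactly the three
    planted factors, and how often every variable loads |.| > 0.5 on its
    own block's dimension."""
    rng = np.random.default_rng(seed)
    blocks = [0] * 6 + [1] * 2 + [2] * 3
    exact = pattern = 0
    for _ in range(n_runs):
        model = pca_fit(planted_factor_data(rng, n=n))
        exact += model.retained == 3
        if model.retained == 3:
            load = np.abs(model.loadings.to_numpy())
            dims = {}
            okay = True
            for b in range(3):
                members = [i for i, bb in enumerate(blocks) if bb == b]
                dims[b] = int(np.argmax(load[members].sum(axis=0)))
            if len(set(dims.values())) == 3:
                okay = all(load[i, dims[b]] > 0.5 for i, b in enumerate(blocks))
            else:
                okay = False
            pattern += okay
    return {"exact_three": exact / n_runs, "loading_pattern": pattern / n_runs}
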