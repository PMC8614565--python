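"""Per-drawing quantitative variables from the raster image.

The measurement grid divides the sheet into 10 x 10 cells.  From the
pixel image the module derives a :class:`LabelMap` (per-pixel crayon
assignment plus luminance), summarises it per cell, and computes the
drawing variables:

1. coverage rate — covered cells / total cells;
2. overlap rate — % of covered cells containing >= 2 crayon colours;
3. solid colour rate — cells with >= 50% of their area marked, / total;
4. distance to centre — from the centre of the minimum-area ellipse
   enclosing all marks to the sheet centre, in mm;
5. number of colours used;
6./7. mean and standard deviation of the colour spectrum (per-pixel
   luminance over the whole sheet, 0 = black, 1 = white);
8. main (predominant) colour;
9.-12. fan / circle / triangle / loop counts, delegated to the vector
   stroke classifier.

Colour labelling inverts the crayon pressure model: a marked pixel is
``p * colour + (1 - p) * white``, so each crayon occupies a straight
segment between its reference RGB and white; a pixel is assigned the
crayon whose pressure segment it is closest to.  (Plain nearest-RGB
matching fails for pale marks, which drift toward intrinsically light
crayons.)
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray

from .ellipse import ellipse_centre
from .palette import Palette, Sheet, default_palette
from .raster import RasterDrawing
from .shapes import ShapeConfig, count_shapes
from .strokes import VectorDrawing

__all__ = [
    "LabelMap",
    "CellSummary",
    "MetricConfig",
    "MetricVector",
    "build_label_map",
    "summarize_cells",
    "coverage_rate",
    "overlap_rate",
    "solid_colour_rate",
    "count_colours",
    "main_colour",
    "colour_spectrum_stats",
    "distance_to_centre",
    "extract_metrics",
    "METRIC_COLUMNS",
]

#: Column order of a metrics table row.
METRIC_COLUMNS = [
    "drawing_id", "individual", "season", "period",
    "coverage_rate", "overlap_rate", "n_colours", "fan", "circle",
    "triangle", "loop", "colour_mean", "colour_sd", "dist_centre_mm",
    "solid_colour_rate", "main_colour",
]

#: The 11 quantitative variables (main colour is qualitative).
QUANTITATIVE_VARS = [
    "coverage_rate", "overlap_rate", "n_colours", "fan", "circle",
    "triangle", "loop", "colour_mean", "colour_sd", "dist_centre_mm",
    "solid_colour_rate",
]


@dataclass(frozen=True)
class MetricConfig:
    """Thresholds of the measurement stage."""

    bg_delta: float = 40.0       # RGB distance to white below which a pixel is paper
    min_pixels: int = 1          # pixels needed before a colour counts as used
    min_pressure: float = 0.35   # lowest crayon pressure the labeller allows for
    shape: ShapeConfig = field(default_factory=ShapeConfig)


@dataclass
class LabelMap:
    """Per-pixel colour assignment and luminance of a raster drawing."""

    labels: np.ndarray        # (H, W) int16, -1 = background
    luminance: np.ndarray     # (H, W) float in [0, 1]
    px_per_mm: float
    palette: Palette

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CellSummary:
    """Grid-cell aggregation of a label map."""

    covered: np.ndarray                 # (rows, cols) bool
    fraction: np.ndarray                # (rows, cols) marked-pixel fraction
    colour_sets: list[list[set[int]]]   # colours present per cell
    sheet: Sheet

    @property
    def n_cells(self) -> int:
        return self.covered.size


def build_label_map(
    raster: RasterDrawing | np.ndarray,
    palette: Palette | None = None,
    config: MetricConfig = MetricConfig(),
    px_per_mm: float | None = None,
) -> LabelMap:
    """Assign every pixel to background or its nearest crayon.

    Accepts either a :class:`RasterDrawing` or a raw ``(H, W, 3)`` uint8
    image (then ``px_per_mm`` is required).  Marked pixels are assigned
    by minimum distance to the crayon pressure segments
    ``{p * c + (1 - p) * white, p in [min_pressure, 1]}``.
    """
    if isinstance(raster, RasterDrawing):
        image = raster.image
        palette = palette or raster.palette
        px_per_mm = raster.px_per_mm
    else:
        image = raster
        palette = palette or default_palette()
        if px_per_mm is None:
            raise ValueError("px_per_mm is required for a bare image array")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3) RGB")

    h, w = image.shape[:2]
    from_white = image.reshape(-1, 3).astype(np.float32) - np.float32(255.0)
    dist2_white = (from_white**2).sum(axis=1)
    marked = dist2_white >= config.bg_delta**2

    labels = np.full(h * w, -1, dtype=np.int16)
    if marked.any():
        fw = from_white[marked]
        seg = (palette.rgb - 255.0).astype(np.float32)  # (n_colours, 3)
        seg_len2 = (seg * seg).sum(axis=1)
        proj = fw @ seg.T
        # t: position of each pixel's projection along each pressure segment
        t = np.clip(proj / seg_len2, config.min_pressure - 0.05, 1.0)
        resid = dist2_white[marked][:, None] - 2.0 * t * proj + t**2 * seg_len2[None, :]
        labels[marked] = np.argmin(resid, axis=1).astype(np.int16)
    lum = rgb2gray(image)
    return LabelMap(labels.reshape(h, w), lum, float(px_per_mm), palette)


def _cell_index(shape: tuple[int, int], px_per_mm: float, sheet: Sheet) -> np.ndarray:
    """Flat cell id of each pixel, by pixel-centre position in mm."""
    h, w = shape
    xs = (np.arange(w) + 0.5) / px_per_mm
    ys = (np.arange(h) + 0.5) / px_per_mm
    cc = np.minimum((xs / sheet.width_mm * sheet.grid_cols).astype(int), sheet.grid_cols - 1)
    rr = np.minimum((ys / sheet.height_mm * sheet.grid_rows).astype(int), sheet.grid_rows - 1)
    return rr[:, None] * sheet.grid_cols + cc[None, :]


def summarize_cells(labels: LabelMap, sheet: Sheet = Sheet()) -> CellSummary:
    """Marked-pixel fraction and colour set of every grid cell."""
    rows, cols = sheet.grid_rows, sheet.grid_cols
    cell = _cell_index(labels.shape, labels.px_per_mm, sheet)
    marked = labels.labels >= 0
    totals = np.bincount(cell.ravel(), minlength=rows * cols)
    hits = np.bincount(cell[marked], minlength=rows * cols)
    fraction = (hits / totals).reshape(rows, cols)
    colour_sets: list[list[set[int]]] = [[set() for _ in range(cols)] for _ in range(rows)]
    pairs = np.unique(np.column_stack([cell[marked], labels.labels[marked]]), axis=0)
    for c, colour in pairs:
        colour_sets[c // cols][c % cols].add(int(colour))
    return CellSummary(fraction > 0, fraction, colour_sets, sheet)


def coverage_rate(cells: CellSummary) -> float:
    """Fraction of grid cells containing at least one stroke."""
    return float(np.count_nonzero(cells.covered)) / cells.n_cells


def overlap_rate(cells: CellSummary) -> float:
    """Percentage of covered cells containing >= 2 crayon colours.

    Zero when nothing is covered.  (Expressed as percent of *covered*
    cells, so a fully multi-coloured drawing reads 100.)
    """
    covered = int(np.count_nonzero(cells.covered))
    if covered == 0:
        return 0.0
    multi = sum(len(s) >= 2 for row in cells.colour_sets for s in row)
    return 100.0 * multi / covered


def solid_colour_rate(cells: CellSummary) -> float:
    """Fraction of all grid cells marked over at least half their area."""
    return float(np.count_nonzero(cells.fraction >= 0.5)) / cells.n_cells


def count_colours(labels: LabelMap, min_pixels: int = 1) -> int:
    """Number of crayon colours with at least ``min_pixels`` pixels."""
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    marked = labels.labels >= 0
    counts = np.bincount(labels.labels[marked], minlength=len(labels.palette))
    return int(np.count_nonzero(counts >= min_pixels))


def main_colour(labels: LabelMap) -> int | None:
    """Colour with the largest marked area; ties to the lowest id."""
    marked = labels.labels >= 0
    if not marked.any():
        return None
    counts = np.bincount(labels.labels[marked], minlength=len(labels.palette))
    return int(np.argmax(counts))


def colour_spectrum_stats(labels: LabelMap) -> tuple[float, float]:
    """Mean and standard deviation of per-pixel luminance.

    Taken over the whole sheet: a blank sheet reads (1.0, 0.0), heavier
    filling lowers the mean, and stronger contrast raises the spread.
    """
    lum = labels.luminance
    return float(lum.mean()), float(lum.std())


def distance_to_centre(labels: LabelMap, sheet: Sheet = Sheet()) -> float:
    """Distance (mm) from the enclosing-ellipse centre to the sheet centre.

    The ellipse is the minimum-area ellipse enclosing all marked pixel
    centres; an empty drawing returns 0 by convention.
    """
    ii, jj = np.nonzero(labels.labels >= 0)
    if len(ii) == 0:
        return 0.0
    s = labels.px_per_mm
    pts = np.column_stack([(jj + 0.5) / s, (ii + 0.5) / s])
    centre = ellipse_centre(pts)
    return float(np.hypot(*(centre - np.array(sheet.centre))))


@dataclass(frozen=True)
class MetricVector:
    """The 12 per-drawing variables (11 quantitative + main colour)."""

    drawing_id: str
    individual: str
    season: str
    period: int
    coverage_rate: float
    overlap_rate: float
    n_colours: int
    fan: int
    circle: int
    triangle: int
    loop: int
    colour_mean: float
    colour_sd: float
    dist_centre_mm: float
    solid_colour_rate: float
    main_colour: int | None

    def __post_init__(self) -> None:
        if self.n_colours <= 1 and self.overlap_rate != 0.0:
            raise ValueError("overlap_rate must be 0 with at most one colour")
        if self.solid_colour_rate > self.coverage_rate + 1e-12:
            raise ValueError("solid_colour_rate cannot exceed coverage_rate")

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def extract_metrics(
    raster: RasterDrawing | np.ndarray,
    drawing: VectorDrawing,
    palette: Palette | None = None,
    sheet: Sheet | None = None,
    config: MetricConfig = MetricConfig(),
    px_per_mm: float | None = None,
) -> MetricVector:
    """All twelve variables of one drawing.

    Grid and colour variables come from the raster; shape counts come
    from the vector strokes.
    """
    sheet = sheet or drawing.sheet
    labels = build_label_map(raster, palette, config, px_per_mm)
    cells = summarize_cells(labels, sheet)
    mean, sd = colour_spectrum_stats(labels)
    shapes = count_shapes(drawing, config.shape)
    return MetricVector(
        drawing_id=drawing.meta.drawing_id,
        individual=drawing.meta.individual,
        season=drawing.meta.season,
        period=drawing.meta.period,
        coverage_rate=coverage_rate(cells),
        overlap_rate=overlap_rate(cells),
        n_colours=count_colours(labels, config.min_pixels),
        fan=shapes.fans,
        circle=shapes.circles,
        triangle=shapes.triangles,
        loop=shapes.loops,
        colour_mean=mean,
        colour_sd=sd,
        dist_centre_mm=distance_to_centre(labels, sheet),
        solid_colour_rate=solid_colour_rate(cells),
        main_colour=main_colour(labels),
    )
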