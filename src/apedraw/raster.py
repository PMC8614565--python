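"""Rendering vector drawings to pixel images.

Strokes are painted as disc-swept polylines: a pixel is marked when its
centre lies within half the stroke width of the stroke path.  Crayon
pressure ``p`` deposits the blend ``p * colour + (1 - p) * white``; the
sheet never darkens cumulatively, so repainting a pixel simply replaces
it (stroke list order, last on top).  Alongside the visible RGB image
the rasterizer keeps the true colour id per pixel and, independently of
paint order, the full set of stroke colours that touched each pixel —
the oracle used to validate colour labelling and overlap measurements.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .palette import Palette, Sheet
from .strokes import GroundTruth, StrokePath, VectorDrawing

__all__ = ["RasterDrawing", "rasterize"]

# Arc-length spacing (in pixels) of the disc-stamping samples; small
# enough that the painted band differs from the exact swept disc by
# well under half a pixel.
_SAMPLE_SPACING_PX = 0.35


@dataclass
class RasterDrawing:
    """Pixel rendering of a drawing plus per-pixel provenance.

    Attributes
    ----------
    image
        ``(H, W, 3)`` uint8 RGB image.
    px_per_mm
        Physical scale.
    true_labels
        ``(H, W)`` int16; visible colour id per pixel, -1 = background.
    membership
        ``(n_colours, H, W)`` bool; colour *c* touched the pixel at some
        point during painting, regardless of what covered it later.
    """

    image: np.ndarray
    px_per_mm: float
    true_labels: np.ndarray
    membership: np.ndarray
    sheet: Sheet
    palette: Palette

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def pixel_centres_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of each column, y of each row) of pixel centres, in mm."""
        h, w = self.image.shape[:2]
        s = self.px_per_mm
        return (np.arange(w) + 0.5) / s, (np.arange(h) + 0.5) / s


def _densify(points: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Subdivide each polyline segment to at most ``spacing_mm`` steps."""
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.hypot(*seg) / spacing_mm)))
        t = np.arange(1, n + 1)[:, None] / n
        out.append(a + t * seg)
    return np.concatenate(out)


def _stroke_mask(stroke: StrokePath, shape: tuple[int, int], s: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose centre is within width/2 of the path."""
    h, w = shape
    r = stroke.width_mm / 2.0
    samples = _densify(stroke.points, _SAMPLE_SPACING_PX / s)
    x0, y0 = samples.min(axis=0) - r
    x1, y1 = samples.max(axis=0) + r
    j0, j1 = max(0, int(np.floor(x0 * s - 0.5))), min(w - 1, int(np.ceil(x1 * s)))
    i0, i1 = max(0, int(np.floor(y0 * s - 0.5))), min(h - 1, int(np.ceil(y1 * s)))
    if j1 < j0 or i1 < i0:
        return np.empty(0, int), np.empty(0, int)
    xs = (np.arange(j0, j1 + 1) + 0.5) / s
    ys = (np.arange(i0, i1 + 1) + 0.5) / s
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    dist, _ = cKDTree(samples).query(pts, k=1, distance_upper_bound=r + 0.25 / s)
    near = np.isfinite(dist) & (dist <= r)
    ii, jj = np.divmod(np.flatnonzero(near), j1 - j0 + 1)
    return ii + i0, jj + j0


def rasterize(drawing: VectorDrawing, px_per_mm: float = 2.0, palette: Palette | None = None) -> RasterDrawing:
    """Render a vector drawing to an RGB raster.

    Parameters
    ----------
    drawing
        The drawing to paint; strokes are painted in list order, the
        last stroke on top.
    px_per_mm
        Resolution; the default of 2 px/mm renders the standard sheet
        to 544 x 484 pixels.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    if palette is None:
        from .palette import default_palette

        palette = default_palette()
    sheet = drawing.sheet
    w_px = round(sheet.width_mm * px_per_mm)
    h_px = round(sheet.height_mm * px_per_mm)
    image = np.full((h_px, w_px, 3), 255, dtype=np.uint8)
    true_labels = np.full((h_px, w_px), -1, dtype=np.int16)
    membership = np.zeros((len(palette), h_px, w_px), dtype=bool)
    ref = palette.rgb
    for stroke in drawing.strokes:
        ii, jj = _stroke_mask(stroke, (h_px, w_px), px_per_mm)
        if len(ii) == 0:
            continue
        p = stroke.pressure
        rgb = np.round(p * ref[stroke.colour_id] + (1.0 - p) * 255.0).astype(np.uint8)
        image[ii, jj] = rgb
        true_labels[ii, jj] = stroke.colour_id
        membership[stroke.colour_id, ii, jj] = True
    return RasterDrawing(image, px_per_mm, true_labels, membership, sheet, palette)


def _pixel_cell_index(raster: RasterDrawing) -> tuple[np.ndarray, np.ndarray]:
    """Cell (row, col) of every pixel, from its centre position in mm."""
    sheet = raster.sheet
    xs, ys = raster.pixel_centres_mm()
    cell_c = np.minimum((xs / sheet.width_mm * sheet.grid_cols).astype(int), sheet.grid_cols - 1)
    cell_r = np.minimum((ys / sheet.height_mm * sheet.grid_rows).astype(int), sheet.grid_rows - 1)
    return cell_r, cell_c


def fill_ground_truth(gt: GroundTruth, raster: RasterDrawing) -> GroundTruth:
    """Record per-cell coverage, colour sets and the main colour.

    Cell colour sets come in two flavours: ``cell_colours`` holds the
    colours *visible* in the final image while ``cell_colour_membership``
    holds every colour painted into the cell even if later covered.
    """
    sheet = raster.sheet
    rows, cols = sheet.grid_rows, sheet.grid_cols
    cell_r, cell_c = _pixel_cell_index(raster)
    flat_cell = cell_r[:, None] * cols + cell_c[None, :]

    marked = raster.true_labels >= 0
    totals = np.bincount(flat_cell.ravel(), minlength=rows * cols)
    hits = np.bincount(flat_cell[marked], minlength=rows * cols)
    gt.cell_fraction = (hits / totals).reshape(rows, cols)

    cell_colours: list[list[set[int]]] = [[set() for _ in range(cols)] for _ in range(rows)]
    pairs = np.unique(
        np.column_stack([flat_cell[marked], raster.true_labels[marked]]), axis=0
    )
    for cell, colour in pairs:
        cell_colours[cell // cols][cell % cols].add(int(colour))
    gt.cell_colours = cell_colours

    member_cells: list[list[set[int]]] = [[set() for _ in range(cols)] for _ in range(rows)]
    for cid in range(len(raster.palette)):
        touched = raster.membership[cid]
        if not touched.any():
            continue
        for cell in np.unique(flat_cell[touched]):
            member_cells[cell // cols][cell % cols].add(cid)
    gt.cell_colour_membership = member_cells

    counts = np.bincount(raster.true_labels[marked], minlength=len(raster.palette))
    gt.colours_used = {int(c) for c in np.flatnonzero(counts)}
    gt.main_colour = int(np.argmax(counts)) if counts.sum() else None
    return gt
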