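"""Vector drawing primitives: strokes, drawings, metadata and ground truth.

A drawing is an ordered list of :class:`StrokePath` objects (coloured
polylines with a width and a crayon pressure) on a :class:`Sheet`.  The
synthetic generator additionally emits a :class:`GroundTruth` record per
drawing — which shapes were planted into which strokes, which colours
are visible, and the exact per-cell pixel coverage — so every
measurement stage can be checked against known truth.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .palette import Sheet

__all__ = [
    "StrokePath",
    "DrawingMeta",
    "VectorDrawing",
    "GroundTruth",
    "season_of",
    "period_of",
    "STUDY_START",
    "N_PERIODS",
    "SEASONS",
]

SEASONS = ("winter", "spring", "summer", "autumn")

#: First day of period 1 of the longitudinal record.  The prolific
#: individual drew from mid-2006 until spring 2011; nineteen consecutive
#: 3-month periods starting here span that window.
STUDY_START = _dt.date(2006, 7, 1)
N_PERIODS = 19


def season_of(date: _dt.date) -> str:
    """Meteorological season of a date (Dec-Feb = winter, etc.)."""
    return SEASONS[(date.month % 12) // 3]


def period_of(date: _dt.date, start: _dt.date = STUDY_START) -> int:
    """1-based 3-month period index of ``date`` counted from ``start``."""
    months = (date.year - start.year) * 12 + (date.month - start.month)
    if months < 0:
        raise ValueError(f"date {date} precedes period calendar start {start}")
    return months // 3 + 1


def period_start(period: int, start: _dt.date = STUDY_START) -> _dt.date:
    months = start.month - 1 + 3 * (period - 1)
    return _dt.date(start.year + months // 12, months % 12 + 1, start.day)


@dataclass
class StrokePath:
    """A single crayon stroke: an open polyline with colour and pressure.

    Attributes
    ----------
    points
        ``(n, 2)`` array of (x, y) vertices in mm, n >= 2, consecutive
        vertices distinct, all inside the sheet.
    colour_id
        Palette index of the crayon used.
    width_mm
        Stroke width (crayon contact diameter).
    pressure
        Fraction in (0, 1]; 1 is a fully saturated mark, lower values
        deposit a paler blend of the crayon colour over the white sheet.
    """

    points: np.ndarray
    colour_id: int
    width_mm: float = 3.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 2:
            raise ValueError("a stroke needs at least 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive stroke points must be distinct")
        if not (0.0 < self.pressure <= 1.0):
            raise ValueError("pressure must be in (0, 1]")
        if self.width_mm <= 0:
            raise ValueError("width_mm must be positive")

    def validate_on(self, sheet: Sheet) -> None:
        x, y = self.points[:, 0], self.points[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() > sheet.width_mm or y.max() > sheet.height_mm:
            raise ValueError("stroke leaves the sheet bounds")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def translated(self, dx: float, dy: float) -> "StrokePath":
        return StrokePath(self.points + [dx, dy], self.colour_id, self.width_mm, self.pressure)

    def to_dict(self) -> dict:
        return {
            "points": [[round(float(x), 4), round(float(y), 4)] for x, y in self.points],
            "colour_id": int(self.colour_id),
            "width_mm": round(float(self.width_mm), 4),
            "pressure": round(float(self.pressure), 4),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrokePath":
        return cls(np.asarray(d["points"], dtype=float), d["colour_id"], d["width_mm"], d["pressure"])


@dataclass(frozen=True)
class DrawingMeta:
    drawing_id: str
    individual: str
    date: _dt.date
    damaged: bool = False

    @property
    def season(self) -> str:
        return season_of(self.date)

    @property
    def period(self) -> int:
        return period_of(self.date)


@dataclass
class VectorDrawing:
    """A drawing as an ordered stroke list plus its metadata."""

    strokes: list[StrokePath]
    sheet: Sheet
    meta: DrawingMeta

    def __post_init__(self) -> None:
        for s in self.strokes:
            s.validate_on(self.sheet)

    def __len__(self) -> int:
        return len(self.strokes)

    def to_json(self) -> str:
        payload = {
            "drawing_id": self.meta.drawing_id,
            "individual": self.meta.individual,
            "date": self.meta.date.isoformat(),
            "season": self.meta.season,
            "period": self.meta.period,
            "damaged": self.meta.damaged,
            "sheet": {
                "width_mm": self.sheet.width_mm,
                "height_mm": self.sheet.height_mm,
                "grid_rows": self.sheet.grid_rows,
                "grid_cols": self.sheet.grid_cols,
            },
            "strokes": [s.to_dict() for s in self.strokes],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "VectorDrawing":
        d = json.loads(text)
        sheet = Sheet(**d["sheet"])
        meta = DrawingMeta(
            d["drawing_id"], d["individual"], _dt.date.fromisoformat(d["date"]), d.get("damaged", False)
        )
        return cls([StrokePath.from_dict(s) for s in d["strokes"]], sheet, meta)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "VectorDrawing":
        return cls.from_json(Path(path).read_text())


@dataclass
class GroundTruth:
    """Known truth for one synthetic drawing.

    ``planted_shapes`` maps every deliberately constructed shape to the
    index of the stroke that carries it.  Cell-level fields are filled
    by the rasterizer and use *visible* (top-most paint) colours;
    ``cell_colour_membership`` instead records every stroke colour that
    touches a cell, independent of paint order.
    """

    planted_shapes: list[tuple[str, int]] = field(default_factory=list)
    colours_used: set[int] = field(default_factory=set)
    cell_fraction: np.ndarray | None = None        # (rows, cols) in [0, 1]
    cell_colours: list[list[set[int]]] | None = None
    cell_colour_membership: list[list[set[int]]] | None = None
    main_colour: int | None = None

    def shape_count(self, kind: str) -> int:
        return sum(1 for k, _ in self.planted_shapes if k == kind)

    @property
    def covered_cells(self) -> int:
        if self.cell_fraction is None:
            return 0
        return int(np.count_nonzero(self.cell_fraction > 0))

    def to_json(self) -> str:
        payload = {
            "planted_shapes": [[k, i] for k, i in self.planted_shapes],
            "colours_used": sorted(self.colours_used),
            "main_colour": self.main_colour,
            "cell_fraction": None
            if self.cell_fraction is None
            else [[round(float(v), 10) for v in row] for row in self.cell_fraction],
            "cell_colours": None
            if self.cell_colours is None
            else [[sorted(s) for s in row] for row in self.cell_colours],
            "cell_colour_membership": None
            if self.cell_colour_membership is None
            else [[sorted(s) for s in row] for row in self.cell_colour_membership],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_shapes=[(k, i) for k, i in d["planted_shapes"]],
            colours_used=set(d["colours_used"]),
            cell_fraction=None if d["cell_fraction"] is None else np.asarray(d["cell_fraction"]),
            cell_colours=None
            if d["cell_colours"] is None
            else [[set(s) for s in row] for row in d["cell_colours"]],
            cell_colour_membership=None
            if d["cell_colour_membership"] is None
            else [[set(s) for s in row] for row in d["cell_colour_membership"]],
            main_colour=d["main_colour"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_json(Path(path).read_text())
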