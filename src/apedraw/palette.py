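"""Crayon palette and drawing sheet geometry.

The study system is a box of 16 coloured wax crayons used on a white
272 x 242 mm paperboard.  Colours are identified by integer ids into a
:class:`Palette`; the sheet carries the physical size and the 10 x 10
analysis grid that all coverage metrics are defined on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Palette", "Sheet", "default_palette", "WHITE"]

#: Background paper colour (8-bit RGB).
WHITE = (255, 255, 255)


@dataclass(frozen=True)
class Palette:
    """An ordered set of crayon colours on a white background.

    Parameters
    ----------
    colours
        ``(colour_id, name, (r, g, b))`` triples.  Ids must be the
        positions ``0..n-1`` so they can double as array indices.
    background
        RGB of the blank sheet; must not be a member colour.
    """

    colours: tuple[tuple[int, str, tuple[int, int, int]], ...]
    background: tuple[int, int, int] = WHITE

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.colours]
        if ids != list(range(len(self.colours))):
            raise ValueError("colour ids must be consecutive 0..n-1")
        rgbs = [c[2] for c in self.colours]
        if len(set(rgbs)) != len(rgbs):
            raise ValueError("palette colours must be pairwise distinct")
        if self.background in rgbs:
            raise ValueError("background must not be a member colour")

    def __len__(self) -> int:
        return len(self.colours)

    @property
    def names(self) -> list[str]:
        return [c[1] for c in self.colours]

    @property
    def rgb(self) -> np.ndarray:
        """``(n, 3)`` float array of reference RGB values."""
        return np.asarray([c[2] for c in self.colours], dtype=float)

    def id_of(self, name: str) -> int:
        for cid, cname, _ in self.colours:
            if cname == name:
                return cid
        raise KeyError(name)

    def name_of(self, cid: int) -> str:
        return self.colours[cid][1]


# Reference RGB triples for the 16-crayon box.  Chosen so that every
# colour, blended over white at any pressure >= 0.35, (a) stays at least
# ~55 RGB units away from white and (b) remains closest to its own
# pressure segment (see gridmetrics.build_label_map).  The closest pair
# of chroma directions (black / dark_green) is still ~7 degrees apart.
_CRAYONS: tuple[tuple[str, tuple[int, int, int]], ...] = (
    ("red", (214, 40, 40)),
    ("orange", (245, 130, 20)),
    ("yellow", (250, 205, 15)),
    ("yellow_green", (160, 200, 40)),
    ("green", (25, 135, 55)),
    ("dark_green", (20, 80, 45)),
    ("teal", (0, 150, 140)),
    ("sky_blue", (100, 180, 240)),
    ("blue", (40, 70, 200)),
    ("navy", (25, 30, 100)),
    ("violet", (130, 55, 175)),
    ("pink", (240, 110, 175)),
    ("magenta", (195, 25, 125)),
    ("brown", (130, 75, 35)),
    ("olive", (125, 125, 30)),
    ("black", (30, 30, 30)),
)


def default_palette() -> Palette:
    """The 16-crayon palette used by the synthetic generator."""
    return Palette(tuple((i, n, rgb) for i, (n, rgb) in enumerate(_CRAYONS)))


@dataclass(frozen=True)
class Sheet:
    """Physical drawing sheet with its analysis grid.

    Coordinates are millimetres with the origin at the top-left corner,
    x rightward and y downward.  Grid cell ``(r, c)`` covers the
    half-open rectangle ``[c*W/cols, (c+1)*W/cols) x [r*H/rows,
    (r+1)*H/rows)``.
    """

    width_mm: float = 272.0
    height_mm: float = 242.0
    grid_rows: int = 10
    grid_cols: int = 10

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("sheet dimensions must be positive")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def centre(self) -> tuple[float, float]:
        return (self.width_mm / 2.0, self.height_mm / 2.0)

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width_mm and 0.0 <= y <= self.height_mm

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell containing the point ``(x, y)`` in mm."""
        c = min(int(x / self.width_mm * self.grid_cols), self.grid_cols - 1)
        r = min(int(y / self.height_mm * self.grid_rows), self.grid_rows - 1)
        return (r, c)
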