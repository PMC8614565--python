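"""Geometric classification of stroke shapes.

The four shape categories counted per drawing are defined on the vector
polyline of a single stroke:

* **fan pattern** — a zigzag stroke making at least three out-and-back
  passes whose legs subtend no more than 45 degrees;
* **circle** — a curved stroke that intersects itself without any
  distinct angle along the way;
* **loop** — a curved self-intersecting stroke with exactly one
  distinct angle;
* **triangle** — a closed ("flat") loop with three or more distinct
  angles joined by near-straight sides.

"Distinct angle" is operationalised as a turning angle of at least
``corner_angle_min`` (default 60 degrees) at a vertex of the
arc-length-resampled polyline, and an out-and-back reversal as a
turning angle of at least ``180 - max_fan_angle``.  The thresholds are
configurable through :class:`ShapeConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strokes import StrokePath, VectorDrawing

__all__ = [
    "ShapeConfig",
    "ShapeCounts",
    "Crossing",
    "turning_angles",
    "count_fan_round_trips",
    "detect_fan",
    "self_intersections",
    "classify_closed",
    "count_shapes",
]


@dataclass(frozen=True)
class ShapeConfig:
    """Thresholds of the shape classifier (angles in degrees, lengths mm)."""

    max_fan_angle: float = 45.0        # legs of a fan subtend at most this
    min_round_trips: int = 3           # fans need at least this many passes
    corner_angle_min: float = 60.0     # turning angle of a "distinct angle"
    resample_mm: float = 2.0           # arc-length resampling step
    gap_tol_mm: float = 3.0            # endpoint gap still counting as closed
    max_side_turn_deg: float = 100.0   # total non-corner turning tolerated
                                       # between triangle corners


@dataclass(frozen=True)
class ShapeCounts:
    fans: int = 0
    circles: int = 0
    triangles: int = 0
    loops: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"fan": self.fans, "circle": self.circles, "triangle": self.triangles, "loop": self.loops}


@dataclass(frozen=True)
class Crossing:
    """A transverse self-intersection of a stroke polyline."""

    seg_i: int
    t_i: float
    seg_j: int
    t_j: float
    point: tuple[float, float]
    angle_deg: float  # incidence angle between the branches, in [0, 90]


def _resample(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Vertex-preserving arc-length subdivision.

    Every original vertex is kept (so genuine corners survive exactly)
    and each segment is subdivided into equal pieces no longer than
    ``step_mm``; on densely sampled smooth curves this reduces to the
    identity while long straight segments gain evenly spaced interior
    vertices.
    """
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        n = max(1, int(np.ceil(np.hypot(*(b - a)) / step_mm)))
        t = np.arange(1, n + 1)[:, None] / n
        out.append(a + t * (b - a))
    return np.concatenate(out)


def _turns(points: np.ndarray) -> np.ndarray:
    """Signed turning angle (degrees) at each interior vertex."""
    d = np.diff(points, axis=0)
    a, b = d[:-1], d[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    return np.degrees(np.arctan2(cross, dot))


def turning_angles(path: StrokePath, resample_mm: float = 2.0) -> np.ndarray:
    """Turning angles of the resampled stroke polyline.

    Returns the signed angle, in ``(-180, 180]`` degrees, between
    successive direction vectors at every interior vertex of the
    resampled path.  A straight stroke returns all zeros.
    """
    if path.length_mm < 1e-9:
        raise ValueError("degenerate zero-length path")
    return _turns(_resample(path.points, resample_mm))


def count_fan_round_trips(path: StrokePath, config: ShapeConfig = ShapeConfig()) -> int:
    """Number of out-and-back passes of a zigzag stroke.

    A direction reversal is a vertex whose turning angle is at least
    ``180 - max_fan_angle`` in magnitude (i.e. the two legs subtend at
    most ``max_fan_angle``); ``r`` reversals bound ``floor((r + 1) / 2)``
    out-and-back passes.
    """
    turns = np.abs(turning_angles(path, config.resample_mm))
    reversals = int(np.count_nonzero(turns >= 180.0 - config.max_fan_angle - 1e-9))
    if reversals == 0:
        return 0
    return (reversals + 1) // 2


def detect_fan(path: StrokePath, config: ShapeConfig = ShapeConfig()) -> bool:
    """True when the stroke makes at least three fan round trips."""
    return count_fan_round_trips(path, config) >= config.min_round_trips


def self_intersections(path: StrokePath) -> list[Crossing]:
    """All transverse crossings between non-adjacent polyline segments.

    Endpoints shared by adjacent segments are not crossings; contacts
    exactly at a segment endpoint are likewise excluded (the generator
    never produces them, and for measured data they are a measure-zero
    coincidence).
    """
    pts = path.points
    n = len(pts) - 1
    if n < 3:
        return []
    a = pts[:-1]
    d = np.diff(pts, axis=0)
    ii, jj = np.triu_indices(n, k=2)
    di, dj = d[ii], d[jj]
    denom = di[:, 0] * dj[:, 1] - di[:, 1] * dj[:, 0]
    w = a[jj] - a[ii]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * dj[:, 1] - w[:, 1] * dj[:, 0]) / denom
        u = (w[:, 0] * di[:, 1] - w[:, 1] * di[:, 0]) / denom
    eps = 1e-12
    ok = (np.abs(denom) > 0) & (t > eps) & (t < 1 - eps) & (u > eps) & (u < 1 - eps)
    out: list[Crossing] = []
    for k in np.flatnonzero(ok):
        p = a[ii[k]] + t[k] * di[k]
        cosang = abs(np.dot(di[k], dj[k])) / (np.linalg.norm(di[k]) * np.linalg.norm(dj[k]))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        out.append(Crossing(int(ii[k]), float(t[k]), int(jj[k]), float(u[k]), (float(p[0]), float(p[1])), ang))
    return out


def _corner_stats(path: StrokePath, config: ShapeConfig, closed_by_gap: bool) -> tuple[int, float]:
    """(number of corners, total non-corner |turning|) of the stroke."""
    pts = _resample(path.points, config.resample_mm)
    turns = _turns(pts)
    if closed_by_gap:
        # closure angle between the last and first segment directions
        d_last = pts[-1] - pts[-2]
        d_first = pts[1] - pts[0]
        cross = d_last[0] * d_first[1] - d_last[1] * d_first[0]
        dot = float(np.dot(d_last, d_first))
        turns = np.append(turns, np.degrees(np.arctan2(cross, dot)))
    corners = np.abs(turns) >= config.corner_angle_min
    side_turn = float(np.abs(turns[~corners]).sum())
    return int(np.count_nonzero(corners)), side_turn


def classify_closed(path: StrokePath, config: ShapeConfig = ShapeConfig()) -> str:
    """Classify a stroke as ``circle``, ``loop``, ``triangle`` or ``none``.

    A stroke qualifies as closed when it intersects itself or when its
    endpoints meet within ``gap_tol_mm``.  Closed strokes are then told
    apart by their distinct angles: none at all is a circle, exactly one
    is a loop, and three or more joined by near-straight sides (total
    intermediate turning below ``max_side_turn_deg``) is a triangle.
    """
    crossings = self_intersections(path)
    gap = float(np.linalg.norm(path.points[-1] - path.points[0]))
    closed_by_gap = gap <= config.gap_tol_mm
    if not crossings and not closed_by_gap:
        return "none"
    n_corners, side_turn = _corner_stats(path, config, closed_by_gap)
    if n_corners == 0:
        return "circle"
    if n_corners == 1:
        return "loop"
    if n_corners >= 3 and side_turn <= config.max_side_turn_deg:
        return "triangle"
    return "none"


def classify_stroke(path: StrokePath, config: ShapeConfig = ShapeConfig()) -> tuple[bool, str]:
    """(is_fan, closed_class) of one stroke.

    A stroke detected as a fan is not additionally assigned a closed
    class: any self-contact of a zigzag lies between its reversal legs
    and would otherwise double-count the same mark.
    """
    fan = detect_fan(path, config)
    closed = "none" if fan else classify_closed(path, config)
    return fan, closed


def count_shapes(drawing: VectorDrawing, config: ShapeConfig = ShapeConfig()) -> ShapeCounts:
    """Aggregate per-stroke shape classes over a drawing."""
    fans = circles = triangles = loops = 0
    for stroke in drawing.strokes:
        fan, closed = classify_stroke(stroke, config)
        fans += fan
        circles += closed == "circle"
        triangles += closed == "triangle"
        loops += closed == "loop"
    return ShapeCounts(fans, circles, triangles, loops)
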