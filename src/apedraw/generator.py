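"""Synthetic drawing generator with known ground truth.

Emulates a corpus of crayon drawings by five captive orang-utans: each
individual has a distinct style profile (filling intensity, colour
preference over the 16-crayon box, pen pressure, shape repertoire), and
one prolific individual carries a longitudinal record across nineteen
3-month periods with a declining filling trend and a winter deficit.
Every drawing is emitted together with a :class:`GroundTruth` record of
the planted shapes, the colours used and (after rasterization) the
exact per-cell pixel coverage, so the measurement and statistics stages
can be validated against known truth.
"""
from __future__ import annotations

import csv
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .palette import Palette, Sheet, default_palette
from .raster import fill_ground_truth, rasterize
from .strokes import (
    N_PERIODS,
    DrawingMeta,
    GroundTruth,
    StrokePath,
    VectorDrawing,
    period_of,
    period_start,
    season_of,
)

__all__ = [
    "StyleProfile",
    "make_fan_stroke",
    "make_closed_shape",
    "sample_drawing",
    "make_dataset",
    "default_profiles",
    "default_counts",
    "colour_weights",
]

_MARGIN_MM = 2.0  # strokes keep this far from the sheet edge


def colour_weights(palette: Palette, prefs: dict[str, float]) -> np.ndarray:
    """Preference weights over the palette.

    Named colours get the stated weights; the remaining mass is spread
    uniformly over the other crayons.  Weights must sum to at most 1.
    """
    w = np.zeros(len(palette))
    for name, p in prefs.items():
        w[palette.id_of(name)] = p
    rest = 1.0 - w.sum()
    if rest < -1e-9:
        raise ValueError("preference weights exceed 1")
    others = w == 0
    if others.any():
        w[others] = max(rest, 0.0) / others.sum()
    return w / w.sum()


@dataclass(frozen=True)
class StyleProfile:
    """Drawing-style parameters of one individual.

    Rates are per-drawing Poisson means; the filling multiplier
    ``exp(period_trend * (period - 10) + season_offsets[season])``
    scales the meander and fan rates, planting the longitudinal
    structure that the statistics stage must recover.
    """

    individual: str
    meander_rate: float = 6.0
    shape_rates: dict[str, float] = field(
        default_factory=lambda: {"fan": 0.8, "loop": 0.4, "circle": 0.1, "triangle": 0.15}
    )
    colour_prefs: dict[str, float] = field(default_factory=dict)
    dominant_focus: float = 0.7     # share of strokes forced to the drawing's dominant colour
    pressure_range: tuple[float, float] = (0.5, 0.9)
    width_range_mm: tuple[float, float] = (2.5, 4.5)
    spread_mm: float = 45.0         # s.d. of stroke anchors around the sheet centre
    meander_steps: tuple[int, int] = (15, 45)
    fan_leg_mm: tuple[float, float] = (18.0, 45.0)
    shape_size_mm: tuple[float, float] = (18.0, 40.0)
    period_trend: float = 0.0       # log-multiplier of filling per 3-month period
    season_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.meander_rate < 0 or any(v < 0 for v in self.shape_rates.values()):
            raise ValueError("rates must be non-negative")
        lo, hi = self.pressure_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("pressure range must lie in (0, 1]")

    def weights(self, palette: Palette) -> np.ndarray:
        return colour_weights(palette, self.colour_prefs)

    def filling_multiplier(self, date: _dt.date) -> float:
        period = period_of(date)
        return math.exp(
            self.period_trend * (period - (N_PERIODS + 1) / 2)
            + self.season_offsets.get(season_of(date), 0.0)
        )


# ---------------------------------------------------------------------------
# planted shape constructions
# ---------------------------------------------------------------------------

def _clip_to_sheet(points: np.ndarray, sheet: Sheet) -> np.ndarray:
    pts = points.copy()
    pts[:, 0] = np.clip(pts[:, 0], _MARGIN_MM, sheet.width_mm - _MARGIN_MM)
    pts[:, 1] = np.clip(pts[:, 1], _MARGIN_MM, sheet.height_mm - _MARGIN_MM)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
    return pts[keep]


def make_fan_stroke(
    anchor: tuple[float, float],
    leg_length: float,
    round_trips: int,
    spread_angle: float,
    rng: np.random.Generator,
    sheet: Sheet = Sheet(),
    colour_id: int = 0,
    width_mm: float = 3.0,
    pressure: float = 0.8,
    base_angle: float | None = None,
) -> StrokePath:
    """A zigzag stroke making ``round_trips`` out-and-back passes.

    Legs radiate from a (slightly jittered) anchor towards tips whose
    directions stay within a cone of ``spread_angle`` degrees, so every
    pair of adjacent legs subtends at most ``spread_angle``; the
    polyline has exactly ``2 * round_trips - 1`` interior
    direction-reversal vertices.
    """
    if round_trips < 1:
        raise ValueError("round_trips must be >= 1")
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if not (0 < spread_angle <= 45):
        raise ValueError("spread_angle must be in (0, 45] degrees")
    if not sheet.contains(*anchor):
        raise ValueError(f"invalid geometry: anchor {anchor} outside sheet")
    if base_angle is None:
        base_angle = float(rng.uniform(0.0, 360.0))
    half = math.radians(spread_angle) / 2.0 * 0.9
    base = math.radians(base_angle)
    anchor = np.asarray(anchor, dtype=float)
    pts = [anchor]
    theta = base + rng.uniform(-half, half)
    for k in range(round_trips):
        length = leg_length * rng.uniform(0.85, 1.0)
        tip = pts[-1] + length * np.array([math.cos(theta), math.sin(theta)])
        pts.append(tip)
        back = anchor + rng.uniform(-0.8, 0.8, size=2)
        pts.append(back)
        # next leg direction: bounded step inside the cone, so adjacent
        # legs never subtend more than spread_angle
        theta = float(np.clip(theta + rng.uniform(-half, half) - base, -half, half) + base)
    return StrokePath(_clip_to_sheet(np.asarray(pts), sheet), colour_id, width_mm, pressure)


def _smooth_radial_noise(theta: np.ndarray, rng: np.random.Generator, amplitude: float = 0.01) -> np.ndarray:
    """Low-frequency multiplicative radius noise; smooth by construction."""
    out = np.zeros_like(theta)
    for k in (1, 2, 3):
        out += amplitude * rng.uniform(0.2, 1.0) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return out


def _circle_points(anchor: np.ndarray, size_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Closed curve whose tail crosses the main arc once, with no corner.

    The path runs 410 degrees at base radius; over the final 80 degrees
    the radius dips inside and climbs back out, crossing the first arc
    transversally exactly once (the radial excursion dominates the
    smooth low-frequency jitter, keeping the crossing unique).
    """
    r0 = size_mm / 2.0
    step = min(4.0, math.degrees(1.0 / r0))
    theta_deg = np.arange(0.0, 410.0 + step, step)
    h = np.interp(theta_deg, [0.0, 330.0, 350.0, 371.3, 410.0], [0.0, 0.0, -0.15, 0.0, 0.15])
    # small secular drift: keeps the overlapping branches from retracing
    # exactly the same points, so the crossing is a generic transverse one
    h = h + 0.012 * (theta_deg / 410.0 - 0.5)
    theta = np.radians(theta_deg + rng.uniform(0.0, 360.0))
    r = r0 * (1.0 + h + _smooth_radial_noise(theta, rng))
    return anchor + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _loop_points(anchor: np.ndarray, size_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Balloon-on-a-string loop: one corner at the apex, one crossing.

    Two straight legs meet at the apex with a 60-degree opening; a
    circular arc leaves the second leg nearly tangentially, swings
    around the far side and crosses the first (slightly longer) leg
    transversally before stopping.
    """
    L = size_mm * 0.55
    phi = rng.uniform(0.0, 2 * np.pi)
    gamma = math.radians(rng.uniform(52.0, 68.0))
    u1 = np.array([math.cos(phi - gamma / 2), math.sin(phi - gamma / 2)])
    u2 = np.array([math.cos(phi + gamma / 2), math.sin(phi + gamma / 2)])
    b = np.array([math.cos(phi), math.sin(phi)])
    apex = anchor - L * b * 0.5
    start = apex + 1.35 * L * u1
    q = apex + L * u2
    centre = apex + L * b
    rho = float(np.linalg.norm(q - centre))
    ang_q = math.atan2(*(q - centre)[::-1])
    ang_x = math.atan2(*((apex + L * u1) - centre)[::-1])  # crossing point on leg 1
    ang_far = math.atan2(*b[::-1])                          # far side of the arc circle
    ccw = lambda a, b_: (b_ - a) % (2 * np.pi)
    if ccw(ang_q, ang_far) <= ccw(ang_q, ang_x):
        sweep = ccw(ang_q, ang_x) + math.radians(14.0)      # counterclockwise via far side
    else:
        sweep = -(ccw(ang_x, ang_q) + math.radians(14.0))   # clockwise via far side
    n_arc = max(24, int(abs(sweep) / math.radians(3.0)))
    ang = ang_q + np.linspace(0.0, 1.0, n_arc) * sweep
    arc = centre + rho * np.column_stack([np.cos(ang), np.sin(ang)])
    legs = np.concatenate([
        start + np.linspace(0, 1, 12)[:, None] * (apex - start),
        apex + np.linspace(1.0 / 10, 1, 10)[:, None] * (q - apex),
    ])
    return np.concatenate([legs, arc[1:]])


def _triangle_points(anchor: np.ndarray, size_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Near-closed path of three near-straight sides.

    The endpoints stop about 1 mm apart (within the classifier's
    endpoint-closure tolerance); vertex placement jitter is bounded so
    every interior angle stays a corner without reaching the fan
    reversal regime.
    """
    r = size_mm / 2.0
    phi0 = rng.uniform(0.0, 2 * np.pi)
    angs = phi0 + np.radians([0.0, 120.0, 240.0] + rng.uniform(-10.0, 10.0, size=3))
    verts = anchor + r * np.column_stack([np.cos(angs), np.sin(angs)])
    pts = [verts[0]]
    for a, b in [(verts[0], verts[1]), (verts[1], verts[2]), (verts[2], verts[0])]:
        side = b - a
        length = np.linalg.norm(side)
        normal = np.array([-side[1], side[0]]) / length
        n = max(6, int(length / 3.0))
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        wobble = 0.1 * np.sin(np.pi * t * 2 + rng.uniform(0, 2 * np.pi)) * rng.uniform(0.3, 1.0)
        seg = a + t[:, None] * side + wobble[:, None] * normal
        seg[-1] = b
        pts.append(seg)
    path = np.concatenate([[pts[0]], *pts[1:]])
    closing = path[-1] - path[-2]
    path[-1] = path[-1] - closing / np.linalg.norm(closing) * 1.0  # stop ~1 mm short
    return path


def make_closed_shape(
    kind: str,
    anchor: tuple[float, float],
    size_mm: float,
    rng: np.random.Generator,
    sheet: Sheet = Sheet(),
    colour_id: int = 0,
    width_mm: float = 3.0,
    pressure: float = 0.8,
) -> StrokePath:
    """A stroke carrying one planted closed shape (circle, loop, triangle)."""
    anchor_arr = np.asarray(anchor, dtype=float)
    if not sheet.contains(*anchor):
        raise ValueError(f"invalid geometry: anchor {anchor} outside sheet")
    if kind == "circle":
        pts = _circle_points(anchor_arr, size_mm, rng)
    elif kind == "loop":
        pts = _loop_points(anchor_arr, size_mm, rng)
    elif kind == "triangle":
        pts = _triangle_points(anchor_arr, size_mm, rng)
    else:
        raise ValueError(f"unknown closed shape kind: {kind!r}")
    return StrokePath(_clip_to_sheet(pts, sheet), colour_id, width_mm, pressure)


def _meander_points(
    anchor: np.ndarray, n_steps: int, rng: np.random.Generator, sheet: Sheet
) -> np.ndarray:
    """Smooth wandering stroke: persistent direction, gentle turning.

    Per-step turning is small (clipped at 30 degrees) so a meander
    never contains a distinct angle or a fan reversal; near the sheet
    edge the heading is steered back toward the interior instead of
    being reflected, which would create a spurious corner.
    """
    step = 4.0
    theta = rng.uniform(0.0, 2 * np.pi)
    pos = anchor.copy()
    pts = [pos.copy()]
    centre = np.array(sheet.centre)
    for _ in range(n_steps):
        turn = np.clip(rng.normal(0.0, math.radians(8.0)), -math.radians(30.0), math.radians(30.0))
        margin = 14.0
        near_edge = (
            pos[0] < margin
            or pos[1] < margin
            or pos[0] > sheet.width_mm - margin
            or pos[1] > sheet.height_mm - margin
        )
        if near_edge:
            want = math.atan2(*(centre - pos)[::-1])
            diff = (want - theta + np.pi) % (2 * np.pi) - np.pi
            turn = np.clip(diff, -math.radians(28.0), math.radians(28.0))
        theta += turn
        pos = pos + step * np.array([math.cos(theta), math.sin(theta)])
        pts.append(pos.copy())
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# drawing sampling
# ---------------------------------------------------------------------------

def _sample_anchor(rng: np.random.Generator, sheet: Sheet, spread: float, inset: float) -> np.ndarray:
    centre = np.array(sheet.centre)
    for _ in range(64):
        p = rng.normal(centre, spread)
        if inset <= p[0] <= sheet.width_mm - inset and inset <= p[1] <= sheet.height_mm - inset:
            return p
    return centre.copy()


def sample_drawing(
    profile: StyleProfile,
    date: _dt.date,
    rng: np.random.Generator,
    sheet: Sheet = Sheet(),
    palette: Palette | None = None,
    drawing_id: str = "d0000",
) -> tuple[VectorDrawing, GroundTruth]:
    """Draw one synthetic drawing from a style profile.

    Stroke counts are Poisson draws scaled by the profile's filling
    multiplier for the date; each drawing first samples a dominant
    crayon from the preference weights and then biases stroke colours
    toward it, so the per-drawing main colour follows the preference
    distribution.  Deterministic given the ``rng`` state.
    """
    palette = palette or default_palette()
    weights = profile.weights(palette)
    mult = profile.filling_multiplier(date)
    dominant = int(rng.choice(len(palette), p=weights))

    def draw_colour() -> int:
        if rng.random() < profile.dominant_focus:
            return dominant
        return int(rng.choice(len(palette), p=weights))

    def draw_pressure() -> float:
        return float(rng.uniform(*profile.pressure_range))

    def draw_width() -> float:
        return float(rng.uniform(*profile.width_range_mm))

    strokes: list[StrokePath] = []
    planted: list[tuple[str, int | None]] = []  # stroke index fixed after shuffle

    n_meander = rng.poisson(profile.meander_rate * mult)
    n_fans = rng.poisson(profile.shape_rates.get("fan", 0.0) * mult)
    kinds = ["meander"] * n_meander + ["fan"] * n_fans
    for kind in ("loop", "circle", "triangle"):
        kinds += [kind] * rng.poisson(profile.shape_rates.get(kind, 0.0))

    tagged: list[tuple[str, StrokePath]] = []
    for kind in kinds:
        if kind == "fan":
            leg = rng.uniform(*profile.fan_leg_mm)
            anchor = _sample_anchor(rng, sheet, profile.spread_mm, leg + _MARGIN_MM)
            stroke = make_fan_stroke(
                tuple(anchor), leg, int(rng.integers(3, 6)), float(rng.uniform(20.0, 42.0)),
                rng, sheet, draw_colour(), draw_width(), draw_pressure(),
            )
        elif kind in ("loop", "circle", "triangle"):
            size = rng.uniform(*profile.shape_size_mm)
            anchor = _sample_anchor(rng, sheet, profile.spread_mm, size + _MARGIN_MM)
            stroke = make_closed_shape(
                kind, tuple(anchor), size, rng, sheet, draw_colour(), draw_width(), draw_pressure()
            )
        else:
            anchor = _sample_anchor(rng, sheet, profile.spread_mm, 16.0)
            n_steps = int(rng.integers(*profile.meander_steps))
            stroke = StrokePath(
                _clip_to_sheet(_meander_points(anchor, n_steps, rng, sheet), sheet),
                draw_colour(), draw_width(), draw_pressure(),
            )
        tagged.append((kind, stroke))

    order = rng.permutation(len(tagged))
    strokes = [tagged[i][1] for i in order]
    planted_shapes = [
        (tagged[i][0], int(pos)) for pos, i in enumerate(order) if tagged[i][0] != "meander"
    ]
    planted_shapes.sort(key=lambda ks: ks[1])

    meta = DrawingMeta(drawing_id, profile.individual, date)
    drawing = VectorDrawing(strokes, sheet, meta)
    gt = GroundTruth(planted_shapes=planted_shapes, colours_used={s.colour_id for s in strokes})
    return drawing, gt


# ---------------------------------------------------------------------------
# default study population
# ---------------------------------------------------------------------------

def default_profiles() -> dict[str, StyleProfile]:
    """Style profiles of the five emulated individuals.

    Tuned so that the population coverage rate lands near 50%, the
    overlap rate near 20% and the mean number of colours near 3, with
    the prolific longitudinal individual (Molly) filling most, pressing
    least, and carrying a declining period trend plus a winter deficit;
    Kiki is the opposite pole (few, small, hard-pressed, single-colour
    marks).
    """
    return {
        "Molly": StyleProfile(
            individual="Molly",
            meander_rate=11.0,
            shape_rates={"fan": 1.8, "loop": 1.0, "circle": 0.35, "triangle": 0.4},
            colour_prefs={"green": 0.21, "pink": 0.14, "violet": 0.10, "red": 0.08},
            dominant_focus=0.8,
            pressure_range=(0.35, 0.6),
            width_range_mm=(2.5, 5.0),
            spread_mm=70.0,
            meander_steps=(20, 55),
            period_trend=-0.045,
            season_offsets={"winter": -0.5},
        ),
        "Gypsy": StyleProfile(
            individual="Gypsy",
            meander_rate=5.0,
            shape_rates={"fan": 0.7, "loop": 0.3, "circle": 0.12, "triangle": 0.15},
            colour_prefs={"red": 0.40, "blue": 0.12, "yellow": 0.10},
            pressure_range=(0.6, 0.9),
            spread_mm=40.0,
        ),
        "Julie": StyleProfile(
            individual="Julie",
            meander_rate=3.5,
            shape_rates={"fan": 0.4, "loop": 0.25, "circle": 0.1, "triangle": 0.1},
            colour_prefs={"red": 0.33, "orange": 0.14, "sky_blue": 0.10},
            pressure_range=(0.55, 0.85),
            spread_mm=35.0,
        ),
        "Yuki": StyleProfile(
            individual="Yuki",
            meander_rate=7.5,
            shape_rates={"fan": 1.2, "loop": 0.55, "circle": 0.15, "triangle": 0.2},
            colour_prefs={"red": 0.37, "green": 0.12, "violet": 0.1},
            pressure_range=(0.5, 0.8),
            spread_mm=48.0,
        ),
        "Kiki": StyleProfile(
            individual="Kiki",
            meander_rate=2.2,
            shape_rates={"fan": 0.45, "loop": 0.15, "circle": 0.1, "triangle": 0.1},
            colour_prefs={"green": 0.27, "blue": 0.15, "black": 0.12},
            dominant_focus=0.92,
            pressure_range=(0.85, 1.0),
            width_range_mm=(2.0, 3.5),
            spread_mm=26.0,
            meander_steps=(10, 30),
        ),
    }


def default_counts() -> dict[str, int]:
    """Analysed drawings per individual in the emulated study (sums to 790)."""
    return {"Gypsy": 26, "Julie": 16, "Yuki": 32, "Kiki": 60, "Molly": 656}


def _longitudinal_dates(n: int, rng: np.random.Generator) -> list[_dt.date]:
    """Period-balanced dates: n spread as evenly as possible over the 19
    3-month periods (round-robin, so the first ``n % 19`` periods get one
    extra), uniform day within each period."""
    per = [n // N_PERIODS + (1 if p < n % N_PERIODS else 0) for p in range(N_PERIODS)]
    dates = []
    for p, k in enumerate(per, start=1):
        start = period_start(p)
        end = period_start(p + 1)
        span = (end - start).days
        offsets = sorted(int(d) for d in rng.integers(0, span, size=k))
        dates.extend(start + _dt.timedelta(days=o) for o in offsets)
    return dates


def _uniform_dates(n: int, rng: np.random.Generator) -> list[_dt.date]:
    start = period_start(1)
    span = (period_start(N_PERIODS + 1) - start).days
    return sorted(start + _dt.timedelta(days=int(d)) for d in rng.integers(0, span, size=n))


def make_dataset(
    profiles: dict[str, StyleProfile] | None = None,
    counts: dict[str, int] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    px_per_mm: float = 2.0,
    render: bool = True,
    longitudinal: str = "Molly",
    sheet: Sheet = Sheet(),
    palette: Palette | None = None,
) -> tuple[list[tuple[VectorDrawing, GroundTruth]], list[dict]]:
    """Generate a full synthetic dataset.

    The longitudinal individual's drawings are balanced across the 19
    3-month periods (emulating period-balanced subsampling of a large
    archive); everyone else draws on dates spread uniformly over the
    study window.  With ``out_dir`` set, writes one PNG, one stroke
    JSON and one ground-truth JSON per drawing plus a manifest CSV;
    byte-identical across runs with the same seed.

    Returns the (drawing, ground truth) pairs and the manifest rows.
    """
    profiles = profiles if profiles is not None else default_profiles()
    counts = counts if counts is not None else default_counts()
    if len(set(profiles)) != len(profiles):
        raise ValueError("duplicate individual ids")
    unknown = set(counts) - set(profiles)
    if unknown:
        raise ValueError(f"counts given for unknown individuals: {sorted(unknown)}")
    palette = palette or default_palette()
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    out: list[tuple[VectorDrawing, GroundTruth]] = []
    manifest: list[dict] = []
    individuals = sorted(counts)
    seeds = master.spawn(len(individuals))
    for ind, ind_seed in zip(individuals, seeds):
        n = counts[ind]
        if n < 0:
            raise ValueError("counts must be >= 0")
        rng = np.random.default_rng(ind_seed)
        dates = (
            _longitudinal_dates(n, rng) if ind == longitudinal else _uniform_dates(n, rng)
        )
        for i, date in enumerate(dates):
            did = f"{ind}_{i:04d}"
            drawing, gt = sample_drawing(
                profiles[ind], date, rng, sheet, palette, drawing_id=did
            )
            if render:
                raster = rasterize(drawing, px_per_mm, palette)
                fill_ground_truth(gt, raster)
                if out_dir is not None:
                    from PIL import Image

                    Image.fromarray(raster.image).save(Path(out_dir) / f"{did}.png")
            out.append((drawing, gt))
            manifest.append(
                {
                    "drawing_id": did,
                    "individual": ind,
                    "date": date.isoformat(),
                    "season": drawing.meta.season,
                    "period": drawing.meta.period,
                }
            )
    if out_dir is not None:
        out_path = Path(out_dir)
        for drawing, gt in out:
            drawing.save(out_path / f"{drawing.meta.drawing_id}.strokes.json")
            gt.save(out_path / f"{drawing.meta.drawing_id}.truth.json")
        with open(out_path / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["drawing_id", "individual", "date", "season", "period"]
            )
            writer.writeheader()
            writer.writerows(manifest)
    return out, manifest
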