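"""Classify planted stroke shapes from their vector polylines.

Builds one stroke of each kind — a fan (zigzag of out-and-back passes
subtending <= 45 degrees), a circle (self-intersecting curve without a
distinct angle), a loop (one distinct angle) and a triangle (closed
path of three near-straight sides) — and runs the classifier on each.
"""
import numpy as np

from apedraw import make_closed_shape, make_fan_stroke
from apedraw.shapes import classify_stroke, count_fan_round_trips, self_intersections

rng = np.random.default_rng(0)

fan = make_fan_stroke(anchor=(136, 121), leg_length=35, round_trips=4, spread_angle=30, rng=rng)
shapes = {"fan": fan}
for kind in ("circle", "loop", "triangle"):
    shapes[kind] = make_closed_shape(kind, anchor=(136, 121), size_mm=32, rng=rng)

for kind, stroke in shapes.items():
    is_fan, closed = classify_stroke(stroke)
    label = "fan" if is_fan else closed
    crossings = len(self_intersections(stroke))
    print(
        f"planted {kind:8s} -> classified {label:8s} "
        f"({len(stroke.points)} vertices, {crossings} self-crossing(s), "
        f"{count_fan_round_trips(stroke)} fan round trips)"
    )

# Each line should report the planted kind classified as itself: the fan
# by its >= 3 reversal passes, the circle by a crossing with no corner,
# the loop by its single corner, the triangle by three corners joined by
# straight sides.
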