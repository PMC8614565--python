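"""Measure one synthetic drawing: the 12 per-drawing variables.

Samples a single drawing from the prolific individual's style profile,
renders it at 2 px/mm, and extracts the full metric vector — grid
coverage, colour statistics, enclosing-ellipse centring and shape
counts.
"""
import datetime as dt

import numpy as np

from apedraw import default_palette, default_profiles, extract_metrics, rasterize, sample_drawing

rng = np.random.default_rng(42)
profile = default_profiles()["Molly"]
drawing, truth = sample_drawing(profile, dt.date(2008, 7, 15), rng, drawing_id="example")
raster = rasterize(drawing, px_per_mm=2.0)
m = extract_metrics(raster, drawing)

palette = default_palette()
print(f"drawing {m.drawing_id} by {m.individual} ({m.season}, period {m.period})")
print(f"  strokes drawn              : {len(drawing.strokes)}")
print(f"  coverage rate              : {m.coverage_rate:.2f}   (fraction of the 100 grid cells marked)")
print(f"  overlap rate               : {m.overlap_rate:.1f}%  (covered cells holding >= 2 colours)")
print(f"  solid colour rate          : {m.solid_colour_rate:.2f}   (cells >= 50% filled)")
print(f"  colours used               : {m.n_colours}")
print(f"  colour spectrum mean / sd  : {m.colour_mean:.3f} / {m.colour_sd:.3f}  (1 = blank white sheet)")
print(f"  distance to centre         : {m.dist_centre_mm:.1f} mm (enclosing-ellipse centre vs sheet centre)")
print(f"  shapes (fan/circle/tri/loop): {m.fan}/{m.circle}/{m.triangle}/{m.loop}")
main = "none" if m.main_colour is None else palette.name_of(m.main_colour)
print(f"  main colour                : {main}")
print(f"  planted shapes (truth)     : {[k for k, _ in truth.planted_shapes]}")
# A heavy filler like this profile typically covers over half the grid
# with several colours at low pressure (high colour mean, modest sd).
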