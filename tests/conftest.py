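import datetime as dt

import numpy as np
import pytest

from apedraw.generator import default_profiles, sample_drawing
from apedraw.palette import Sheet, default_palette
from apedraw.raster import fill_ground_truth, rasterize


@pytest.fixture(scope="session")
def palette():
    return default_palette()


@pytest.fixture(scope="session")
def sheet():
    return Sheet()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rendered_drawings():
    """A small batch of rendered drawings with filled ground truth,
    spanning all five default profiles."""
    rng = np.random.default_rng(99)
    out = []
    profiles = default_profiles()
    for name in sorted(profiles):
        for i in range(3):
            d, gt = sample_drawing(
                profiles[name], dt.date(2008, 3 + i, 15), rng, drawing_id=f"{name}_{i}"
            )
            raster = rasterize(d, px_per_mm=1.0)
            fill_ground_truth(gt, raster)
            out.append((d, gt, raster))
    return out
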