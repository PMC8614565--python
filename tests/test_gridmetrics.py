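import datetime as dt

import numpy as np
import pytest

from apedraw.gridmetrics import (
    CellSummary,
    MetricConfig,
    MetricVector,
    build_label_map,
    colour_spectrum_stats,
    count_colours,
    coverage_rate,
    distance_to_centre,
    extract_metrics,
    main_colour,
    overlap_rate,
    solid_colour_rate,
    summarize_cells,
)
from apedraw.palette import Sheet, default_palette
from apedraw.raster import rasterize
from apedraw.strokes import DrawingMeta, StrokePath, VectorDrawing

A_DATE = dt.date(2008, 7, 15)


def drawing_of(strokes, sheet=None):
    return VectorDrawing(strokes, sheet or Sheet(), DrawingMeta("d", "x", A_DATE))


def cells_oracle(labels, sheet):
    """Independent per-cell route: python loop over cells, np.unique per
    block, instead of the bincount/pair path of summarize_cells."""
    h, w = labels.labels.shape
    s = labels.px_per_mm
    frac = np.zeros((sheet.grid_rows, sheet.grid_cols))
    sets = [[set() for _ in range(sheet.grid_cols)] for _ in range(sheet.grid_rows)]
    xs = (np.arange(w) + 0.5) / s
    ys = (np.arange(h) + 0.5) / s
    col_of = np.minimum((xs / sheet.width_mm * sheet.grid_cols).astype(int), sheet.grid_cols - 1)
    row_of = np.minimum((ys / sheet.height_mm * sheet.grid_rows).astype(int), sheet.grid_rows - 1)
    for r in range(sheet.grid_rows):
        for c in range(sheet.grid_cols):
            block = labels.labels[np.ix_(row_of == r, col_of == c)]
            frac[r, c] = (block >= 0).sum() / block.size
            sets[r][c] = set(int(v) for v in np.unique(block) if v >= 0)
    return frac, sets


class TestLabelMap:
    def test_blank_sheet_is_all_background(self):
        r = rasterize(drawing_of([]), px_per_mm=1.0)
        lm = build_label_map(r)
        assert (lm.labels == -1).all()
        assert lm.luminance.max() == pytest.approx(1.0)

    def test_pure_palette_colours_label_exactly(self, palette):
        img = np.full((20, 30, 3), 255, np.uint8)
        img[5:15, 5:25] = palette.rgb[palette.id_of("teal")].astype(np.uint8)
        lm = build_label_map(img, palette, px_per_mm=1.0)
        assert set(np.unique(lm.labels)) == {-1, palette.id_of("teal")}

    def test_all_pressures_recover_true_colour(self, palette):
        """Every crayon at any generator pressure labels as itself."""
        for cid in range(len(palette)):
            for p in (0.35, 0.5, 0.75, 1.0):
                px = np.round(p * palette.rgb[cid] + (1 - p) * 255).astype(np.uint8)
                img = np.full((4, 4, 3), 255, np.uint8)
                img[1:3, 1:3] = px
                lm = build_label_map(img, palette, px_per_mm=1.0)
                got = set(np.unique(lm.labels[lm.labels >= 0]))
                assert got == {cid}, (palette.name_of(cid), p)

    def test_labels_match_ground_truth_colours(self, rendered_drawings):
        for _d, gt, r in rendered_drawings:
            lm = build_label_map(r)
            got = set(int(v) for v in np.unique(lm.labels[lm.labels >= 0]))
            assert got == gt.colours_used

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            build_label_map(np.zeros((5, 5), np.uint8), px_per_mm=1.0)


class TestSummarizeCells:
    def test_empty_drawing_no_covered_cells(self, sheet):
        lm = build_label_map(rasterize(drawing_of([]), 1.0))
        cells = summarize_cells(lm, sheet)
        assert not cells.covered.any()
        assert coverage_rate(cells) == 0.0

    def test_single_dot_covers_exactly_one_cell(self, sheet):
        # a dot strictly inside cell (4, 7): cell x in [190.4, 217.6), y in [96.8, 121)
        dot = StrokePath(np.array([[204.0, 108.0], [204.5, 108.0]]), 2, 2.0, 1.0)
        lm = build_label_map(rasterize(drawing_of([dot]), 2.0))
        cells = summarize_cells(lm, sheet)
        assert cells.covered.sum() == 1
        assert cells.covered[4, 7]

    def test_fraction_and_sets_match_cell_oracle(self, rendered_drawings, sheet):
        for _d, _gt, r in rendered_drawings:
            lm = build_label_map(r)
            cells = summarize_cells(lm, sheet)
            frac, sets = cells_oracle(lm, sheet)
            np.testing.assert_array_equal(cells.fraction, frac)
            assert cells.colour_sets == sets

    def test_covered_iff_nonempty_set_iff_positive_fraction(self, rendered_drawings, sheet):
        for _d, _gt, r in rendered_drawings:
            cells = summarize_cells(build_label_map(r), sheet)
            for rr in range(10):
                for cc in range(10):
                    cov = bool(cells.covered[rr, cc])
                    assert cov == (len(cells.colour_sets[rr][cc]) > 0)
                    assert cov == (cells.fraction[rr, cc] > 0)


def make_cells(n_covered, n_multi, n_solid=0):
    frac = np.zeros((10, 10))
    sets = [[set() for _ in range(10)] for _ in range(10)]
    k = 0
    for r in range(10):
        for c in range(10):
            if k < n_covered:
                frac[r, c] = 0.6 if k < n_solid else 0.1
                sets[r][c] = {0, 1} if k < n_multi else {0}
                k += 1
    return CellSummary(frac > 0, frac, sets, Sheet())


class TestRates:
    def test_coverage_extremes(self):
        assert coverage_rate(make_cells(0, 0)) == 0.0
        assert coverage_rate(make_cells(100, 0)) == 1.0

    def test_overlap_five_multi_of_fifty_covered(self):
        assert overlap_rate(make_cells(50, 5)) == pytest.approx(10.0)

    def test_overlap_all_multi_is_100(self):
        assert overlap_rate(make_cells(40, 40)) == pytest.approx(100.0)

    def test_overlap_zero_when_uncovered(self):
        assert overlap_rate(make_cells(0, 0)) == 0.0

    def test_solid_rate_counts_half_covered_cells(self):
        assert solid_colour_rate(make_cells(20, 0, n_solid=3)) == pytest.approx(0.03)

    def test_solid_never_exceeds_coverage(self, rendered_drawings, sheet):
        for _d, _gt, r in rendered_drawings:
            cells = summarize_cells(build_label_map(r), sheet)
            assert solid_colour_rate(cells) <= coverage_rate(cells)


class TestColourStats:
    def test_count_colours_min_pixels(self, palette):
        img = np.full((10, 10, 3), 255, np.uint8)
        img[0, 0] = palette.rgb[0].astype(np.uint8)       # 1 px of red
        img[5:9, 5:9] = palette.rgb[4].astype(np.uint8)   # 16 px of green
        lm = build_label_map(img, palette, px_per_mm=1.0)
        assert count_colours(lm, 1) == 2
        assert count_colours(lm, 2) == 1
        with pytest.raises(ValueError):
            count_colours(lm, 0)

    def test_main_colour_majority_and_tie_break(self, palette):
        img = np.full((10, 10, 3), 255, np.uint8)
        img[:7, 0] = palette.rgb[4].astype(np.uint8)
        img[:3, 2] = palette.rgb[0].astype(np.uint8)
        lm = build_label_map(img, palette, px_per_mm=1.0)
        assert main_colour(lm) == 4
        img2 = np.full((10, 10, 3), 255, np.uint8)
        img2[:3, 0] = palette.rgb[7].astype(np.uint8)
        img2[:3, 2] = palette.rgb[2].astype(np.uint8)
        assert main_colour(build_label_map(img2, palette, px_per_mm=1.0)) == 2

    def test_main_colour_none_when_empty(self):
        lm = build_label_map(rasterize(drawing_of([]), 1.0))
        assert main_colour(lm) is None

    def test_blank_sheet_spectrum(self):
        lm = build_label_map(rasterize(drawing_of([]), 1.0))
        assert colour_spectrum_stats(lm) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_half_black_half_white(self):
        img = np.full((10, 10, 3), 255, np.uint8)
        img[:5] = 0
        lm = build_label_map(img, px_per_mm=1.0)
        mean, sd = colour_spectrum_stats(lm)
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.5)

    def test_spectrum_matches_pixel_loop(self, rendered_drawings):
        _d, _gt, r = rendered_drawings[0]
        lm = build_label_map(r)
        mean, sd = colour_spectrum_stats(lm)
        vals = [lm.luminance[i, j] for i in range(lm.shape[0]) for j in range(0, lm.shape[1], 7)]
        # strided pixel loop as an independent estimate
        assert mean == pytest.approx(float(np.mean(lm.luminance.ravel())))
        assert sd == pytest.approx(float(np.std(lm.luminance.ravel())))

    def test_colour_mean_decreases_with_pressure(self):
        """Re-rendering the same strokes at higher pressure darkens the
        sheet monotonically."""
        rng = np.random.default_rng(31)
        from apedraw.generator import default_profiles, sample_drawing

        d, _ = sample_drawing(default_profiles()["Gypsy"], A_DATE, rng)
        means = []
        for p in (0.35, 0.5, 0.65, 0.8, 0.95):
            strokes = [StrokePath(s.points, s.colour_id, s.width_mm, p) for s in d.strokes]
            lm = build_label_map(rasterize(drawing_of(strokes), 1.0))
            means.append(colour_spectrum_stats(lm)[0])
        assert all(a > b for a, b in zip(means, means[1:]))


class TestDistanceToCentre:
    def test_empty_drawing_convention(self):
        lm = build_label_map(rasterize(drawing_of([]), 1.0))
        assert distance_to_centre(lm) == 0.0

    def test_centre_symmetric_pattern_is_zero(self, sheet):
        ring = []
        t = np.linspace(0, 2 * np.pi, 100)
        pts = np.column_stack([136 + 50 * np.cos(t), 121 + 50 * np.sin(t)])
        s = StrokePath(pts, 0, 3.0, 1.0)
        lm = build_label_map(rasterize(drawing_of([s]), 2.0))
        assert distance_to_centre(lm, sheet) <= 0.5

    def test_single_dot_100mm_off_centre(self, sheet):
        dot = StrokePath(np.array([[36.0, 121.0], [36.4, 121.0]]), 0, 1.0, 1.0)
        lm = build_label_map(rasterize(drawing_of([dot]), 2.0))
        assert distance_to_centre(lm, sheet) == pytest.approx(100.0, abs=0.8)

    def test_translation_covariance(self, sheet):
        rng = np.random.default_rng(17)
        from apedraw.generator import StyleProfile, sample_drawing

        prof = StyleProfile(individual="x", meander_rate=3.0, spread_mm=20.0)
        d, _ = sample_drawing(prof, A_DATE, rng)
        lm0 = build_label_map(rasterize(d, 2.0))
        base = distance_to_centre(lm0, sheet)
        ii, jj = np.nonzero(lm0.labels >= 0)
        c0 = np.array([(jj + 0.5).mean(), (ii + 0.5).mean()]) / 2.0
        moved = drawing_of([s.translated(18.0, -11.0) for s in d.strokes])
        lm1 = build_label_map(rasterize(moved, 2.0))
        ii1, jj1 = np.nonzero(lm1.labels >= 0)
        c1 = np.array([(jj1 + 0.5).mean(), (ii1 + 0.5).mean()]) / 2.0
        np.testing.assert_allclose(c1 - c0, [18.0, -11.0], atol=0.5)
        from apedraw.ellipse import ellipse_centre

        e0 = ellipse_centre(np.column_stack([(jj + 0.5) / 2, (ii + 0.5) / 2]))
        e1 = ellipse_centre(np.column_stack([(jj1 + 0.5) / 2, (ii1 + 0.5) / 2]))
        np.testing.assert_allclose(e1 - e0, [18.0, -11.0], atol=0.5)


class TestExtractMetrics:
    def test_empty_drawing_conventions(self, sheet):
        d = drawing_of([])
        m = extract_metrics(rasterize(d, 1.0), d)
        assert (m.coverage_rate, m.overlap_rate, m.solid_colour_rate) == (0, 0, 0)
        assert m.n_colours == 0 and m.main_colour is None
        assert m.colour_mean == pytest.approx(1.0)
        assert m.colour_sd == pytest.approx(0.0)
        assert m.dist_centre_mm == 0.0
        assert (m.fan, m.circle, m.triangle, m.loop) == (0, 0, 0, 0)

    def test_single_centred_circle(self, rng):
        from apedraw.generator import make_closed_shape

        s = make_closed_shape("circle", (136, 121), 40, rng, colour_id=4)
        d = drawing_of([s])
        m = extract_metrics(rasterize(d, 2.0), d)
        assert m.n_colours == 1
        assert m.circle == 1 and m.fan == 0
        assert m.overlap_rate == 0.0
        assert m.main_colour == 4
        assert m.dist_centre_mm < 3.0

    def test_invariants_on_profile_batch(self, rendered_drawings):
        for d, _gt, r in rendered_drawings:
            m = extract_metrics(r, d)
            assert 0 <= m.coverage_rate <= 1
            assert 0 <= m.overlap_rate <= 100
            assert m.solid_colour_rate <= m.coverage_rate
            assert m.dist_centre_mm <= np.hypot(272, 242) / 2
            if m.n_colours <= 1:
                assert m.overlap_rate == 0.0

    def test_metric_vector_invariants_enforced(self):
        with pytest.raises(ValueError):
            MetricVector("d", "x", "winter", 1, 0.5, 10.0, 1, 0, 0, 0, 0, 0.9, 0.1, 10.0, 0.2, 0)
        with pytest.raises(ValueError):
            MetricVector("d", "x", "winter", 1, 0.1, 0.0, 2, 0, 0, 0, 0, 0.9, 0.1, 10.0, 0.2, 0)
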