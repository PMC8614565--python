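# Methods

`apedraw` quantifies non-figurative crayon drawings and analyses the
resulting per-drawing variables for differences between individuals and
changes over time.  Because corpora of real ape drawings are typically
not redistributable, the package ships a synthetic drawing generator
with full ground truth; every measurement and statistical stage is
validated against planted structure rather than against a private
image archive.  This note documents the model behind each stage, the
parameters that matter, and the design choices made where the
published measurement protocol leaves the operational details open.

## Drawing model

A drawing is an ordered list of strokes on a white 272 × 242 mm sheet.
Coordinates are millimetres, origin at the top-left corner, x
rightward, y downward; the 10 × 10 analysis grid divides the sheet
into half-open cells.  A stroke is a polyline with a palette colour
id, a width (crayon contact diameter, default 2–5 mm) and a pressure
in (0, 1].  Pressure is modelled as opacity over white: a marked pixel
takes the value `p·c + (1 − p)·white`.  This is the simplest model
that reproduces the empirical signature of a light hand — paler marks,
lower contrast against the paper — and it makes colour labelling
exactly invertible (below).  Repainting replaces the pixel (stroke
list order, last on top); wax build-up is not modelled.

The 16-crayon palette was chosen once so that every colour at any
pressure ≥ 0.35 stays at least ~55 RGB units away from white and
remains nearest to its own pressure segment; the closest pair of
chroma directions (black vs. dark green) is still ≈ 7° apart.  The
generator never uses pressures below 0.35.

### Rasterization

Strokes are painted as disc-swept polylines: a pixel is marked when
its centre lies within half the stroke width of the path, evaluated by
dense arc-length sampling (0.35 px spacing, error well under half a
pixel).  The default resolution of 2 px/mm (544 × 484 px) keeps a
single drawing around 0.2 s to measure while resolving the grid cells
at ~54 × 48 px each.  Alongside the visible image the rasterizer
retains the true colour id per pixel and the order-independent set of
stroke colours that touched each pixel; both feed the ground-truth
record used by the validation suite.

## Style profiles and planted structure

Each individual is a `StyleProfile`: Poisson rates for meander strokes
and for each planted shape, colour-preference weights over the 16
crayons, pressure and width ranges, and a spatial spread.  Five
default profiles emulate the study population: one prolific,
heavy-filling, low-pressure individual with broad colour use (Molly);
one minimal, hard-pressing, nearly monochrome individual (Kiki); and
three intermediates.  Profile means were calibrated once, at design
time, toward the corpus-level summary statistics of the emulated
study — population coverage rate near 50%, overlap near 20%, about
three colours per drawing (measured 53% / 15% / 2.9, with mean fan and
loop counts of 1.7 and 0.70 against reported 1.8 and 0.7) — and were
not revisited afterwards.

Colour preference is realised hierarchically: each drawing first draws
a dominant crayon from the preference weights, then biases stroke
colours toward it (`dominant_focus`, default 0.7).  This emulates
sessions dominated by one crayon and makes the per-drawing *main
colour* follow the preference distribution, which a flat per-stroke
draw would not (the area argmax would over-represent the top colour).

The longitudinal individual carries a filling multiplier
`exp(trend·(period − 10) + season_offset)` applied to the meander and
fan rates, with a default trend of −0.045 per 3-month period (halving
filling across the 19 periods) and a winter offset of −0.5
(≈ 40% less filling in winter).  These two knobs plant the declining
trend and winter deficit that the statistics stage must recover.
Dates are balanced across the 19 periods for the longitudinal
individual (round-robin, uniform day within period) and uniform over
the study window for everyone else.  Seasons follow meteorological
quarters (Dec–Feb = winter), which the measurement protocol leaves
unstated.

Meander strokes are persistent random walks (4 mm steps, turning noise
σ = 8°, clipped at 30°) steered smoothly back toward the sheet
interior near the edge rather than reflected — a reflection would
create a spurious corner.  By construction a meander can never contain
a distinct angle or a fan reversal; the only spurious detection it can
trigger is a self-crossing read as a circle, measured at < 1% of
meander strokes under the defaults.

### Planted shapes

* **Fan**: legs radiate from a lightly jittered anchor to tips whose
  directions stay within the spread cone, giving exactly
  `2·round_trips − 1` reversal vertices with adjacent legs subtending
  at most the spread angle.
* **Circle**: a 410° sweep at base radius with a localized radial
  excursion over the final 80° that dips inside and climbs back out,
  crossing the first arc exactly once and transversally (≈ 15°
  incidence); low-frequency radial jitter is kept an order of
  magnitude below the excursion so the crossing stays unique.
* **Loop**: two straight legs meeting at a ≈ 60° apex (the single
  distinct angle), closed by a circular arc leaving the second leg
  near-tangentially and crossing the first, slightly longer, leg once.
* **Triangle**: three vertices on a jittered circle joined by
  near-straight sides (≤ 0.1 mm wobble), ending ≈ 1 mm short of the
  start — within the classifier's endpoint-closure tolerance.

## Measurement stage

### Colour labelling

A pixel within `bg_delta` (default 40 RGB units) of white is paper.
Every other pixel is assigned the crayon whose *pressure segment*
`{p·c + (1 − p)·white, p ∈ [0.35, 1]}` it is closest to.  Plain
nearest-reference-RGB matching is not usable here: a pale mark of a
dark crayon moves toward white and lands nearer to an intrinsically
light crayon (pale red reads as pink, pale black as grey).  The
segment rule inverts the blending model exactly; on the shipped
palette it recovers the true colour of every generator drawing with
zero errors, which the test suite asserts against ground truth.

### Grid and colour variables

From the label map: coverage rate (covered cells / 100), overlap rate
(percent of *covered* cells containing ≥ 2 colours), solid colour rate
(cells with ≥ 50% of their pixels marked, / 100), number of colours
(≥ `min_pixels` labelled pixels, default 1), main colour (largest
labelled area, ties to the lowest colour id), and the colour spectrum
mean and standard deviation — per-pixel luminance (ITU-R 601 greyscale
of the RGB image) over the whole sheet, so a blank sheet reads
(1.0, 0.0), filling lowers the mean and contrast raises the spread.
The overlap denominator is the number of covered cells: the published
verbal definition ("divided by the coverage rate and multiplied by
100") would exceed 100% for any fractional denominator, while the
percent-of-covered-cells reading matches the scale of the reported
values.

Distance to centre is the Euclidean distance from the centre of the
**minimum-area enclosing ellipse** of all marked pixel centres to the
sheet centre.  "An ellipse surrounding the design" implies
containment, so moment-based ellipse fits were rejected.  The ellipse
is computed by Khachiyan's Frank–Wolfe iteration on the convex hull of
the marked pixels, stopped at a duality gap of 10⁻³ (centre error
≤ 0.07 mm in measurements, far below pixel resolution); collinear or
single-point mark sets fall back to the midpoint of the extremes, and
an empty sheet reports distance 0 by convention.

### Shape classification

Shape analysis runs on the vector strokes, not the raster: synthetic
data always carries vector truth, and human coders judged shapes from
the original strokes.  (Automated raster-to-vector reconstruction is
out of scope; for scanned real drawings a stroke extraction step would
have to precede this classifier.)

Turning angles are measured on a vertex-preserving arc-length
subdivision (default 2 mm): each segment is subdivided uniformly but
every original vertex is kept.  Pure uniform resampling would split a
sharp corner across two sample points — two ≈ 90° turns instead of one
≈ 170° reversal — and break both corner and reversal detection; the
vertex-preserving variant keeps corners exact while still normalising
the angle scale of long smooth segments.

A *reversal* is a vertex turning by at least `180° − 45°`; `r`
reversals make `floor((r + 1)/2)` out-and-back passes, and a stroke
with ≥ 3 passes is a fan.  Self-intersections are exact all-pairs
segment crossings (strict interior; endpoint contacts and collinear
overlaps excluded).  A stroke is *closed* when it self-intersects or
its endpoints meet within 3 mm.  Distinct angles are turning angles of
at least 60°: a closed stroke with none is a circle, with exactly one
a loop, and with three or more joined by near-straight sides (total
intermediate turning ≤ 100°) a triangle.  The 60° corner threshold,
2 mm resampling step, 3 mm closure gap and 100° side-straightness
budget are committed interpretations — the verbal definitions ("a
single distinct angle", "a flat loop") give no thresholds — and all
are configurable in `ShapeConfig`.  A stroke detected as a fan is
never additionally assigned a closed class: its self-contacts lie
between the zigzag legs and would double-count the same mark.  The
fan criterion and the closed-shape classes remain non-exclusive across
strokes, matching the protocol's note that several shapes can appear
in one drawing.

## Statistical stage

The metrics table feeds two arms.  Eleven quantitative variables enter
a PCA on the correlation matrix (variables centred and scaled); the
qualitative main colour is analysed separately by chi-square.
Components are retained while their eigenvalue exceeds 1 (Kaiser
rule); per-drawing scores are the standardized data projected on the
retained eigenvectors, reported loadings are eigenvector ×
√eigenvalue (variable–component correlations), and an optional varimax
rotation (via statsmodels) can be applied to the retained block.  A
correlation screen (Pearson, flag |r| strictly above 0.8) is reported
before the PCA but never drops variables automatically.

*Inter-individual arm*: per retained dimension, a tie-corrected
Kruskal–Wallis omnibus across individuals followed by all pairwise
two-sided rank-sum tests, Benjamini–Hochberg corrected, summarised as
a compact letter display; the same tests run per raw variable.

*Longitudinal arm*: a second PCA restricted to the prolific
individual, then per dimension a linear model `score ~ season +
period` with period as a numeric 1–19 covariate.  Per-term p-values
are Monte Carlo permutation probabilities: the response vector is
permuted B times (default 10,000; reduced modes documented below), the
partial F of each term is recomputed, and `p = (1 + #{F* ≥ F_obs}) /
(1 + B)` — the add-one convention keeps p ≥ 1/(B+1).  Raw-response
permutation with a partial-F statistic was chosen as the simplest
scheme consistent with the cited permutation-LM behaviour; its type-I
error is verified at 0.03–0.07 under a true null.  Collinearity is
reported as generalized VIFs (Fox–Monette determinant form, so the
4-level season factor gets a single value; both terms sit near 1.02 on
the balanced design).  Season post hocs are pairwise permutation tests
on mean differences, BH corrected.

Main-colour chi-squares test each group's main-colour counts against a
uniform distribution over the colour categories observed anywhere in
the dataset ("non-random use" is the only published null); groups with
expected counts below 5 carry a small-sample flag.

## Validation against planted truth

Because the emulated corpus is synthetic, what the passing suite shows
is that the *pipeline* is correct under the generative model — exact
grid-rate bookkeeping, exact colour recovery under the pressure model,
≥ 95% shape recovery under generator jitter, calibrated permutation
inference, and reliable recovery of planted individual, seasonal and
temporal effects.  It does not show robustness to properties of real
scanned drawings the generator does not emulate: paper texture,
stains, smudging, water damage, overlapping wax deposits that mix
pigments, or the absence of vector stroke data.

Validation routines (in `apedraw.validation`, driven by both the test
suite and `scripts/acceptance.py`):

* grid rates vs. a brute-force per-cell pixel tally, exact equality on
  100 seeded drawings;
* isolated planted shapes classified at 100%, and ≥ 95% recovery /
  ≤ 5% spurious detection over 500 full drawings;
* permutation-LM type-I error within [0.03, 0.07] at α = 0.05 (1000
  null replicates, B = 999, n = 60);
* 20 end-to-end runs at desk scale: individual effect (dimension-1
  Kruskal–Wallis p < 0.001), winter deficit and declining period trend
  (permutation p < 0.05 with the correct direction) each detected in
  ≥ 90% of runs;
* 3 planted latent factors over 11 variables → exactly 3
  eigenvalue-above-1 dimensions and the planted loading pattern in
  ≥ 90% of 100 runs.

## Problem sizes and reduced modes

The generator default remains the full corpus composition
(26/16/32/60 drawings for the four occasional drawers and 656
period-balanced drawings for the prolific one; 790 total).  Repeated
validation runs use a deliberately scaled condition — 8 drawings per
occasional drawer and 114 (6 × 19 periods) for the longitudinal
individual at 1 px/mm with B ≈ 300 — chosen so that a 20-run recovery
experiment completes on a single desk-class core while the planted
effects remain comfortably detectable.  The `--quick` CLI flag runs
analyses at B = 199 for interactive use; published-quality runs should
keep the default B = 10,000.

## Numerical conventions and degenerate inputs

Empty drawings report coverage 0, overlap 0, colour spectrum
(1.0, 0.0), distance 0 and no main colour; main-colour ties break to
the lowest colour id.  Overlap is 0 whenever at most one colour is
present.  PCA refuses zero-variance variables by name and warns (but
proceeds) when rows are fewer than variables; with no eigenvalue above
1 the retention count is 0 but one dimension of scores is still
emitted for inspection.  Eigenvector signs are fixed by making each
component's largest-magnitude coefficient positive, so reports are
reproducible across platforms.  Permutation p-values never equal 0;
group tests exclude groups with fewer than two observations with a
warning.  All randomness flows from explicit seeds through NumPy
`SeedSequence` spawning; a repeated run with the same seed produces
byte-identical stroke JSONs, manifests and report files.

## Known count discrepancy in the emulated corpus

The emulated study's reports state both 749 and 790 analysed drawings
in different places, while its per-individual counts sum to 790.  The
generator defaults follow the per-individual counts (790); the
discrepancy is surfaced here rather than resolved.

## Limitations

Shape classification requires vector strokes; the raster path alone
yields only variables 1–8.  The labeller assumes marks are blends of
palette colours over white — heavily mixed or stained regions of real
drawings would violate it.  The permutation model treats drawings as
exchangeable under the null, ignoring any within-period correlation;
no mixed-effects or time-series structure is modelled.  The chi-square
null of uniform colour use is a convention, not a behavioural model of
crayon availability.
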