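# Methods and design notes

## Scope and data model

The package analyzes 1-ha stem-mapped plots and their UAS-photogrammetry
counterparts. All coordinates are plot-local meters with the origin at the
lower-left corner; heights and crown radii are meters, DBH is centimeters,
basal area m² ha⁻¹. Readers never auto-convert units. CHM grids are
addressed `values[row, col]` with row 0 at the bottom edge and cell centers
at `origin + (index + 0.5) · cell_size`; GeoTIFF output is flipped to the
conventional north-up orientation with ModelPixelScale/ModelTiepoint/
GDAL_NODATA tags (written and read via tifffile). Point clouds are
whitespace- or comma-delimited XYZ text or LAS 1.2 point-format-0 binaries;
the LAS codec is a deliberately minimal, self-contained implementation
sufficient for height-normalized x/y/z payloads.

Inputs are assumed height-normalized (flat ground at z = 0). Ground
filtering, photogrammetric reconstruction, and georectification are out of
scope.

## Tree detection

A cell of the CHM is a treetop iff its value is at least the inventory
threshold (1.37 m, breast height) and is ≥ every cell whose center lies
within `0.2 × value` meters of its own center. The window is circular in
world distance, not a square of pixels, because the radius rule is stated in
meters of canopy height. Empty CHM cells are treated as ground (0 m), not
nodata, before detection; no smoothing or pit-filling is applied.

Plateau ties (exactly equal values within each other's windows, which occur
on rendered synthetic surfaces and quantized rasters) are resolved
deterministically: candidates are processed in descending height then
(row, col) order, and an equal-valued already-accepted treetop within the
window suppresses the later cell. A uniform CHM smaller than its own search
window therefore yields exactly one treetop at (0, 0).

The implementation prefilters candidates with a 3×3 maximum filter (valid
whenever the window radius reaches the 8-neighborhood, i.e. for every cell
above ~0.71 m at 0.10 m resolution) and then verifies the full circular
predicate per candidate. Tests compare it against an independent brute-force
evaluation of the predicate at every cell.

Crowns are delineated by marker-controlled watershed on the inverted CHM,
seeded at the treetops and restricted to cells at or above the crown
threshold (default 1.37 m). Canopy cover from a CHM is the fraction of cells
at or above that threshold; canopy cover of a stem map is the dissolved
(union) area of circular crowns rasterized at the same 0.10 m grain, so the
two cover definitions share one discretization.

## DBH chain

Circle fitting uses the algebraic Kåsa solution (on centered coordinates for
conditioning) as the start of a Levenberg–Marquardt refinement of the
geometric radial residuals; the reported RMS is from the refined fit.
Collinear configurations are rejected as degenerate.

`extract_dbh` collects slice points (z ∈ [1.32, 1.42] m) within 1.0 m of the
detected stem. Absence is a value, not an error: the fit is discarded when
fewer than 10 points are in range, when `rms / radius > 0.25`, or when the
fitted radius exceeds half the search radius. The last gate exists because
uniform branch clutter inside the search disk produces well-conditioned
circles of roughly three-quarters the search radius (far larger than any
stem here, which would imply DBH > 100 cm); the rms gate alone cannot reject
them. All three gates are parameters of the function.

The height–diameter model `DBH = β₁·h^β₂` is fit by nonlinear least squares
on the original scale, initialized from the log–log regression. The
prediction interval is two-sided t with the delta-method variance
`resid_se² + gᵀCg` (g the parameter gradient of the fitted curve, C the
parameter covariance); a Monte-Carlo propagation variant (`method="mc"`)
draws parameters from N(β̂, C) plus t-distributed residual noise and takes
empirical quantiles — the two agree to within a few millimeters of DBH on
typical site models and are cross-checked in tests. The regional model is
supplied as configuration (JSON with β₁, β₂, residual SE, n, covariance) or
fit from any height–DBH CSV; `make_synthetic_regional_model` packages a
synthetic stand-in fit on simulated inventory pairs with 6.2 cm residual
scatter so the prediction-bound filter can run without external inventory
data. Pairs passing the bound refit a site model that imputes DBH for the
remaining trees; imputation never touches extracted values and is
idempotent.

## Matching and error metrics

Matching is greedy: UAS trees are processed tallest-first (the procedure is
iterative but its original ordering is not documented; tall-first is
deterministic and exposed via the `order` argument for sensitivity checks).
For each UAS tree the not-yet-matched stem-map trees within 4.0 m are
screened for height error strictly below 2.0 m; the smallest height error
wins, ties broken by distance then field id. Unmatched UAS trees are false
positives, leftover field trees false negatives, which guarantees
`TP + FP = #UAS` and `TP + FN = #field`.

Rates are reported per dominance class — understory < 5 m, intermediate
5–15 m (inclusive at both ends), overstory > 15 m — with TP/FN classed by
field height and FP by UAS height (a false positive has no field height).
Empty classes are omitted rather than reported as zeros. F-score is the
harmonic mean of precision and recall, defined as 0 when TP = 0.
Measurement errors (UAS − field everywhere) are summarized as mean error
and RMSE in half-open 5-m field-height bins starting at 0.

## Stand metrics and the paired table

`ba = Σ π(dbh/200)²/area`, `qmd = √(Σd²/n)`, and the two are linked by the
identity `qmd = 200·√(ba/(π·tph))`, which is property-tested as a
round-trip. The packaged paired table carries stem-map and UAS values of
QMD, TPH, TPH of trees > 5 m, BA, and canopy cover for the eleven study
plots; `compare_tables` reports mean error, mean percent error, MAE, MAPE,
and RMSE per metric. Percent errors are averaged per plot (mean of per-plot
ratios, not ratio of means) — this is the convention under which the
table's printed percent statistics (+27.9% TPH, −1.7%/11.4% BA) reproduce
exactly. Canopy cover is already in percent, so its unsigned error
statistics are percentage points.

Two known discrepancies in the source table's narrative are left as the
table implies: the mean stem-map TPH of the table is 279 (not the narrated
332), and the >5 m TPH difference is +10 (UAS − stem map), matching the
narrated magnitude with opposite sign.

## Clumps and openings

Clumps are connected components of the graph joining stems at ≤ 6 m
(the distance at which crowns can interlock); an isolated tree is an
"individual". This is DBSCAN with a 2-point neighborhood, but is computed
directly as connected components over a KD-tree radius query for exact,
deterministic semantics (sklearn's DBSCAN is retained in the tests as an
independent cross-check). Clump ids are ordered by smallest member id.
Size classes are individual / 2–4 / 5–9 / 10–15 / >15 trees. Per clump the
package reports percent of stand BA (summing to 100 across clumps), height
CV (sample SD over mean, ×100; undefined for singletons), and dissolved
crown area. Per-class crown area is aggregated as the per-plot mean of
per-clump areas.

Openings are the proportions of plot area in bands of distance to the
nearest stem — [0,3), [3,6), [6,9), [9,12), [12,∞) m — evaluated at the
centers of a 1-m grid. Distances are stem-to-point (not crown-edge).

## ANOVA comparisons

Stem-map vs UAS metrics are compared with classical one-way F tests and
Bonferroni-adjusted p-values `min(1, k·p)` (the cap matters: adjusted values
are reported as at most 1). The comparison unit follows the metric: plot
level for clump counts, crown area, and opening proportions; clump level
for BA share and height CV. The default k is 5 comparisons per family,
except 4 for height CV (no singleton class). Zero within-group variance
with unequal means is reported as p = 0 with a warning.

## Synthetic stands

The generator defines the test conditions. Four archetypes mirror the
studied treatments, loosely calibrated to the observed per-treatment
densities (overall 160–660 trees ha⁻¹):

| archetype | overstory process | overstory /ha | understory /ha | notes |
|---|---|---|---|---|
| SGR | Thomas, 5 parents/ha, sd 4 m | 100 | 280 | retained groups over dense regeneration patches |
| CT | hard-core, 4.9 m minimum spacing | 170 | 6 | thinned from below, tall and even |
| FS-On | Thomas, 12 parents/ha, sd 6 m | 180 | 105 | more understory (vertical heterogeneity) |
| FS-Off | Thomas, 12 parents/ha, sd 6 m | 200 | 52 | less understory |

Offspring and patch points are wrapped toroidally so realized densities are
unbiased at plot edges; hard-core placement is dart-throwing with rejection,
capped at 10⁴ attempts per tree. Heights are truncated log-normals per
stratum (overstory meanlog ≈ ln 14–16 m; understory meanlog ln 2.3 m on
[1.37, 5) m). DBH follows `4.29·h^0.68` with 1.20 cm Gaussian residual —
the reported site-model means — truncated positive; crown radius is
`0.5 + 0.15·h` m clipped at ≥ 0.3 m, putting a 16-m overstory tree near the
~3 m crown radius typical of these stands.

Crowns render into the CHM as generalized paraboloids
`h(r) = H(1 − (r/R)^e)` with exponent 2 by default; the crown profile is a
modeling choice (no crown shape is prescribed by the workflow) — any
surface with a unique apex and monotone falloff exercises the detector, and
the stem cell is set to the exact tree height so apex identities are sharp.
The breast-height simulator places points on each stem circle (radius
dbh/200 m) with radial Gaussian noise and uniform z in the slice, plus
branch-like clutter uniform in crown disks.

`perturb_to_uas` converts a truth stem map into a detection-like tree list:
per-dominance-class deletions (false negatives), position/height jitter, a
height bias emulating growth between mapping and flight, class-targeted
spurious trees, and uniformly placed 1.37–2.0 m "ingrowth" trees emulating
regeneration crossing the inventory threshold. The spurious-tree parameter
is specified as the target false-positive *rate* FP/(TP+FP): the generator
adds `round(n_surviving·p/(1−p))` spurious trees so a matcher that recovers
all survivors observes rate p. The outcome retains each output tree's truth
ancestor for test oracles only.

What the generator does *not* emulate: photogrammetric noise structure
(height-dependent smoothing, occlusion, reconstruction artifacts), terrain,
species mixtures, crown asymmetry, and real branch geometry. Passing tests
therefore demonstrate algorithmic correctness and calibration under the
stated stochastic model, not field-level accuracy; the field-scale accuracy
figures (overall F-scores, height RMSE ≈ 1.3 m, DBH RMSE ≈ 4.8 cm) depend
on the original imagery and are not reproduction targets.

## Verification design and problem sizes

Every algorithmic stage is checked against an independent oracle:
brute-force per-cell local-max evaluation for detection (50 random stands),
a literal step-by-step replay of the matching rule (500 random
configurations), union-find connected components for clumping (500 random
plots), exhaustive per-grid-point distances for openings, hand-computed
sums of squares and the t² ≡ F identity for the ANOVA, and closed forms for
the scalar equations. Calibration checks use seeded Monte Carlo sized to
keep the suite fast while leaving binomial error well inside the asserted
bands: 100 refits of 500 noisy height–DBH pairs for exponent recovery
(|bias| < 0.02), 20 fits × 500 fresh draws for 90% ± 2% prediction-interval
coverage, 2000 null simulations for the 5% ± 1% type-I error, and 20
perturbed 1-ha stands for detection-rate recovery. The recovery tolerances
(±2.5 percentage points per class, ±5 for the understory) include a small,
analytically bounded downward bias that is a property of greedy matching
itself: a spurious tree can coincidentally fall within the match tolerances
of a deleted stem, converting a would-be FN/FP pair into a TP.

The end-to-end recovery condition uses a sparse hard-core stand
(80 overstory + 20 understory trees ha⁻¹) so that coincidental matches stay
rare, with class deletion rates (0.32, 0.17, 0.07) and false-positive rates
(0.614, 0.15, 0.172) chosen so the expected understory FP rate is 61.4% and
the expected overall FP/FN rates are ≈ 29.5%/16.8% at this class mix.

## Numerical and degenerate-input conventions

Dominance-class boundaries are closed on the intermediate side (5.0 and
15.0 m are intermediate). A tree exactly 1.37 m tall is inventoried. Error
bins and opening bands are lower-inclusive. An empty plot yields TPH 0 and
an absent (None) QMD rather than NaN; an empty class yields absent rates.
Tree CSVs are read with correctly-rounded float parsing so write→read is
bit-exact. All random generation flows through `numpy.random.default_rng`
with caller-supplied seeds; equal seeds give identical outputs everywhere,
including the pipeline's artifact hashes.

## Known limitations

Detection recall inside dense clumps is structurally limited (interlocking
crowns merge into one surface); the package reports this honestly rather
than compensating. The LAS codec handles only point format 0 without VLRs
or compression. The dissolved-area rasterization at 0.10 m slightly
underestimates the area of sub-meter crowns. ANOVA assumes independence of
clump-level observations within a plot, as in the comparison design it
mirrors.
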