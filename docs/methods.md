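# Methods

This note documents the models, estimators, numerical choices, and
limitations behind `osmofit`, in the order the pipeline runs.

## Growth-curve model

Plate-reader growth curves are modelled with the Zwietering modified
Gompertz sigmoid applied to the *log* of optical density:

    ln[OD(t)/OD₀] = K · exp(−exp(μmax·e/K · (λ − t) + 1)),   K = ln(A/OD₀)

with carrying capacity `A` (OD₆₀₀), lag time `λ` (h), inoculum `OD₀`
(default A/100, mirroring a 1:100 daily back-dilution), and `μmax` (h⁻¹).
Applying the sigmoid in log space — Zwietering's original formulation, where
the modelled quantity is the log of relative population size — makes `μmax`
exactly the maximum *specific* growth rate max d ln OD/dt. This matters
because every rate this package reports is a specific rate: rates quoted
"at OD = 0.2", maxima of rate-vs-OD curves, and single-cell rates are all
d ln(biomass)/dt in h⁻¹. Had the sigmoid been applied to OD directly, its
μmax would be an absolute slope (OD·h⁻¹) and the specific rate would diverge
at low OD, making "maximum specific rate" floor-dependent. The fitted
`GompertzFit` nevertheless also reports `mu_max_od`, the maximum d(OD)/dt of
the fitted curve, so results can be compared against either convention.

Useful closed forms (used by the generator, the tests, and
`growth_params_for_rate_at_od`): at OD between OD₀ and A the specific rate
is ν(OD) = μmax·e/K · G · ln(K/G) with G = ln(OD/OD₀); this is solved for
μmax when a curve must be planted with a prescribed rate at a prescribed OD.

Measurement noise is multiplicative log-normal with unit mean and
coefficient of variation `noise_cv` (default 0.02), applied pointwise —
plate-reader error scales with signal. The study's plate reader noise
magnitude is not published; 2% is a typical value for shaken 96-well
readers and the default is not tuned to any test outcome.

**Diauxic curves** are built piecewise, not from a substrate model: phase 1
runs to its plateau, OD then continues along phase 1's asymptote for
`shift_pause` hours, and phase 2 follows its own log-Gompertz starting from
the reached OD. The phase-2 log-ratio is anchored by subtracting its value
at the junction — a constant shift of ln OD that makes the curve continuous
without touching the specific rate, so the planted phase-2 μmax stays exact.
If phase 2's carrying capacity does not exceed the phase-1 plateau by more
than 1%, the curve simply continues phase 1 (the two-phase construction
degenerates to a single phase). Only the observable curve shape matters
downstream; the mechanism of the glucose→osmolyte switch is out of scope.

## Rate estimation and shift detection

`instantaneous_growth_rate` is the least-squares slope of ln OD over a
centred window (default 5 points; clipped one-sided at the series ends).
Rates are undefined (NaN) at or below the OD floor of 0.005, a typical
post-blank noise floor. On an exact exponential the estimator is exact for
any window; on curved (Gompertz) input the window introduces a small
smoothing bias — with 15-min sampling and the default window, recovering a
planted rate at OD 0.2 is accurate to ~0.3% and a planted rate maximum to
~1.5%, which is why recovery tolerances of 2% are used.

`detect_shift` finds the diauxic dip as the deepest interior local minimum
of the rate series whose flanking maxima both exceed it by at least 10% of
the global maximum rate (the prominence guard rejects ripple); flat valleys
resolve to their plateau midpoint, which places the shift time at the
midpoint of a constructed pause. scipy's peak finder performs the search; an
exhaustive-scan oracle in the tests checks it.

`saturation_od` returns the curve maximum when the trailing 2 h have a
relative slope below 0.01 h⁻¹ (a plateau, tolerant of slight post-peak
decline) and the final measurement otherwise — matching the operational rule
of using the last OD when a culture has not saturated.

## Relative fitness

`relative_fitness(evolved, ancestor)` computes saturation OD of the evolved
curve, locates T₁/₂ as the *first upward crossing* of half that value
(linear interpolation between bracketing samples), interpolates the ancestor
at T₁/₂, and reports fitness = (OD_max^ev/2) / OD^anc(T₁/₂). Properties
enforced by tests: self-fitness is exactly 1 (the same linear segment is
interpolated both ways), joint rescaling of both curves cancels, and the
interpolated statistic agrees with brute-force evaluation on a 1000× denser
analytic resampling to within 0.5%. The statistic is monoculture-based by
design; it is not a competition-assay fitness.

## Cell geometry

Cells are idealized as spherocylinders: radius R, pole-to-pole length L,
volume V = πR²(L − 2R) + (4/3)πR³. A published variant of this formula with
a doubled cylinder term, 2πR²(L − 2R) + (4/3)πR³, is available as
`formula="printed"`; the geometric form is the default because it is the
volume of the named solid, and the two coincide in the sphere limit L = 2R.
The doubled-coefficient variant is preserved as an option rather than
silently corrected so either convention can be reproduced exactly.

The midline algorithm: (1) poles are the farthest-apart pair of boundary
points — curvature does not localize the tip of a capped rod because it is
constant over the whole hemispherical cap, whereas the boundary diameter is
exact for spherocylinders and robust for gently bent cells; (2) the contour
is split at the poles and the two side arcs are paired by normalized arc
length, their pointwise mean giving an initial midline; (3) one relaxation
pass recentres each interior station on its perpendicular
boundary-to-boundary chord (stations inside the caps, oblique chords wider
than 1.5× the median, and steps larger than a quarter width are skipped) —
this corrects the pairing misalignment that bent cells produce, and a single
pass is the default because further unregularized passes can drift on
strongly curved cells; (4) the cap portions are rebuilt by extending the
body midline along its end tangents to the boundary ("extend to poles").
The construction always runs at a fixed internal resolution of 25 stations
(pairing wiggles scale with station density) and is resampled to the
requested output density afterwards. On noise-free spherocylinders over
R ∈ [0.3, 0.7] µm, L ∈ [1.5, 5] µm, recovered width/length/volume are within
1% of truth (in practice ~10⁻⁵); on circular-arc "banana" cells with bend
half-angles up to 0.45 rad, midline length is within 0.2% of the generating
arc length.

Width is the mean perpendicular chord over midline stations, excluding
stations within one local half-width of either pole (cap chords are short)
and septal stations below 0.8× the median width — the septation criterion is
a package choice, as no quantitative rule is published. Contours with
aspect ratio < 1.05 cannot define poles; they are measured along a
centroid/principal-axis chord and flagged `degenerate`.

## Single-cell kinetics

The instantaneous rate over one imaging interval is
(1/Δt)·ln[V(t+Δt)/V(t)], Δt in hours; the formula is Δt-aware, so missing
frames simply enter as longer intervals. The per-cell rate is the mean of
interval rates whose interval ends within the imaging window (15 or 21 min
in the emulated experiments) — for gap-free sampling this telescopes to
(1/T)·ln[V(T)/V(0)] and is exact on noiseless exponentials regardless of
frame interval. A per-cell regression of ln V on t is a natural alternative;
the mean-of-rates reading matches how a "mean instantaneous growth rate over
the imaging window" is defined and is what is implemented.

Population comparisons use the Welch (unequal-variance) two-sample
two-tailed t-test — the safer default when only "two-tailed t test" is
specified — with the percent difference reported relative to the reference
(ancestor) group. Two zero-variance groups with equal means give p = 1 by
convention. `growth_law_table` regresses ln(mean volume) on mean rate
across conditions and reports slope, intercept, and R², quantifying how far
the data fall from the single-line Growth-Law prediction without making a
biological verdict.

## Mutation summaries

The prevalence filter keeps records with prevalence ≥ threshold (default
0.05): "present at <5% were not included" read literally makes the boundary
inclusive. Histogram weights accrue per mutation record (a gene hit twice
contributes twice), records without a class annotation accumulate in an
explicit "unclassified" bin, and fractions are weights over total weight.
Histograms from multiple populations are pooled by raw weight summation
(`merge_histograms`); equal-population weighting would be an alternative
pooling mode, but raw sums match a histogram computed from the concatenated
tables, which is the invariant the tests enforce.

## Synthetic data: what it does and does not emulate

The generator plants ground truth with the study's own conditions as
defaults: 15-min plate-reader sampling over 24 h, 1:100 daily dilution
(≈6.6 generations/cycle), 3-min imaging frames over 15/21-min windows,
single-cell group sizes of 405/125, 77/97, and 159/148, a 15% between-cell
rate CV, and the printed rate and prevalence values (0.82, 0.43, 0.50 h⁻¹;
83.3%, 17.6%). Base single-cell mean rates for the three comparison media
(0.6, 0.8, 0.5 h⁻¹) are package choices in the physiological range for
*E. coli* in minimal media; percent-difference recovery is scale-free, so
their exact values do not affect the planted quantities. One root seed
drives deterministic per-cell/per-curve substreams, so fixed seeds give
bit-identical outputs (CSV writers emit shortest round-trip decimals and
readers parse with round-trip precision for the same reason).

What passing recovery tests shows: the estimators invert the generators —
unbiased rate and percent-difference recovery at the stated n, exact
geometry on ideal and jittered contours, exact round trips. What it cannot
show: robustness to real plate-reader artefacts (condensation, drift,
carryover), segmentation errors beyond radial Gaussian jitter, cell-cycle
and lineage structure in trajectories (cells are pre-tracked and purely
exponential), or variant-calling error in mutation tables. Growth curves are
generated from the same Gompertz family the fitter assumes, so fit-recovery
tests validate the optimizer and parameterization, not model adequacy for
real curves.

Stochastic recoveries (the ±4-percentage-point percent-difference checks)
are reported as the mean over 5 independent replicate experiments at the
full group sizes: a single draw at these n has a ~2-point sampling SE, and
averaging tests the estimator rather than one draw's luck.

## Problem sizes

Default problem sizes are chosen so the full test suite runs in well under a
minute and the acceptance script in seconds: 97–101-point growth curves,
25 midline stations, 96-point validation contours, populations up to 405
cells, and 5 replicate experiments per stochastic scenario. All are
parameters, not limits.

## Known limitations

* The Gompertz specific rate has a single interior maximum; genuinely
  bi-phasic single curves must go through the diauxic constructor.
* `saturation_od` on a monotone but slowly rising curve (slope just above
  the plateau tolerance) returns the last measurement, which underestimates
  the eventual plateau — intended behaviour for cultures that never
  saturate, but worth knowing when comparing very slow conditions.
* The midline relaxation is validated for smooth convex-ish rods and gentle
  bends; strongly lobed or branched contours are outside its domain and may
  only be caught by the degenerate/width guards.
* The kinetics module assumes trajectories arrive pre-linked; no tracking,
  drift correction, or division detection is performed.
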