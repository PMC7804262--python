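# Methods

## Surface model and coordinate conventions

All lengths are micrometres; unit conversion happens only at I/O boundaries.
A scan field is represented as a digital elevation model (DEM): a regular
grid of heights with an explicit boolean measured-cell mask (never a magic
no-data elevation). Grid rows follow the cuspo-cervical (y) axis and columns
the mesiodistal (x) axis; `occlusal_axis` records which axis-aligned
direction points toward the cusp, and `flip_vertical` (an involution)
corrects the row order of raster imports that arrive upside-down.

Point clouds are gridded by piecewise-linear (barycentric) interpolation over
a Delaunay triangulation (scipy's Qhull-based `LinearNDInterpolator`). The
linear interpolant was chosen over higher-order alternatives because it
passes through the data exactly, never overshoots the enclosing triangle's
values (depths can only be attenuated, not invented), and reproduces the
behavior expected of the standard XYZ-to-DEM import route. Nodes outside the
convex hull of the measured points are never extrapolated. Exact duplicate
(x, y) positions keep the last-read z with a warning.

Unmeasured instrument dropouts (typically 0.1–2% of points with a good
confocal setup) are carried through the whole chain: they are flagged on
input, masked in the DEM, ignored by the spike filter's window statistics,
and excluded from extremum search; a transect with more than 20% unmeasured
samples, or an unmeasured endpoint, is rejected as unusable rather than
silently interpolated across.

## Spike cleaning

`reduce_noise` replaces a cell by its window median when it deviates from
that median by more than k robust standard deviations (1.4826 × the window
median absolute deviation; defaults window = 5 px, k = 3). On smooth enamel
ripple the local MAD tracks the local slope, so noise-free topography is
untouched, while isolated spikes (bubbles, scratches) sit many MADs out and
are removed. No smoothing is ever applied to profiles themselves: the depth
conventions operate on raw elevations, and transect placement is the primary
defense against aberrations.

## Depth measurement conventions

Profiles are sampled bilinearly at the DEM pixel pitch along straight
transects and re-ordered so the occlusal end is at distance 0.

Extrema are detected with an amplitude-threshold peak finder: strict local
extrema (plateaus collapse to their midpoint, which keeps output
deterministic on quantized elevations), then adjacent maximum–minimum pairs
are annihilated smallest-amplitude-first until every surviving adjacent pair
spans at least `min_amplitude`. Ties break on the more occlusal pair. This
pruning is confluent in practice; the test suite verifies it against an
exhaustive exploration of all smallest-first removal orders on 1000 random
profiles. One consequence of pair pruning is that a sub-threshold ridge
always annihilates together with a neighboring groove, so on a 1 µm ripple
with a 5 µm threshold no ripple ridge survives next to a deep defect. The
defect convention therefore resolves its occlusal reference in two steps:
the nearest retained maximum occlusal of the floor when one exists, otherwise
the highest measured sample occlusal of the floor. The cervical shoulder is
recorded for audit but never used as the reference.

- Defect depth = occlusal shoulder elevation − deepest surviving minimum.
  Measured in triplicate on parallel transects (default lateral offset
  25 µm, chosen to stay within one defect's lateral extent); the replicate
  mean is the depth of record.
- Perikyma depth = occlusal-side adjacent retained ridge − groove floor, for
  up to n (default 10) grooves per tooth. The occlusal ridge was chosen over
  "either ridge" for consistency with the defect convention; the convention
  is stamped into every measurement record.
- Default amplitude thresholds: 5 µm for defect search (between the
  perikymata regime, ≲4 µm, and the furrow-defect regime, ≳9 µm) and 0.2 µm
  for perikymata search (below essentially all reported perikymata depths).
  Both are parameters, because long transects and shallow features require
  lowering the threshold.

Depth measurements are shift-invariant and scale equivariantly with the
elevations; both properties are property-tested.

## Form removal and its bias

Plane fits are ordinary least squares on all measured cells. Sphere fits use
the algebraic (Kåsa) linearization as a deterministic starting point,
refined by Levenberg–Marquardt on the radial residuals (parameter tolerance
10⁻⁶ µm, ≤100 iterations); the hemisphere branch is chosen from the data
side of the fitted center. Forms are always fitted to the whole field,
mimicking whole-field leveling in profilometer software — which is precisely
what produces the bias: the fit is dragged into deep defects, so leveled
defect depths read shallower than raw, while the residual slope introduced at
perikymata sites makes leveled perikymata read deeper.

`leveling_bias` reports, per feature and in summary, percent differences with
the raw value as denominator — positive = "leveled shallower" for defects and
positive = "leveled deeper" for perikymata, matching the direction each bias
takes. Replicability comparisons between two imaging sessions use the same
arithmetic with the symmetric (pair-mean) denominator, since neither session
is privileged.

A geometric note on the direction tests: for plane removal the leveled-minus-
raw depth change of *any* feature is b·Δ, where b is the fitted tilt along
the transect and Δ > 0 the occlusal-reference-to-floor distance. Both feature
kinds therefore shift the same way under a plane on one field, and the
opposite-direction pair of effects is realized across the two kinds of scan
fields actually used in practice: a defect-centered field (defect cervical of
the local curvature apex → b < 0 → leveled defects shallower, and the sphere
additionally dips into the furrow) and a perikymata field on an occlusal
flank rising toward the cervix (raw depths are slope-deflated; removing the
slope makes them deeper). With the sphere form, both directions do hold on a
single field, and the suite tests that too.

## Severity ratios and statistics

Severity ratio = defect depth ÷ median perikymata depth of the same tooth
(same specimen and tooth type). If the tooth's perikymata are flagged
unpreserved, the fallback reference is the median over all perikymata of that
species and tooth type; the reference kind is recorded per ratio, and the
fallback fires for exactly the flagged teeth. Ratios are unit-free and
invariant under common rescaling of all depths.

Depths are natural-log-transformed before analysis (their distributions are
right-skewed); severity ratios are log-transformed by default as well (log
preserves ratio symmetry), with an untransformed option. Correlation between
perikymata and defect depth uses Pearson's r on log tooth medians, reporting
R² = r².

Group comparisons are linear mixed models with a specimen-level random
intercept, REML-fitted via statsmodels `MixedLM`. Specimens contribute
multiple teeth and features, and matched defects across teeth of one
dentition share a stress episode; the random intercept absorbs that
dependence, so matched defects are deliberately not collapsed. The fixed
factor is tested with a Wald F whose denominator degrees of freedom follow
the containment rule — number of specimens minus the number of fixed-effect
coefficients — which reproduces the dfs conventional mixed-model software
reports for between-specimen factors (e.g. 18 specimens, 2 groups → F(1,16);
4 groups → F(3,14)). Simulation places the type-I error of this test near
the nominal 5% (observed ≈ 0.04–0.05 over 500 null replicates at 18
specimens) and 95% CI coverage of a log-scale group effect near 0.95.
Pairwise post-hoc contrasts are adjusted Tukey-style via the
studentized-range distribution on the containment df by default (Holm
selectable); the adjustment method is recorded in the output.

## Synthetic surfaces and cohorts

The generator emulates a midcrown scan strip:

elevation(x, y) = crown form(y) + perikymata ripple(y) + defect furrows(y),
then Gaussian noise, spike artifacts and dropouts.

- Crown form: circular arc along the cuspo-cervical axis with configurable
  radius (default 5000 µm, a realistic anterior-crown scale; ∞ = flat) and
  apex position.
- Perikymata: per-groove depths drawn once from N(mean, sd) (defaults
  1.5 ± 0.3 µm, the published anterior-tooth regime), spacing 45 µm at the
  occlusal edge tightening toward the cervix (gradient 0.15), groove shape an
  asymmetric raised-cosine (cervically skewed) so ridges sit at elevation 0
  and groove floors exactly at −depth: the nominal per-groove depth is the
  feature's amplitude by construction.
- Defects: Gaussian furrows (width = FWHM, spanning several perikymata;
  depth 10–100 µm regimes as published). Box-shaped "plane-form" defects are
  available but excluded from default validation runs, matching the
  furrow-form measurement scope.
- Instrument effects: noise sd 0.05 µm, spike rate 5·10⁻⁴ at ±50 µm, dropout
  1.5% (the 98–99.9% measured-point regime). One seed drives all stochastic
  components; identical spec + seed reproduces surfaces bit for bit.

Ground truth carries two depths per feature. The *nominal* amplitude is the
feature component's construction parameter (form excluded). The *surface*
depth applies the package's own occlusal-shoulder convention to a densely
sampled (quarter-pixel) noise-free analytic profile of the full surface,
form included. Recovery checks compare the gridded pipeline against the
dense analytic truth: on a curved crown the form difference between shoulder
and floor is part of what the convention measures (several µm at crown radius
2000 µm), so nominal amplitudes cannot serve as a percent-level reference for
raw measurements — that gap is the curvature sensitivity the short-transect
protocol manages, and it is tested separately as a curved-vs-flat comparison
(< 5% change for a 200 µm transect on a 5000 µm crown; the shift scales as
(half-span)²/(2·radius·depth)).

Cohort generation is hierarchical: multiplicative lognormal specimen effects
(sd 0.25 on the log scale), tooth-level perikymata medians (canines 1.7×
deeper than incisors), 10 perikymata records per preserved tooth, and defect
depths = severity draw × the tooth's true median (severity geometric mean 17,
log-sd 0.35, matching published severity-ratio medians). A configurable
fraction of teeth (default 12/71) is flagged unpreserved — contributing no
perikymata records and forcing the fallback reference — with the constraint
that no (taxon, tooth-type) reference pool is ever emptied, so the fallback
rule remains exercisable at any seed.

What the generator does *not* emulate: wear and calculus obscuring the
surface, pits and plane-form defect morphology in the default runs,
mesiodistal curvature (features are uniform across x), perikymata
count/spacing chronologies, and scan-strip mosaicking. Passing tests
therefore demonstrate correctness of the measurement chain and statistics
under known geometry and noise, not robustness to every taphonomic condition
of real archaeological surfaces.

## Problem sizes and numerical choices

Validation runs use scan strips of 60–100 × 200–1500 µm at 0.5–2 µm pitch
(up to ~5·10⁴ gridded points per field), 500 null and 200 effect-recovery
mixed-model replicates at 18 specimens, and 1000 random profiles for the
peak-finder oracle; these sizes give stable statistics while keeping the
whole suite inside a coffee break on one CPU. Degenerate inputs fail loudly:
collinear clouds (no triangulation), coplanar cells (no sphere), single
specimens (random intercept inestimable, with a fixed-effects fallback
suggested), empty replicate sets, nonpositive depths under log transforms,
and zero-variance correlations are all explicit errors rather than NaNs.
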