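# Methods

This note records the statistical procedures the package implements, the
defaults it ships, and the choices made where more than one defensible
convention exists.

## Factor coding and designs

Every method parameter is handled in a coded metric,
`coded = (physical − center) / step`.  Decoding rounds to a per-factor
number of decimals that matches how the setting is dialed in on the
instrument (whole mM and kV, two decimals of pH).  The embedded CCD
stores *exact* coded levels (±1, 0, ±α) while its physical table shows
the rounded values an operator would set; the loader snaps
rounding-induced offsets (≤0.02 coded units) back onto the exact levels
so that orthogonality is preserved to machine precision.

The orthogonal central composite design places a regular two-level
fraction at ±1, one low/high axial pair per factor at ±α and `n_center`
center runs.  α is always recomputed from the geometry,
α² = (√(N·F) − F)/2 with F factorial and N total runs, which makes the
centered pure-quadratic columns of the model matrix mutually orthogonal
and orthogonal to the intercept (verified in the tests by brute-force
moment computation).  For the study geometry (F = 16, N = 29) this gives
α = 1.6644.  Half fractions use the maximum-resolution defining relation
I = AB…K and are refused below five factors, where the resolution would
drop under V and alias interactions with main effects.  Run order is
deterministic (factorial, axial, center); randomization is out of scope
because the package analyzes fixed printed tables.

Plackett-Burman designs come from the standard cyclic first rows for
8–24 runs; columns are exactly orthogonal (X'X = n·I) and balanced.  The
default size for k factors is the smallest supported design with at
least four unassigned (dummy) columns, i.e. n ≥ k + 5.

The 16-run, seven-factor, three-level screening array is an orthogonal
array of external (software-vendor) origin whose construction algorithm
is not public; it ships as a checksummed fixture, and any user-supplied
orthogonal array can be loaded in its place.

## Screening fit

The Free-Wilson model assigns one additive effect per factor level under
sum-to-zero (deviation) coding: a run at level 1 of a factor contributes
(1, 0) to that factor's two columns, level 2 (0, 1), level 3 (−1, −1).
This was chosen over reference-cell coding because the natural display
is all three level effects per factor; the third coefficient is the
negative sum of the other two.  On the embedded screen the 16×15 model
matrix has rank 15 and a single residual degree of freedom.  Because the
model saturates the 15 distinct rows, the residual mean square equals
the pure error of the duplicated center pair exactly; both error
conventions are nevertheless exposed (`level_contrasts(error=...)`)
since screening software differs on this point.  Whole-model ANOVA is
the F test against the intercept-only model; with one error df it has
very little power, and borderline verdicts (p near 0.05) should be read
accordingly.  Level-change contrasts (2→1, 3→2, 3→1) are t tests with
var(c'β̂) = c'(X'X)⁻¹c·s².  The significance level defaults to 0.05
everywhere and is configurable.

## Response surfaces

The full quadratic model on k factors has 1 + 2k + k(k−1)/2 terms in a
fixed canonical order (intercept, linear, quadratic, interactions).
Responses that are strictly positive and span orders of magnitude (plate
counts) are fitted on log10; log10 rather than natural log so that the
acceptance threshold N ≥ 10,000 is the round number 4.0 on the fitting
scale.  Runs with a missing response are excluded from that response's
fit only — in the embedded study the three co-migration runs (signed
resolution exactly zero) have no measurable efficiency, leaving 26 runs
for the log-efficiency model while all other responses keep 29.

Quality metrics are computed on the fitting scale: R² = 1 − SSE/SS_tot
and Q² = 1 − PRESS/SS_tot with PRESS from the exact leave-one-out
identity e_i/(1 − h_ii); a leverage of 1 (self-predicting run) raises
rather than returning a misleading number.  Q² may legitimately be
negative; a zero-floored variant is exposed alongside the raw value
because some commercial RSM packages floor it.

Backward refinement: among the currently non-significant terms
(p > 0.05, t tests with the current model's residual df), drop the one
whose removal raises Q² the most; stop when no removal raises Q².  Ties
within 1e-12 of Q² go to the larger p, then to the later canonical term.
The intercept is never dropped and model heredity is *not* enforced (a
quadratic can outlive its linear parent), matching the default of the
commercial software this workflow mirrors.  By construction refinement
never lowers Q², and removing terms never raises R².

Predictions back-transform the point estimate (10^mean) for log models,
with no smearing correction: compliance checking happens per Monte Carlo
draw on the original scale, where the question of mean-transform bias
does not arise.  The prediction standard deviation combines coefficient
covariance and residual variance on the fitting scale,
x'(X'X)⁻¹x·s² + s².  Predictions beyond a coded radius of α + 0.1 warn
about extrapolation.

Sweet-spot overlays count, at each grid node, how many CMA thresholds
the mean predictions satisfy.  The default trellis mirrors the study's
reporting layout: cyclodextrin concentration vs pH panels at three
levels each of voltage and buffer concentration, butanol fixed at its
center; 61×61 nodes per panel for mean-prediction overlays.

## MODR Monte Carlo

Per draw, each model's coefficient vector is sampled from
N(β̂, s²(X'X)⁻¹) and residual noise N(0, s²) is added on the fitting
scale; log-scale draws are exponentiated before spec checking, so the
efficiency threshold applies to simulated plate counts, not to means.
Sampling both uncertainty sources is the default and either can be
disabled, since design-space engines differ on what they propagate.
DPMO = 10⁶·(1 − p); a node is inside the MODR when DPMO ≤ 100,000
(risk ≤ 10%).  The default is 20,000 draws per evaluation (binomial SE
≈ 0.2 percentage points near 10% risk); risk maps trade draws for nodes
(2,000 per node by default) and each map node consumes its own
deterministic seed stream derived from the single study seed, so any
node is exactly reproducible in isolation.

The MODR *box* is a reporting convenience around the working point: each
axis is expanded by bisection (other factors held at the working point)
until the pass probability drops below the target, then the box is
validated at all 2^k vertices and shrunk proportionally (factor 0.95 per
iteration) until every vertex complies.  Because all k coordinates sit
at extremes simultaneously at a vertex, this validation is far stricter
than the per-axis scan and the returned box is deliberately
conservative — the probability map, not the box, is the primary
design-space artifact.  The embedded study carries two fixed parameters
(surfactant 65.0 mM, temperature 22 °C) that are never simulated.

Note: the source study's own reporting of the cyclodextrin MODR interval
is internally inconsistent (17–23 mM in the results text vs 21–26 mM in
the summary tables, the latter excluding the 20 mM working point); the
package takes no side — it reports whatever its own simulation yields.

## Robustness and suitability

Main effects on the Plackett-Burman design are contrast means
(mean high − mean low), exactly twice the regression coefficients.  The
noise yardstick defaults to the root-mean-square of the dummy-column
effects (df = number of dummies) and falls back to the regression
residual when fewer than two dummies exist.  Suitability ranges are the
observed [min, max] per response; when a model prediction exceeds the
observed maximum the upper limit is raised and flagged (`widened`), the
convention used for plate counts in practice; downward widening exists
but is off by default.  The original study's robustness data are not
public, so the pipeline exercises this stage on synthetic studies
generated around the working point with perturbations of 0.05 pH,
1 mM buffer, 1 mM cyclodextrin, 1.5 kV (half of the 3 kV minimum
practical voltage window), 0.10% butanol, 2.5 mM surfactant and 1 °C —
magnitudes a laboratory would use for a deliberate-variation study.

## Synthetic-data generator

`TruthModel` draws responses from a known quadratic truth on the coded
domain with additive Gaussian noise; log-scale responses are generated
on the log scale and exponentiated, so they are strictly positive.  The
co-migration rule censors the efficiency response wherever the simulated
signed resolution falls within |R3| < 0.05 — the tolerance reflects that
co-migration is recorded as a resolution of exactly 0.00 at reporting
precision.  `truth_from_table3` uses the refined fitted models as truth
with their residual sd as noise, which makes the generator's working
point compliant by construction (~93% joint pass) and reproduces the
migration-order inversion across the pH axis.  A separate additive
per-level generator supports Free-Wilson recovery tests.

What the generator does *not* emulate: electropherogram-level structure
(peak shapes, baseline drift, integration error), heteroscedastic or
correlated response noise, run-order drift, and day/analyst blocks.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
features.

A closure property worth recording: regenerating 50 studies from the
fitted truth and re-running fit → refine → Monte Carlo yields a working
point that stays MODR-compliant in about three quarters of replicates
(median replicate pass probability ≈ 96%), with a genuine lower tail
caused by refit variability near the 90% boundary.  This is the honest
sampling behavior of the full workflow at n = 29 runs, and the tests
assert exactly that measured level.

## Problem sizes

Default analyses are desk-scale: 16- and 29-run embedded studies, 21-61
node grid axes, 2,000-20,000 Monte Carlo draws per evaluation, 50-500
replicate simulation studies in the test suite.  All are package
defaults chosen to keep a full analysis interactive on a single core.

## Known limitations

* Backward elimination explores single-term removals greedily; it can
  miss term sets a best-subset search would find.
* The MODR box assumes the compliant region is locally box-approximable
  around the working point; strongly curved regions make it very small.
* No Box-Cox transform search, D-optimal augmentation, blocking, or
  desirability-function optimization.
* Whole-model screening ANOVA with a single residual df is nearly
  powerless; its verdicts are reported but should not drive decisions
  alone.
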