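# Methods

This note records the models, conventions and numerical choices behind
`pbomics`, and what its synthetic-data tests do and do not demonstrate.

## Spectral bucketing and normalization

Buckets are left-closed, right-open intervals `[lo, hi)` tiling the scheme
range; a trailing partial bucket (the HRMAS range 0.50–5.60 ppm is not an
integer number of 0.04 ppm widths) is dropped, so all features have equal
width. A bucket is removed whenever its interval overlaps an exclusion
region with positive length — conservative removal, chosen because the
plasma water exclusion (4.68–5.15 ppm) is not aligned to the 0.02 ppm grid.
Bucket edges are reconstructed from integer multiples of the width, so no
float drift accumulates across hundreds of buckets.

Integration uses the trapezoidal rule on the native ppm grid, with bucket
edges inserted by linear interpolation before accumulating. The integral of
a piecewise-linear signal is therefore exact: kept-bucket integrals plus
excluded-region integrals equal the full-range integral to rounding error.
Whether the original analysis summed raw points or trapezoids is
unknowable from the outside; for the uniform grids used here the two differ
by a constant factor per spectrum, which the constant-sum normalization
removes, so the choice is recorded rather than consequential.

Each spectrum is normalized so its row total is 10 000, making every bucket
a fraction of total observed signal (a proxy for relative concentration).
When a few resonances dominate — glucose and glycogen in liver extracts —
the table can be renormalized with those regions (3.35–4.05, 4.60–4.72,
5.20–5.55 ppm) removed, re-exposing dose responses of minor metabolites.
Referencing, phasing and baseline correction are assumed done upstream; the
package never modifies the ppm axis.

## PCA and PLS

Pareto scaling (centered column / √SD) is the default for binned NMR data:
it suppresses noise-only regions without letting them dominate, while
unit-variance scaling is used for peak tables and for the transcriptome
block in fusion, where every feature is an identified entity. Zero-variance
columns cannot be scaled and are dropped with a warning. SDs use the n−1
convention.

PCA is computed from the SVD of the scaled matrix. PLS uses NIPALS with
deflation of both blocks; the weight vector is seeded from X'u with u the
largest-variance Y column, so fits are deterministic, and for a single
response the inner loop is exact after one pass. Convergence tolerance for
multi-Y problems is 1e−12 on the score vector with a 500-iteration cap. If
a residual X block carries no covariance with the residual Y (e.g. Y
orthogonal to all X columns), component extraction stops and R²Y simply
stops growing — no error, matching the convention that such a model has no
predictive power rather than being invalid.

### Cross-validated Q²

Segments are round-robin by input order: segment *k* holds samples with
index ≡ *k* (mod 7). This is the deterministic "exclude every 7th sample"
convention; random segmentation would make Q² seed-dependent. For each
component count *a*, the model (including centering/scaling) is refit
without each segment and the held-out responses predicted:

    PRESS_a = Σ (y − ŷ₍₋segment₎)²,  Q²_a = 1 − PRESS_a / SS_{a−1}

with SS₀ the total sum of squares of centered Y and SS_{a−1} the residual
sum of squares of the full-data model after a−1 components; the cumulative
Q² is 1 − Π_a (PRESS_a/SS_{a−1}). Component counts can be selected by
adding components only while Q²_a > 0.05 (configurable); the dose models on
synthetic data need one.

### Validation

`permutation_validate` permutes the response rows uniformly (default 200
iterations for dose models, 30 for fusion), refits, and records the
|correlation| of the permuted with the original response alongside R² and
Q² — the data behind the standard validate plot. `predict_left_out` makes
the complementary check: random folds (default 7), five repetitions, each
sample predicted by a model that never saw it; predicted dose should track
true dose group. The fold structure for this check is a recorded choice
(random, 5 repeats); nothing downstream depends on it.

Dose enters PLS as the raw ppm value (0/50/500/1000) in a single Y column.
Because biological responses saturate near the top dose, the attainable
group-level correlation between a saturating profile and raw dose caps the
dose-model Q² near 0.7 — which is precisely the regime such studies report.

## The expression cascade

The stages run strictly in order and only remove probesets: arrays are
normalized to mean 500; values are floored at 0.01 and divided by the row
median; the detection filter keeps probesets with ≥ 3 Present flags *and*
intensity ≥ 90 in ≥ 3 samples (the 90-threshold is applied to globally
normalized, pre-per-gene values); the fold-change filter keeps probesets
whose treated-group median differs ≥ 1.5-fold from the time-matched control
median, in either direction, in at least one (dose, day) cell; finally a
two-way ANOVA with dose and day as categorical factors plus interaction is
computed on log2 values (expression changes are multiplicative; log2
stabilises variance), with BH step-up FDR control per term across
probesets. A probeset is "significant" when its adjusted treatment (dose)
p-value is below 0.05; interaction-only probesets are reported separately,
since a cascade defined only as "on time and treatment" is ambiguous about
them. The intensity filter is read as *requiring* ≥ 3 samples at ≥ 90; the
literal inverse reading ("< 90 in ≥ 3 samples excluded") would discard
nearly everything in an 80-sample study.

Balanced designs use an exact vectorised sums-of-squares computation across
all probesets at once (verified against statsmodels OLS per gene);
unbalanced designs fall back to per-gene type-II OLS. A (dose, day) cell
with fewer than two replicates forces the interaction term to be dropped,
with a log message.

Ratio profiles (sample / same-day control median) feed hierarchical
clustering with distance 1 − Pearson r and average linkage (complete
available); the linkage is scipy's, checked against brute-force nearest-pair
agglomeration. Term over-representation uses the upper-tail hypergeometric
p-value with no multiple-testing correction, with a qualifying rule of
overlap ≥ 1 for GO-style term maps and overlap ≥ 3 for pathway-style maps,
both at p < 0.05. The pathway overlay simply flags pathways containing at
least one changed transcript *and* one changed metabolite — a report
generator, not a test.

## Fusion

For each metabolite, PLS1 with the expression matrix (unit-variance scaled)
as X and the metabolite as y; Q² from 7 round-robin segments; 30 response
permutations. The model is accepted iff Q² > 0.40 and the real Q² exceeds
every permuted Q². Under a global null the permutation hurdle alone gives a
pass probability of about 1/31, and the Q² threshold reduces it further —
measured at 0 of 200 null runs. "Loadings" are the first component's
X-weights w (for a single response the w*c loading used in commercial
software reduces to w), ranked by |w| with ties broken by probeset id. One
component is the default, as correlate-hunting examines the first component
only; the count is configurable. The fusion X-block defaults to the full
detection-filtered transcriptome; restricting it to the
differentially-expressed subset is a caller choice.

## Endpoint statistics

One-way ANOVA and two-sided Dunnett many-to-one comparisons are computed
from group (mean, SD, n) summaries, which are sufficient statistics for the
one-way layout — raw vectors give identical results. The Dunnett adjusted
p-value is P(max_i |T_i| ≥ |t_obs|) for the equicorrelated multivariate t
(correlation 1/2 when groups are balanced); conditioning on the shared
control mean and the pooled variance makes the comparisons independent,
leaving a 2-D quadrature: 96-node Gauss–Hermite over the control mean and
128-node Gauss–Legendre over the probability transform of the pooled SD.
Agreement with an independent randomized-quadrature implementation is ~1e−4,
well below any flagging decision. Two-sided tests are used throughout (the
direction of endpoint changes is not pre-specified). Percent change rounds
half away from zero, which is what reproduces published integer percents.

The lipid tally counts a fatty acid once per occurrence — a diacyl species
with two identical chains counts that chain twice (configurable to count
species once); headgroup rows always count species once. Totals are
reported with the free-fatty-acid/monoacyl/diacyl breakdown.

## The synthetic study

The generator emulates the 4-dose × 4-day × 5-replicate design. Dose acts
through u = log(dose+1)/log(1001) ∈ {0, 0.57, 0.90, 1} — a saturating
transform chosen because published fold changes at 500 and 1000 ppm are
near-equal. Planted spectral effects: glucose and glycogen halve at the top
dose, succinate rises 1.8×, adenosine falls to 0.7×, glutamine and
glutathione rise early and fade by day 14. Spectra are sums of positive
Lorentzians (half-width 0.006 ppm) on a 0.01 baseline, so intensities are
strictly positive and interval integrals analytic; within-animal variation
is lognormal on the concentrations with log-SD 0.12, a typical biological
CV for liver extract metabolites, and the value that places the dose-model
Q² at 0.61–0.66 — inside the 0.4–0.7 range such models report.

Expression: a ten-probeset panel carries fold changes from ~0.3× to ~25×
with per-day profiles (transient induction, late induction, sustained
repression); residual log2 noise is 0.15 (replicate CV ≈ 11%, typical of
MAS5-summarised expressed genes). Panel base intensities are bounded by
each probeset's maximum fold change so that strongly induced genes do not
dominate the array total — on a genome-wide array the changed probesets are
a small fraction of total signal, and without the bound the mean-to-500
normalization would imprint an artifactual dose effect on every null gene.
Gene–metabolite links are built by projecting a noise vector orthogonal to
the standardised metabolite before mixing, so the sample Pearson
correlation equals the target exactly; the aminolevulinate-synthase
surrogate tracks succinate at r = 0.9, and a malic-enzyme /
glutathione-reductase pair shares a glutathione latent at r = √0.7 each,
making the pair correlate at r ≈ 0.7. Ten percent of null probesets are
"unexpressed" (low intensity, Present with probability 0.05 instead of
0.95) so the detection filter has real work. Detection flags are Bernoulli,
independent of intensity — only the ≥ 3-flag rule consumes them.

All generators are pure functions of (arguments, seed); the master seed is
split into independent child streams per sub-generator, so e.g. adding a
metabolite does not perturb the expression draw.

### What passing tests show — and don't

The generator plants linear(ised) links, Lorentzian peaks on a clean
baseline, and independent noise. Real spectra add peak overlap, chemical-
shift drift, baseline error and correlated biology; real arrays add probe
effects and heavier-tailed noise. Passing the recovery tests therefore
shows the *procedures* are implemented correctly and behave as designed in
their intended regime — not that the same sensitivity/FDR/Q² would be
achieved on real data. Published headline values that depend on the
original animals (specific Q² values per day and platform, the exact count
of significant probesets) are deliberately not targets; the tests check
regimes and operating characteristics instead.

## Problem sizes and determinism

Default test and acceptance sizes: 80 samples, 942 liver buckets, 513
probesets (10 panel + 3 linked + 500 null), 50-seed replications for
operating characteristics and 200 runs for null specificity — sizes at
which every check completes in seconds to a few minutes on one core while
keeping Monte-Carlo error well inside the asserted margins. Every source of
randomness flows from explicit seeds; pipeline runs embed a config hash and
are byte-identical when re-run with an identical configuration.

## Known limitations

* No raw-signal processing (phasing, baseline, peak alignment or
  assignment) and no probe-level array summarisation — inputs are bucketed
  or bucket-ready spectra and probeset-level intensities with flags.
* OPLS, variable selection (VIP), kernel PLS and confidence ellipses are
  out of scope; so are sparse multi-omic factor models (CCA/MOFA-style).
* The Dunnett computation assumes a common within-group variance, as the
  classical test does.
* Fusion ranks correlates; it makes no causal claim about gene → metabolite
  direction.
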