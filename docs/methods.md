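# Methods

This note documents the models, conventions and numerical choices behind
`nectarweb`, and what the synthetic scenarios can and cannot demonstrate.

## Trait matching

Nectar use requires a temporal match and a morphological match.

**Temporal.** Nectar is *available* to a parasitoid when it is produced
during the adult flight period. In `window` mode this is an inclusive
day-of-year interval intersection (at least one shared day) between the
flowering window and the activity window; extrafloral producers use their
production window instead, which defaults to the whole season because
extrafloral nectaries are not tied to anthesis. In `survey` mode
availability is judged from a phenology snapshot: the recorded stage on the
11-point (0–10) scale must fall in the flowering range — stages 5–8 by
default, configurable — and the survey date must fall inside the activity
window; extrafloral producers only need to be present.

**Morphological.** The decision tree uses three constraints, with head
radius `r = head_width/2` (the convention adopted here, since head *width*
is what is measured):

1. *penetration* — the head enters the corolla iff `w >= 2r`;
2. *reach* — corolla height `h` and nectar depth `p` are treated as disjoint
   segments along the flower axis (total depth `h + p`); an insect whose
   head enters needs `x >= p`, an excluded insect needs `x >= h + p`;
3. *tube width* — where a nectar tube is recorded (`d` present), `z <= d`;
   open nectaries skip the check.

Extrafloral nectar short-circuits the tree as accessible. Missing flower
morphology yields a conservative *inaccessible* verdict with a distinct
reason code and a warning — never an exception and never silent access. The
disjoint-segments convention is one of two defensible geometric readings
(the other nests `p` inside `h`); it is isolated in `nectar_accessible` and
can be swapped without touching anything downstream. An independently coded
nested-conditional oracle and a 5^7-point parameter sweep in the test suite
pin the implemented semantics.

`tube_diameter = None` means "no narrow tube" for the tree but counts as a
missing value in `trait_coverage_report`, which is the conservative reading
for data-completeness reporting.

## Functional diversity

Gower dissimilarity treats all traits with equal weight: range-scaled
absolute differences for quantitative traits (a constant trait contributes
zero), 0/1 mismatch for categorical and binary traits, pairwise deletion
with renormalization for missing values (a species pair sharing no observed
trait is an error naming the pair). FDis embeds the matrix by principal
coordinates; when negative eigenvalues exceed 1e-8 of the largest magnitude
the Cailliez constant is added to off-diagonal dissimilarities first. FDis
is the abundance-weighted mean distance to the abundance-weighted centroid;
Rao Q uses `d_ij` (not squared). Both are computed and reported; the
pipeline's regressions use FDis, with Rao retained for the correlation
check (the two are nearly collinear on realistic communities — the
acceptance script reports their correlation).

## Mixed models

One-random-intercept binomial (logit) and Poisson (log) GLMMs, fitted by
maximum likelihood. The marginal likelihood per grouping level is
integrated by *adaptive* Gauss–Hermite quadrature: a damped Newton step
finds the conditional mode of the random effect, the rule is recentred and
rescaled by the conditional curvature, and 15 nodes (default) integrate the
conditional likelihood; one node recovers the Laplace approximation. For
the group sizes used here 15 nodes agree with 51 nodes to < 1e-6 in
log-likelihood, and the fitter matches `lme4::glmer` (nAGQ = 15) to ~1e-4
on coefficients, standard errors and the random-effect SD on a fixture
dataset (a cross-check test, not the implementation).

Optimization is BFGS on `(beta, log sigma_u)` with the quadrature
approximation of the score (posterior-weighted score contributions);
gradient tolerance 1e-8, with any stationary point below 1e-3 accepted
because the approximate score is only consistent with the objective to
quadrature accuracy. Three fixed starting points (GLM coefficients with
sigma_u in {0.3, 1.0, 0.05}) are available; the all-subsets and neutral
loops use the first start only and escalate to the others on failure, a
throughput choice that changed no fit in testing. Fewer than two grouping
levels collapses to the GLM with `sigma_u = 0`; an interior optimum drifting
to `sigma_u < 1e-4` is snapped to the GLM solution when the GLM likelihood
is at least as good. `AIC = -2 logLik + 2k` with `k` = fixed effects + 1
(the variance parameter is always counted, including in the degenerate
single-group case). Covariances come from central differences of the score
at the optimum.

Type-II Wald tests respect marginality: a term with higher-order relatives
in the model (its quadratic, or an interaction containing it) is tested in
a refit without those relatives; a maximal term is tested directly via
`b' V^{-1} b` on the full fit. Pseudo-R² follows the variance-partition
formulation with distribution-specific variance π²/3 (binomial-logit) and
`ln(1 + 1/exp(beta0))` (Poisson-log, using the fitted intercept).

## Multimodel inference

Covariates are z-scored on the analysis dataset; quadratics are squares of
the scaled term and interactions products of scaled terms. The candidate
set enumerates all additive combinations of the nine predictors with
marginality enforced (quadratic requires its linear term; an interaction
requires every lower-order term it dominates), giving 95 models; a switch
disables marginality. Ranking is by ML AIC; the confidence set is strictly
`ΔAIC < 2`. Conditional averaging renormalizes Akaike weights within the
set, averages each coefficient over the members containing it, and uses the
revised unconditional-variance estimator
`SE = Σ w_m sqrt(se_m² + (b_m − b̄)²)` for the adjusted SE; a term's
importance is the summed renormalized weight of the selected members
containing it (an option computes it over the full candidate set instead).
Exact ΔAIC = 2 ties are excluded by the strict inequality; non-converged
candidates are dropped with a logged count.

A caution documented here deliberately: with a strictly-ΔAIC<2 set, any
one-term extension of the best model enters the set whenever it improves
the deviance at all, so "importance" of genuinely null predictors has
substantial probability mass above 0.5. This is a property of the averaging
convention, not a defect of the fitter; simulation in the test suite
quantifies it.

## Multi-threshold multi-species parasitism

Reference maxima are computed per herbivore and distance as the mean of the
three highest plot-level rates (fewer than three rates: mean of what
exists, with a warning). For each plot and threshold τ in 0.1 … 0.9 the
statistic counts herbivores whose rate *strictly exceeds* τ times their
reference maximum; exact ties are logged. Plots missing any herbivore are
dropped by default (option: count over available herbivores). The counts
(27 complete plots × 9 thresholds = 243 rows at the near distance) are
modelled as Poisson GLMMs with the strip random intercept; the candidate
pool is the community predictors (linear + quadratic), the threshold (also
z-scored, like every explanatory variable) and threshold-by-predictor
interactions including threshold-by-quadratic, with at most five
fixed-effect variables per model. Partial-effect curves are predicted from
the conditional averaged coefficients at mean covariates.

## Neutral model

For each parasitoid, the observed interaction count `k` is the number of
species in the community whose nectar is available and accessible. Each
iteration draws `k` species uniformly without replacement from one of two
pools — species in flower during the parasitoid's activity (tests the
morphological match alone) or all species present (tests temporal +
morphological) — sums their cover per plot, re-standardizes, and refits the
*top-ranked* trait-matching model's formula with the covariate swapped (a
full model-selection rerun per iteration would be another defensible
reading; the single-formula refit was chosen for tractability and is the
variant implemented). 1000 iterations per parasitoid by default. Seeds flow
master → per-comparison → per-iteration via named `SeedSequence`
substreams, so reports are bit-identical under a fixed seed. Iteration
failures are logged and excluded; above 10% failures the comparison errors
out.

## Synthetic scenarios

The generator emulates the design: nine treatments (two identity sets ×
{low-FD/14, high-FD/9, high-FD/14, high-FD/29 sown species} + unsown
control) × three strips; a pool of 85 species (55 sown candidates, 30
spontaneous) with log-normal flower morphologies (mm), categorical nectar
types and colors, uniform flowering onsets/durations; low-FD assemblages
are built by nearest-neighbour clustering in Gower space and high-FD
assemblages by greedy max–min dispersion, so the sown FD contrast holds by
construction. Covers are Dirichlet-distributed (sown total 60–90%,
spontaneous 3–10%, control 15–30%). Seven parasitoid taxa get log-normal
morphologies and staggered 30–60-day activity windows. Parasitism is
binomial per plot × distance × herbivore with 20–200 hosts examined:
`logit(rate) = b0_h + decay_d (bn Z_nectar + br Z_rich + bf Z_fdis +
bf2 Z_fdis²) + u_strip`, `u ~ N(0, sigma_strip²)`. Defaults: herbivore
baselines spanning rates ~0.11–0.45, `bn = 0.5`, `bf2 = -0.4`, `br = bf = 0`,
`sigma_strip = 0.3` (a plausible placeholder; the field value is unknown and
it is exposed in the config), distance attenuation 1.0 at 5 m and 0.4 at
20 m, season days 60–240. The hump is injected on the latent logit scale per
herbivore; the multi-species hump then *emerges* through the counting
statistic rather than being forced into it.

What passing tests show — and do not. The generator mirrors the analysis
model family, so parameter-recovery, power and calibration results validate
the estimation and inference machinery, not the field biology: real data
carry overdispersion, spatial structure, phenology measurement error and
trait–environment correlations the generator omits. Problem sizes in the
test suite (100 replicates for selection and hump-recovery properties, 50
datasets × 200 iterations for the neutral-model power and calibration, 200
datasets for coverage) were chosen as the package's own compromise between
Monte-Carlo error and suite runtime.

## Degenerate inputs and tie-breaks

Single-species communities have FDis = Rao = 0 by definition. Random-effect
selection breaks AIC ties (within 1e-9) toward the first candidate, logged.
Zero-range quantitative traits contribute zero dissimilarity. Plots with no
positive cover are rejected. Survey stages outside 0–10 and negative
morphologies raise; missing morphology degrades to warnings.

## Known limitations

The exact branch order of field decision trees of this kind — and whether
nectar depth is measured to include corolla height — varies between
protocols; the implemented tree honors the three constraints above and is
isolated in one function for replacement. Only one random intercept is supported (no
crossed/nested terms, no observation-level overdispersion term). The
averaged-model prediction curves use conditional averaged coefficients
rather than weight-averaged per-model predictions. Cross-distance tests,
post-hoc pairwise treatment comparisons and residual-diagnostic suites are
out of scope.
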