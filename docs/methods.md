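# Methods

## Thermal-requirement estimation

The linear degree-day model assumes the developmental rate r = 1/t (t the
development time in days at constant temperature T) follows
r(T) = a + b·T over the species' ecologically relevant range (roughly a
20 °C window below the optimum). The lower developmental threshold is the
rate line's zero, LDT = −a/b, and the sum of effective temperatures its
reciprocal slope, SET = 1/b. The model deliberately ignores the nonlinear
roll-off near the thermal optimum and any upper threshold; fits should only
be fed observations from the quasi-linear range.

Estimation is ordinary least squares of per-observation rates on
temperature. Regressing individual replicate rates (the default) preserves
replicate weighting; `on_means=True` collapses to per-temperature mean
rates for reproducing studies that published treatment means only. At least
three distinct temperatures are required — two points determine any line
and make R² meaningless. Standard errors for (LDT, SET) come from
first-order (delta-method) propagation of the coefficient covariance:

    Var(LDT) = Var(a)/b² + a²Var(b)/b⁴ − 2aCov(a,b)/b³,   Var(SET) = Var(b)/b⁴,

cross-checked in the tests against a parametric bootstrap from the
coefficient sampling distribution. The SEs are carried for reporting but
never used to weight downstream analyses, which average estimates
unweighted.

Aggregation across independently studied populations of a species uses a
robust screen before the unweighted mean: estimates farther than
k·1.4826·MAD (default k = 3) from the cross-population median — screened
independently for LDT and SET, with a joint option — are discarded and
logged. This quantifies the otherwise subjective discarding of "obviously
different" literature values; the median-based rule can never empty the
set. Across life stages, egg-to-adult values are preferred; failing that, a
single available stage is used as-is, and with several partial stages the
LDT is averaged (all stages of a population are assumed to share a
threshold) while the SET is taken from the longest stage and flagged,
since partial-stage SETs are not additive without knowing stage coverage.

## Pair assembly

Comparison units pair one non-invasive species with invasive relatives
from the same continent of origin at the tightest shared taxonomic rank,
preferring genus, then tribe, subfamily, family. Rank identity is checked
within the enclosing order and family, missing intermediate ranks are
skipped rather than treated as mismatches, and all invasive candidates tied
at the tightest rank are averaged — deterministic and more conservative
than picking one. Non-invasive species are used at most once; invasive
species may recur across pairs (reuse is logged). Records flagged as
intentionally introduced (e.g. biological control agents), stored-product
pests or cryptogenic are excluded before matching. Matching is entirely
deterministic, so the stage needs no seed.

## Comparative inference

Three analyses of each trait against invasive status, differing in how
they treat non-independence within and between pairs:

1. **t-tests.** A pooled two-sample t (ignores pairing; sensitive to
   invasive reuse in the opposite direction) and a paired-difference t on
   per-pair differences with df = n_pairs − 1.
2. **Paired mixed model.** trait ~ status with a random intercept per pair,
   fitted by REML. Its variance components give the intraclass correlation
   ICC = σ²_pair/(σ²_pair + σ²_res) of trait values within pairs.
3. **Taxonomic mixed models.** trait ~ status with no random effect, a
   random intercept per order, or intercepts per order and per family
   nested in order; likelihood-ratio statistics L = 2(ℓ_alt − ℓ_null)
   between successive structures (1 df each) measure how much taxonomy
   explains.

All mixed models are estimated by REML with a shared in-package engine for
Gaussian random-intercept models. The marginal covariance is block-diagonal
by the coarsest factor, so the restricted likelihood is accumulated block
by block (closed form for a single factor; small dense Cholesky per block
for nested factors) and maximized with L-BFGS-B under non-negativity
bounds. This engine exists because the analysis needs two things fitting
libraries do not expose together: REML log-likelihoods computed identically
across random-effect structures including the no-random-effect model (OLS
log-likelihoods are ML, not REML, and mixing criteria invalidates the LR
sequence), and Satterthwaite denominator df. The engine is verified in the
tests against statsmodels `MixedLM` and R `lmerTest` on shared data.

Satterthwaite df for the status effect are computed as
df = 2f²/(gᵀAg), with f = Var(β̂), g its finite-difference gradient in the
variance parameters and A the inverse observed information of the
restricted likelihood (central differences). Variance components estimated
on the zero boundary are held fixed when forming the information; the df is
clipped to [1, n − p]. Negative variance estimates are not permitted
(boundary fits report 0 and ICC 0); LR statistics that come out negative by
numerical round-off are clipped to 0 and logged. All p-values are
two-sided; no multiple-testing correction is applied.

The difference correlation is a plain Pearson r of (d_LDT, d_SET) over
pairs with both differences, with a two-sided p; the concordance fraction
counts pairs with strictly opposite signs, zero differences counting as
non-concordant. Normality diagnostics report sample skewness, *excess*
kurtosis (normal = 0; stated to avoid convention drift) and the
Shapiro–Wilk test. Residual diagnostics return conditional fitted values,
residuals and per-group predicted random intercepts (BLUPs, shrunk toward
zero relative to raw group means), with a residual-vs-fitted plotting
helper.

## Phenology

Daily heat sums above the LDT use the single-sine method: the diurnal
course is modelled as m + w·sin(2πτ) with m the daily mean and w the
half-range, and the area above the threshold has the closed form
(1/π)[(m − LDT)(π/2 − θ) + w cos θ], θ = arcsin((LDT − m)/w). It reduces to
the simple-average method m − LDT when the whole day is above the threshold
(the simple-average method is available as an option). No upper cut-off is
applied — a documented limitation of the linear model. Completion is
resolved at day granularity. The crossing temperature of two rate lines,
T_c = (LDT_I·SET_N − LDT_N·SET_I)/(SET_N − SET_I), marks where the
steeper (lower-SET) line overtakes; equal SETs are parallel lines with no
finite crossing and raise an error.

## Synthetic data

`generate_development_dataset` draws rates (T − LDT)/SET + ε with Gaussian
ε on the *rate* scale (SD 0.002 day⁻¹ by default), redrawn while
non-positive, at a default design of 15/20/25/30 °C × 5 replicates. Noise
on the rate scale matches the linear-model assumption under which the
constants are estimated; real rearing data additionally carry
temperature-dependent variance and curvature near the extremes, which the
generator does not emulate.

`generate_pair_dataset` draws, per pair, a baseline trait from nested
Gaussian order/family/pair components and adds a fixed status effect;
within-pair sums and differences are drawn independently, with the
(d_LDT, d_SET) differences jointly bivariate normal so their correlation is
exactly the configured ρ. Defaults encode the study conditions the
comparative analyses target: 100 pairs, mean d_LDT = 1.4 °C,
mean d_SET = −39.3 D°, ρ = −0.276, target ICCs 0.22 (LDT) and 0.222 (SET),
12% of pairs without SET (missing completely at random). Residual SDs
follow from the paired t-statistics these conditions imply:
σ_res = |effect|·√n/(|t|·√2), giving 2.26 °C for LDT (t ≈ 4.4 at n = 100)
and 171.5 D° for SET (|t| ≈ 1.5 at n = 88); trait levels centre at 10 °C
and 400 D°, and SET values are floored at 1 D° to respect positivity. The
between-pair variance implied by the target ICC is split 25% order, 25%
family-within-order, 50% pair-specific across 6 orders × 4 families —
a plausible hierarchy chosen once, as no empirical decomposition is
available. Continents are assigned with weights 0.36/0.43/0.15 for
Europe/North America/Asia and the remainder spread over the other
continents, and each pair shares a unique genus so taxonomic matching
recovers every simulated pair at genus rank.

Because every random component is Gaussian with only these first and
second moments, moment-type statistics (means, t, ICC, r) are recovered
well, while orthant-type statistics (the share of pairs with a positive
d_LDT, the sign-concordance fraction) and the taxonomy LR statistics
depend on distributional detail and on the variance split that real data
would pin down; passing tests demonstrate correct inference under the
stated Gaussian conditions, not distributional realism of literature
compilations. All generators are driven by a single integer-seeded
`numpy.random.default_rng` stream and are fully deterministic given the
seed.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations at the sizes the
statistics need rather than at scale: 100-pair studies for the default
conditions, 500 pairs × 20 replicates for ICC recovery across generating
values, 200 replicate seeds for Monte-Carlo means and type-I error checks,
and 100-replicate averages in the acceptance script. Optimizer variance
floors are relative (10⁻¹⁰ of the response variance), boundary components
below ten floors are snapped to exactly zero, and finite-difference steps
for the Satterthwaite computation are 10⁻⁵ of each parameter's scale.

## Known limitations

* The linear rate model has no upper threshold or curvature; estimates from
  data that include supra-optimal temperatures are biased.
* Taxonomic ranks stand in for phylogeny; no formal phylogenetic
  comparative methods (PGLS, contrasts) are provided.
* The generator does not emulate literature heterogeneity (study-level
  biases, publication effects) or continent-specific trait distributions.
* Mixed models support random intercepts on nested factors only — exactly
  the structures the analyses use; crossed designs are out of scope.
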