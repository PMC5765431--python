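# Methods

`telodyn` re-implements, as a reusable and tested pipeline, the statistical
workflow of a long-term longitudinal study of relative telomere length (RTL)
in a wild cooperative-breeding passerine: qPCR relative quantification with
sample QC, variance-component repeatability, age/cohort trajectory model
selection, a measurement-error-aware test battery for within-individual
telomere lengthening, and environmental covariate models. Because the
package ships no field data, a first-class synthetic-data generator emulates
the study's statistical structure with known truth; every statistical claim
the test suite makes is a claim about behaviour on that generator.

## The observation model

All modelling happens on the square-root scale of RTL, which linearises the
age trajectories. The true sqrt-RTL of bird *i* from cohort *c* at age *t*
(years) is

    u_ic(t) = α + a_c + (β + b_c)·log t + ind_i + Σ_k γ_k x_k + J_i(t)

with cohort intercepts `a_c ~ N(0, σ²_cohort)`, cohort-specific slope
deviations `b_c ~ N(0, σ²_slope)`, individual intercepts
`ind_i ~ N(0, σ²_id)`, covariate effects γ on standardised covariates x, and
a nondecreasing elongation process `J_i`: on each inter-sample interval, with
probability `p_elong`, an `Exponential(λ)` jump is added. Jumps rather than a
smooth lengthening term encode the working hypothesis that within-individual
telomere gains are sporadic bouts against a backdrop of loglinear decline,
not a consistent trend.

Each qPCR run observes `u + p_r + ε`, with plate effects
`p_r ~ N(0, σ²_plate)` shared by all runs on a plate and independent run
noise `ε ~ N(0, σ²_meas)`. A configurable fraction of samples is re-run on a
second, distinct plate; these duplicates are the empirical
measurement-error distribution that the elongation battery exploits.
Sampling ages sit on the field rounding grid (nestling 1/12 yr, fledgling
0.5 yr, subadult 10/12 yr, adults whole years); simulated sqrt-RTL values
below 0.05 are truncated there and flagged.

### Default generator parameters

| parameter | default | role |
|---|---|---|
| cohorts × birds | 22 × 46 | ~1,000 birds, ~1,700 samples, ~420 duplicate runs |
| α (baseline sqrt-RTL) | 1.0 | intercept at age 1 yr |
| β (log-age slope) | −0.07 | loglinear decline per log-year, sqrt scale |
| σ_cohort, σ_slope | 0.015, 0.02 | cohort intercept / slope heterogeneity |
| σ_id | 0.03 | individual intercepts |
| σ_plate, σ_meas | 0.035, 0.073 | plate effects, run noise |
| p_elong, λ | 0.5, 0.1225 | elongation bout rate and mean size (sqrt scale) |
| γ | insect +0.02, tarsus −0.01, sex +0.01 | covariate effects per SD / for males |

The noise and elongation defaults are a *joint* calibration to the study
regime the pipeline targets: inter-plate repeatability of RTL ≈ 0.68,
intra-plate repeatability ≈ 0.73–0.74, and ~40–45% of within-individual
RTL changes positive, with the increase-side rank-sum comparison able to
detect the elongation signal at study-scale n. These four constraints are
mutually tight — run noise large enough to pull inter-plate repeatability
down to 0.68 also destroys rank-sum power — so the cohort-intercept SD
(the remaining free variance component) is kept small at default. Analyses
that need pronounced cohort structure (model-selection experiments)
configure `cohort_intercept_sd = 0.06` explicitly. No printed effect size
exists for elongation bouts; `p_elong` and `λ` reproduce the qualitative
variance ordering and the positive-delta fraction only.

What the generator does *not* emulate: survival/selective disappearance,
parental or inheritance effects on telomere length, spatially structured
territories, and within-plate duplicate wells. Tests passing on this
generator therefore say nothing about selective-disappearance biases in
real data.

## Quantification and QC

RTL is computed by two-efficiency relative quantification against a per-plate
reference sample, `RTL = E_T^(refCq_T − Cq_T) / E_G^(refCq_G − Cq_G)` with
default efficiencies 1.78 (telomere) and 1.92 (GAPDH). The generator's
`emit_cq` inverts this identity exactly, so quantification of emitted Cq
values reproduces the simulated RTL to numerical precision (the round-trip is
asserted at 1e−10).

QC keeps a record iff DNA concentration ≥ 15 ng/µl, 260/280 within
[1.8, 2.0] inclusive, 260/230 > 1.8, Cq_tel ≤ 25 and Cq_gapdh ≤ 26
("at least", "between", "higher than" map to ≥, closed interval, strict >).
Exclusions carry the first failing reason in a fixed order (conc → 260/280 →
260/230 → Cq_tel → Cq_gapdh); records with missing QC fields are excluded as
`missing_qc`, never silently kept. Replicates are averaged on the RTL scale
and the mean is then square-root transformed; averaging before transforming
keeps the sample mean unbiased for the sample's expected RTL.

## Repeatability

Agreement repeatability is `R = σ²_group / (σ²_group + σ²_resid)` from a
one-way random-intercept model fitted by REML. The REML criterion for this
model depends on the data only through group sizes, group means and the
pooled within-group sum of squares, so the package fits it with a dedicated
1-D profile optimisation (the variance ratio on a log scale, residual
variance profiled out in closed form) rather than a generic mixed-model
solver; this makes the 1,000-draw parametric bootstrap for the CI cheap. The
estimate is checked against statsmodels `MixedLM` and against the balanced
one-way ANOVA closed form in the tests. Negative component estimates are
truncated at zero before the ratio; the estimate is clipped to [0, 1].

Inter-plate repeatability groups RTL by sample across the duplicate runs.
Individual repeatability adjusts for age and cohort
(`sqrt_rtl ~ log age + cohort` + bird random intercept) and reports
σ²_bird over the total random variance.

## Mixed models, model sets, AICc

Mixed models are fitted with statsmodels `MixedLM`: a single random
intercept uses the grouped formulation; crossed structures (bird × catch
year × plate, or cohort intercepts plus a random log-age slope among
cohorts) use variance components over one all-encompassing group. Model
comparison uses ML fits (AICc across fixed-effect structures is invalid
under REML); reported coefficients come from REML refits. Intervals are
Wald (±1.96 SE) throughout. `k` counts fixed coefficients, variance
components and the residual, and `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`.
Boundary fits (a variance component at zero) are flagged and ranking
refuses flagged fits unless explicitly overridden; on simulated data a
zero catch-year component is routine, so the pipeline overrides with the
flag recorded.

The cross-sectional candidate set contains ten structures — {linear,
quadratic, loglinear, factor} age codings with and without cohort, cohort
only, and the null — plus an eleventh log-age × cohort interaction follow-up
used to test cohort-varying slopes. The longitudinal set applies
within-subject centring: per bird, age (linear, log, and squared) is split
into a bird mean and deviations from it; the eight candidate models always
carry the mean-age term so the delta-age coefficients are purely
within-individual. The plate random term is dropped there because
consecutive samples of a bird sit on different plates, confounding plate
with residual. The within-vs-between slope contrast is read off the
mean-age coefficient of the raw-plus-mean parameterisation
(`sqrt_rtl ~ log age + bird-mean log age`), which equals (between slope −
within slope) exactly.

## The elongation battery

ΔRTL_individual is the change in replicate-averaged RTL between consecutive
samples of a bird; ΔRTL_sample is the change between independent runs of the
same sample on separate plates (pairs sharing a plate are skipped with a
warning). Both use consecutive pairing, not all-pairs, and the untransformed
RTL scale. The battery:

- **Variance equality** — Brown–Forsythe (median-centred Levene) F between
  the two delta distributions; mean-centring available as an option.
- **Signed split** — deltas split at zero (exact zeros dropped); rank-sum
  tests compare negatives with negatives and positives with positives. Exact
  enumeration is used when both groups have ≤ 12 tie-free values, otherwise
  the tie-corrected normal approximation. An empty side is reported as NaN.
- **Lengthening probability** — binomial GLMM of 1{Δ>0} on log age at the
  first sample for pairs ≤ 2 years apart, random intercept per bird. No
  installed Python library offers a Laplace-approximation binomial GLMM, so
  the package implements it directly: per-group posterior modes by a
  vectorised Newton iteration inside a BFGS optimisation of the Laplace
  marginal likelihood over (β, log σ_u) — the same approximation `glmer`
  uses. Complete separation is detected and flagged.
- **Consistency test** — per bird with ≥ 3 measurements at ≥ 3 distinct
  ages, an OLS line of RTL on age gives a residual SD s_i; d_i is the
  first-to-last change. Among gainers (d_i > 0) a one-sided Wilcoxon
  signed-rank compares d_i against √2·s_i, the SD that pure measurement
  error predicts for a first-to-last difference (Var = 2σ²). Comparing d_i
  to s_i itself is anticonservative under a flat truth (E|Δ| = 1.13σ exceeds
  E[s] ≈ σ), which is why the √2 scaling is built in; with it, the
  lengthening direction is conservative and an error-only regime instead
  triggers the reverse direction ("error dominates"). Both directions and
  both sd/variance scales are reported.

Under the calibrated default regime the battery detects elongation (Levene
F far above 1, both Wilcoxon sides significant); under an error-only regime
(flat truth, elongation off, plate variance folded into iid run noise so
deltas are exchangeable) its rejection rates are close to nominal.

## Environmental models

The full model regresses sqrt-RTL on log age, tarsus, mass, sex, seasonal
insect abundance, territory quality, island-wide density, group size and
helper number, with random intercepts for bird, plate and cohort plus a
random log-age slope among cohorts. Continuous covariates are centred and
scaled to unit SD — required for meaningful zero-substitution model
averaging and comparable importances. Missing territory-quality values are
imputed with the territory's across-year mean. The ΔRTL model reuses the
fixed terms with covariates taken at the first sample of each pair and a
bird-only random structure.

All-subsets model averaging (≤ 12 terms, interaction hierarchy enforced)
ranks every fixed-effect subset by ML-AICc, keeps the top set (ΔAICc ≤ 6,
inclusive), and reports zero-substitution averaged coefficients with
Burnham–Anderson unconditional SEs, natural (conditional) averages, and
per-term relative importance (sum of renormalised top-set weights of models
containing the term); whether the original analysis used zero-substitution
or conditional averaging is unstated, so both are emitted. Marginal and
conditional R² follow the fixed-vs-random variance partition for mixed
models, with each random term contributing its component times the mean row
sum of squares of its design — 1 for intercepts, mean(log age²) for the
random slope — so random-slope models use the observation-averaged
random-effect variance.

## Numerical and scale choices

- Problem sizes in the test suite and acceptance script are scaled to the
  package's own simulation experiments: full-scale studies (~1,700 samples)
  for the cheap stages, 12 × 12-cohort studies for model-selection
  replicates, and 10 × 15 for the environment models. These sizes were
  chosen for statistical adequacy of each check (coverage and win-rates
  computed over replicates), with coefficients recoverable at the stated
  tolerances.
- Mixed-model optimisation falls back from statsmodels' default optimiser
  to conjugate gradients on linear-algebra failures; remaining failures are
  recorded on the fit object, never raised mid-ranking.
- Ranking ties break by fewer parameters, then input order.
- Exact-zero deltas are excluded from the signed split and from the
  positive-fraction summary (they occur only in degenerate simulations).
- Seeds: every stochastic component (generator, bootstrap, acceptance
  script) takes an explicit seed; identical configuration + seed gives
  byte-identical outputs.

## Known limitations

- Intra-plate repeatability in the strict sense (duplicate wells within a
  plate) is not computable from the generator, which emits one reaction per
  sample-plate; the generator's noise partition is calibrated so that the
  implied intra-plate repeatability `(V_between + σ²_plate) / V_total` sits
  at ≈ 0.73.
- Wald intervals understate uncertainty for variance-component-heavy
  models; profile or bootstrap intervals are not implemented for the LMMs.
- The binomial GLMM supports a single random intercept only.
- The elongation process makes adult mean RTL change slightly positive at
  default calibration; the overall loglinear decline is carried by the
  juvenile phase, and lengthening probability rises with age — consistent
  with the qualitative pattern the battery is designed to detect.
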