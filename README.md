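# telodyn

Lifelong telomere-dynamics analysis for longitudinal qPCR field studies.

Relative telomere length (RTL) — the telomere qPCR signal normalised to a
single-copy control gene and a reference sample — is widely used as a
biomarker of the costs wild animals accumulate from their environment. Long
studies that sample the same individuals repeatedly over decades face three
intertwined statistical problems: qPCR measurement error is large and
multi-level (plate effects plus run noise), apparent within-individual
telomere *lengthening* must be distinguished from that error, and
age, cohort and environmental effects must be separated in unbalanced,
crossed longitudinal data. `telodyn` packages the full workflow for
ecologists and biostatisticians working with such data:

- **Quantification & QC** — two-efficiency relative quantification
  `RTL = E_T^(refCq_T − Cq_T) / E_G^(refCq_G − Cq_G)`, threshold-based sample
  QC with reason-coded exclusions, replicate averaging and the sqrt
  transform.
- **Repeatability** — agreement intraclass correlation
  `R = σ²_group/(σ²_group + σ²_resid)` by one-way REML with parametric
  bootstrap CIs, at plate, sample and individual level.
- **Age/cohort trajectories** — linear mixed models over a fixed candidate
  set (linear/quadratic/loglinear/factor age × cohort), ranked by AICc with
  Akaike weights; within-subject centring splits age effects into
  within-individual (Δage) and between-individual (mean age) components.
- **Elongation vs. error** — contrasts the distribution of RTL changes
  between consecutive samples of a bird (ΔRTL_individual) with changes
  between independent re-runs of the same sample on separate plates
  (ΔRTL_sample): Brown–Forsythe variance test, signed-split rank-sum
  comparisons, a Laplace binomial GLMM for lengthening probability with
  age, and a per-bird consistency test of lifetime gains against residual
  scatter.
- **Environment** — a full mixed model of RTL on morphometric, social and
  ecological covariates with a random log-age slope among cohorts,
  all-subsets AICc model averaging (ΔAICc ≤ 6 top set, relative
  importances), and Nakagawa marginal/conditional R².
- **Synthetic studies** — a generator with known truth (cohorts, birds,
  plates, replicates, covariates, sporadic elongation bouts) that emulates
  the statistical structure the analysis assumes; all tests are
  parameter-recovery and calibration experiments against it.

See `docs/methods.md` for the model definitions and design choices.

## Worked example

```python
from telodyn import (SimTruth, simulate_study, summarize_samples, icc,
                     build_cross_sectional_set, fit_lmm, rank_models)

# a synthetic study: 12 cohorts x 12 birds, loglinear decline -0.07,
# cohort intercept SD 0.06, two-level qPCR noise
truth = SimTruth(seed=1, n_cohorts=12, birds_per_cohort=12,
                 cohort_intercept_sd=0.06, cohort_slope_sd=0.0,
                 elongation_prob=0.0, covariate_effects={})
study = simulate_study(truth)
samples = summarize_samples(study.measurements)

# inter-plate repeatability from duplicate runs
multi = samples.loc[samples.n_measurements >= 2, "sample_id"]
runs = study.measurements[study.measurements.sample_id.isin(multi)]
r = icc(runs.rtl, runs.sample_id, n_boot=500, seed=1)
print(f"inter-plate repeatability {r.estimate:.2f} "
      f"(CI {r.ci_low:.2f}, {r.ci_high:.2f}; {r.n_groups} samples)")

# rank the cross-sectional age/cohort model set by AICc
fits = [fit_lmm(s, samples, criterion="ML")
        for s in build_cross_sectional_set(samples)[:10]]
for spec, aicc, delta, w in rank_models(fits, allow_flagged=True).entries[:3]:
    print(f"{spec.name:40s} dAICc {delta:7.2f}  weight {w:.3f}")

best = fit_lmm(fits[0].spec, samples, criterion="REML")
b, lo, hi = best.estimates["log_age"]
print(f"log-age slope (sqrt scale) {b:.3f} (CI {lo:.3f}, {hi:.3f})")
```

prints

```
inter-plate repeatability 0.61 (CI 0.42, 0.74; 62 samples)
Cohort + Age (log)                       dAICc    0.00  weight 0.849
Cohort + Age (factor)                    dAICc    3.46  weight 0.151
Age (log)                                dAICc   39.13  weight 0.000
log-age slope (sqrt scale) -0.065 (CI -0.072, -0.057)
```

The duplicate-run repeatability (0.61 from 62 re-assayed samples at this
small scale) quantifies the share of RTL variance that is biological rather
than assay noise; the model ranking identifies the loglinear-age-with-cohort
structure the data were generated under; and the REML refit's interval
covers the simulated decline of −0.07 sqrt-RTL per log-year.

## Command line

```
telodyn simulate --seed 1 --output-dir out          # synthetic study CSV + truth
telodyn run-all --seed 1 --output-dir out           # full pipeline, JSON + CSV reports
telodyn run-all --input study.csv --output-dir out  # ... on your own study table
```

Stage subcommands (`qc`, `summarize`, `repeatability`, `age-models`,
`elongation`, `env-models`) run individual steps; `--config config.yaml`
overrides QC thresholds, simulation truth and stage toggles. Results go to
CSV/JSON files with provenance headers; logs go to stderr.

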