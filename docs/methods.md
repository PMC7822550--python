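# Methods

## Risk model

### PRS normalization

Each panel SNP carries a published per-allele odds ratio `OR` and a
risk-allele frequency `p`. Genotype relative risks `1, OR, OR²` are divided
by the Hardy–Weinberg population mean `μ = (1−p)² + 2p(1−p)OR + p²OR²`, so
the adjusted risks average exactly 1 in a population at HWE with that
allele frequency. The subject-level PRS is the product of adjusted risks
over the panel; it is accumulated as a sum of logs and exponentiated once,
so 70+ factors near 1 cannot underflow or accumulate product-order error.
The model assumes panel SNPs act independently and additively on the
log-odds scale; no linkage-disequilibrium pruning or correlation
adjustment is performed — supplying an approximately LD-independent panel
is the caller's responsibility.

Missing genotypes default to the population-average factor 1
(`missing_policy="population_mean"`), with `n_missing` surfaced and a
warning when more than 10% of the panel is missing; `missing_policy="error"`
refuses instead, listing the rsids. Monomorphic SNPs (`p` of 0 or 1) are
allowed and contribute `OR^count/μ` exactly as the formula dictates. VCF
ingestion matches on rsID and requires the stated risk allele to equal REF
or an ALT allele; a mismatch raises rather than attempting strand
resolution, because a silently flipped allele corrupts the score in a way
no downstream check can catch.

### Absolute 5-year risk

Rate tables hold annual incidence hazards (per-person, converted from
per-100,000 on input) and annual competing-mortality survival
probabilities, indexed by completed year of age. Numerical conventions:

- **Hazard discretization.** Hazards are piecewise-constant over single
  years; cumulative incidence to age `a` is the plain sum of hazards over
  completed years `[0, a)`, and the 5-year window is the half-open
  interval `[a, a+5)`. This is the simplest convention consistent with
  "cumulative incidence from birth to baseline" and makes the flat-hazard
  case exactly closed-form (below).
- **Competing mortality.** Tables carry annual non-breast-cancer survival
  directly; `competing_survival_from_mortality` converts all-cause and
  breast-cancer mortality hazards into this column
  (`exp(−(all_cause − breast))`). The 5-year survival is the product of
  the five annual values. Incidence and competing mortality are treated as
  independent single-decrement processes multiplied together, not as a
  joint double-decrement life table; at the annual hazards involved
  (≲0.05) the difference is below the precision of any input.
- **The projection** conditions on being disease-free at baseline:
  `abs_risk_5 = (cumul_b_5 − cumul_b)·mortsurv_5/(1 − cumul_b)`, with the
  division by `(1 − cumul_b)` adopted as the standard conditional-risk
  algebra.
- **Ages** are integer years at last birthday; fractional ages are
  truncated with a warning. Interior gaps in a rate table are an error —
  interpolation would silently fabricate rates. Ages below a table's first
  row contribute zero hazard.

With a flat hazard λ and no competing mortality the formula collapses
algebraically to `1 − exp(−5·fh·snp·λ)` independent of baseline age; the
test suite asserts this to 1e-10 over a grid of λ, relative risks and
ages, which pins the discretization conventions above.

Family history enters as a single configurable relative risk (default 2.0:
an affected first-degree relative approximately doubles risk). Unknown
family history raises in strict mode, mirroring validation practice of
excluding such subjects because the factor is central to the model;
lenient mode scores it as "no" with a logged warning. Absolute-risk flags
default to 1.67% and 3.0% — the thresholds at which US guidelines discuss
risk-reducing medication and designate elevated risk — and are
configurable.

## Evaluation statistics

**OPERA.** The paper-trail definition "log odds per adjusted standard
deviation" leaves the adjustment mechanics open; this implementation (1)
logs the score, (2) fits a linear regression on the adjusters (default:
age) *among controls only* and residualizes all subjects with those
coefficients, (3) divides by the residual SD *among controls*, (4) fits a
logistic regression of status on the standardized score. Fitting both the
adjustment and the SD in controls keeps the standardization disease-free,
so OPERA reflects the score's effect per unit of its natural population
spread. Consequences asserted in tests: OPERA is invariant to affine
transformations of the log score, and for a score that *is* the true log
relative risk with control SD σ, OPERA → e^σ (rare-disease regime).
Confidence intervals and p-values are Wald on the log scale. A score whose
adjusted control residual SD is below 1e-10 of the score scale is refused
as degenerate; non-convergence (e.g. perfect separation) raises with a
diagnostic rather than returning a silent extreme.

**AUC.** Mann–Whitney estimate (ties one half) with the DeLong
structural-components variance, computed from midranks; the CI is Wald,
clipped to [0, 1]. All-tied scores return AUC 0.5 with a degenerate CI and
a warning. An exhaustive pair-counting oracle checks the estimator exactly
on small datasets.

**Improvement** from adding a component is `100·(ln OPERA_full − ln
OPERA_base)/ln OPERA_base`; the ratio is identical in any log base
(asserted), and a base OPERA ≤ 1 is refused since relative improvement
over a non-discriminating base is undefined. **Model mean comparisons**
use two-sided t-tests on log risks — paired for two models on the same
subjects, Welch for independent groups.

Stratified reports analyze each ethnicity separately and never pool
across strata; a stratum lacking cases or controls is skipped with a
warning.

## Synthetic data

The generators emulate the study design the evaluation assumes: a
case-control cohort of screening-age women scored by family history, PRS
and their combination. Defaults (chosen once, as the package's stated
study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_snps` | 75 | typical validated breast-cancer panel size (70+ SNPs) |
| `or_log_sd` | 0.1 | per-SNP ORs mostly 0.85–1.2, matching published panels of modest-effect common variants |
| `freq_range` | (0.1, 0.9) | common variants; avoids degenerate monomorphic draws |
| `fh_prevalence` | 0.15 | population prevalence of first-degree breast-cancer family history |
| `fh_rr` | 2.0 | the approximate doubling of risk used by the model itself |
| `baseline_hazard` | 0.003/yr flat | order of screening-age US incidence (~300/100k) |
| `age_range` | [40, 70) | typical screening band |
| `case_fraction` | 0.11 | matches the roughly 1:8 case:control mix of published validation cohorts |

Genotypes are Binomial(2, p) per SNP (HWE, no LD); disease is assigned
with probability proportional to `fh_rr^FH · PRS · baseline_5yr(age)`,
capped at 0.99 — a multiplicative relative-risk model on a rare baseline,
which approximates the logistic model the evaluation fits (the odds ratio
for family history recovers the generative RR only as the baseline becomes
rare; tests therefore check it at a 2% case fraction). A run in which more
than 10% of probabilities hit the cap is refused as an unattainable
design. `simulate_score_cohort` provides the cleaner theoretical object —
a single score that is exactly the true relative risk, log-normal with
known σ — for which OPERA ≈ e^σ and AUC ≈ Φ(σ/√2) hold and are used as
calibration targets; its `informative=False` mode gives the null
(score-independent disease) used for OPERA ≈ 1 / AUC ≈ 0.5 / type-I-error
checks. Questionnaire simulation applies independent per-question
missingness (defaults near observed commercial-testing rates, e.g. 4.4%
for age at menarche) with age and ethnicity never missing.

What the synthetic data does *not* emulate: linkage disequilibrium,
population stratification or admixture, age-dependent family-history
effects, correlated question missingness, or miscalibrated published ORs.
Passing tests therefore demonstrate internal correctness and statistical
calibration of the machinery under the model's own assumptions, not
real-world predictive performance of any particular panel.

The bundled rate table is synthetic (logistic-shaped incidence rising to
~440/100k by age 75; Gompertz all-cause mortality `3.5e-5·e^{0.09·age}`),
labelled as such in its filename; real registry rates should replace it
for substantive work.

## Problem sizes

Statistical checks run at sizes where their targets are sharp: 20,000
subjects for HWE mean-PRS convergence (3-SE bands), 50,000 for OPERA/AUC
calibration, 500 replicates of n=2,000 for t-test type-I error, and 100
replicates of n=10,000 for the combined-model dominance rate. The whole
suite completes in well under a minute on one CPU.

## Known limitations

- The family-history relative risk is a single scalar; no age-band decay,
  number-of-relatives dose, or bilateral/early-onset weighting.
- Full multi-factor clinical models (menarche/parity/biopsy relative
  risks) are out of scope; any externally computed relative risk can be
  supplied in place of `fh·snp` for interface-level comparisons.
- Lifetime-risk projection is deliberately not offered; the model is
  specified and validated for the 5-year horizon only.
- OPERA's bootstrap CI alternative is not implemented; Wald and DeLong
  intervals are the defaults throughout.
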