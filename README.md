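# streamrisk

Streamlined 5-year breast-cancer risk prediction for primary-care-style
screening: a Hardy–Weinberg-normalized multiplicative polygenic risk score
(PRS) combined with the two clinical risk factors women can reliably
report — age and first-degree family history — projected onto age-specific
incidence rates with competing mortality, plus the discrimination
statistics (OPERA, AUC, log-OPERA improvement, log-risk t-tests) used to
compare risk models on case-control data.

Full clinical questionnaires (age at menarche, age at first live birth,
biopsy history, atypical hyperplasia) go unanswered often enough that
multi-factor risk models are underused in practice. `streamrisk`
implements the streamlined alternative — keep only the questions with
near-zero missingness, recover the lost discrimination with a validated
PRS — together with the machinery to quantify what that trade costs, and a
seeded synthetic-cohort simulator so every stage can be exercised without
restricted cohort data.

## The model

**Per-SNP normalization.** For a SNP with per-allele odds ratio `OR` and
risk-allele frequency `p`, the Hardy–Weinberg population-average unscaled
risk is

    μ = (1 − p)² + 2p(1 − p)·OR + p²·OR²

and the three genotypes (0, 1, 2 risk alleles) get adjusted risks
`1/μ, OR/μ, OR²/μ`, whose HWE-weighted mean is exactly 1. The PRS is the
product of adjusted risks over the panel (independent, additive on the
log-odds scale), so it is a relative risk with population average 1.

**Absolute 5-year risk.** With `incid_b` the cumulative incidence from
birth to baseline age, `incid_b_5` the same to baseline + 5, `fh` the
family-history relative risk (default 2.0 for an affected first-degree
relative), `snp` the PRS, and `mortsurv_5` the probability of surviving
competing (non-breast-cancer) mortality over the next 5 years:

    cumul_b    = 1 − exp(−fh·snp·incid_b)
    cumul_b_5  = 1 − exp(−fh·snp·incid_b_5)
    abs_risk_5 = (cumul_b_5 − cumul_b) · mortsurv_5 / (1 − cumul_b)

**Evaluation.** OPERA (odds per adjusted standard deviation) is the
exponentiated logistic-regression coefficient of case status on the log
risk score after residualizing on age among controls and standardizing to
unit control SD; AUC is the Mann–Whitney estimate with a DeLong confidence
interval; improvement from adding the PRS is the percentage increase in
log OPERA.

## Worked example

```python
from streamrisk import (
    GenotypeVector, RiskProfile, SnpDescriptor, SnpPanel,
    compute_prs, load_bundled_rates, streamlined_risk,
)

panel = SnpPanel(
    snps=(
        SnpDescriptor("rs2981582", "A", 1.26, 0.38),
        SnpDescriptor("rs3803662", "T", 1.20, 0.25),
        SnpDescriptor("rs889312",  "C", 1.13, 0.28),
    ),
    ethnicity_label="caucasian",
)
genotype = GenotypeVector("subject-001", {"rs2981582": 2, "rs3803662": 1, "rs889312": 0})
prs = compute_prs(genotype, panel)
print(f"PRS = {prs.value:.4f}  (missing SNPs: {prs.n_missing})")

profile = RiskProfile("subject-001", age=52, family_history="yes",
                      ethnicity_label="caucasian")
rates = load_bundled_rates("caucasian")   # SYNTHETIC illustrative rates
risk = streamlined_risk(profile, panel, genotype, rates)
print(f"absolute 5-year risk = {risk.percent:.2f}%")
print(f"components: fh RR = {risk.components['fh']:.1f}, PRS = {risk.components['snp']:.4f}")
print(f"flags: {risk.flags}")
```

prints

```
PRS = 1.3325  (missing SNPs: 0)
absolute 5-year risk = 2.71%
components: fh RR = 2.0, PRS = 1.3325
flags: {'flag_1_67': True, 'flag_3_0': False}
```

The subject is homozygous for one modest risk allele and heterozygous for
another, giving a PRS 1.33× the population average; with a first-degree
family history (RR 2.0) her 5-year risk on the bundled illustrative rate
table is 2.71% — above the 1.67% threshold commonly used to discuss
risk-reducing medication, below the 3.0% threshold.

The bundled rate table is **synthetic** (smooth curves with the broad age
shape of US female incidence and mortality); substitute real
registry-derived rates via `RateTable.from_csv` for any substantive use.

## Command line

```
streamrisk simulate --seed 1 --out-dir demo      # synthetic fixture set
streamrisk score --panel demo/panel.csv --genotypes demo/genotypes.csv \
    --profiles demo/profiles.csv --rates demo/rates.csv \
    --ethnicity caucasian --out risks.csv
streamrisk evaluate --cohort demo/cohort.csv --out evaluation.csv
streamrisk report --questionnaires demo/questionnaires.csv
```

All outputs are deterministic given identical inputs and seed.

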