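"""Seeded generators for panels, genotypes, rate tables, cohorts and
questionnaires with the statistical structure the risk model assumes.

The generators let every pipeline stage be exercised end to end with known
generative truth: Hardy-Weinberg genotypes at the panel's allele
frequencies, log-normal-ish multiplicative PRS distributions, binary
first-degree family history with a stated relative risk, disease assigned
by a multiplicative relative-risk model on a rare baseline, and
per-question missingness patterns typical of clinical risk questionnaires.

Everything is driven by an explicit integer seed; the same configuration
and seed reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .absolute_risk import RateTable
from .evaluation import CaseControlDataset
from .exceptions import ValidationError
from .panel_prs import (
    GenotypeVector,
    SnpDescriptor,
    SnpPanel,
    compute_prs_matrix,
)

logger = logging.getLogger("streamrisk.synthetic_data")

#: Default per-question missing-or-unknown rates for simulated
#: questionnaires, matching magnitudes seen in commercial risk testing
#: (age and ethnicity are always answered).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "age_menarche": 0.044,
    "age_first_birth": 0.013,
    "family_history": 0.024,
    "biopsy_ever": 0.011,
    "biopsy_count": 0.024,
    "atypical_hyperplasia": 0.040,
}

#: Positive-response rates used when populating simulated questionnaires.
_POSITIVE_RATES = {"family_history": 0.403, "biopsy_ever": 0.341, "atypical_hyperplasia": 0.049}

_ETHNICITIES = ("caucasian", "african_american", "hispanic")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a screening-age case-control study built around a
    75-SNP panel of modest-effect variants (per-SNP log odds ratios
    N(0, 0.1^2), risk-allele frequencies uniform on (0.1, 0.9)), 15%
    prevalence of first-degree family history with relative risk 2, a flat
    annual baseline incidence hazard of 0.003, baseline ages uniform on
    [40, 70), and an 11% case fraction.
    """

    seed: int
    n_snps: int = 75
    n_subjects: int = 10_000
    or_log_sd: float = 0.1
    freq_range: tuple[float, float] = (0.1, 0.9)
    fh_prevalence: float = 0.15
    fh_rr: float = 2.0
    baseline_hazard: float | tuple[float, float, float, float] = 0.003
    case_fraction: float = 0.11
    n_cases: int | None = None
    n_controls: int | None = None
    age_range: tuple[int, int] = (40, 70)
    ethnicity_label: str = "caucasian"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory: all randomness must be reproducible")
        if self.n_snps < 1 or self.n_subjects < 1:
            raise ValidationError("n_snps and n_subjects must be positive")
        if self.or_log_sd < 0:
            raise ValidationError("or_log_sd must be >= 0")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError(f"freq_range must satisfy 0 < lo <= hi < 1, got {self.freq_range}")
        if not (0.0 <= self.fh_prevalence <= 1.0):
            raise ValidationError("fh_prevalence must lie in [0, 1]")
        if self.fh_rr <= 0:
            raise ValidationError("fh_rr must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValidationError("case_fraction must lie in (0, 1)")
        a0, a1 = self.age_range
        if not (0 <= a0 < a1):
            raise ValidationError(f"invalid age_range {self.age_range}")


# ---------------------------------------------------------------------------
# Panels and genotypes
# ---------------------------------------------------------------------------

def simulate_panel(config: SimulationConfig) -> SnpPanel:
    """Draw a synthetic SNP panel: log odds ratios N(0, or_log_sd^2),
    risk-allele frequencies uniform on ``freq_range``, unique synthetic
    rsids."""
    rng = np.random.default_rng(config.seed)
    log_ors = rng.normal(0.0, config.or_log_sd, size=config.n_snps)
    freqs = rng.uniform(*config.freq_range, size=config.n_snps)
    bases = np.array(list("ACGT"))
    snps = []
    for i in range(config.n_snps):
        risk, other = rng.choice(4, size=2, replace=False)
        snps.append(
            SnpDescriptor(
                rsid=f"rs9{i + 1:06d}",
                risk_allele=str(bases[risk]),
                other_allele=str(bases[other]),
                or_per_allele=float(np.exp(log_ors[i])),
                risk_allele_freq=float(freqs[i]),
            )
        )
    return SnpPanel(
        snps=tuple(snps),
        ethnicity_label=config.ethnicity_label,
        version=f"synthetic-seed{config.seed}",
    )


def simulate_genotype_matrix(
    panel: SnpPanel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_snps) risk-allele counts drawn Binomial(2, p) per SNP (HWE)."""
    freqs = np.array([s.risk_allele_freq for s in panel])
    return rng.binomial(2, freqs, size=(n, len(panel))).astype(np.int8)


def simulate_genotypes(
    panel: SnpPanel, n: int, seed: int
) -> list[GenotypeVector]:
    """HWE genotypes as :class:`GenotypeVector` objects (counts independent
    Binomial(2, p) at the panel's frequencies)."""
    counts = simulate_genotype_matrix(panel, n, np.random.default_rng(seed))
    rsids = panel.rsids
    return [
        GenotypeVector(
            subject_id=f"sim{i + 1:06d}",
            counts=dict(zip(rsids, row.tolist())),
        )
        for i, row in enumerate(counts)
    ]


# ---------------------------------------------------------------------------
# Rate tables
# ---------------------------------------------------------------------------

def make_rate_table(
    hazard: float | tuple[float, float, float, float] = 0.003,
    min_age: int = 0,
    max_age: int = 89,
    gompertz_mortality: bool = True,
    ethnicity_label: str = "synthetic",
) -> RateTable:
    """Deterministic synthetic rate table.

    ``hazard`` is either a flat annual incidence hazard or an age ramp
    ``(start_age, start_hazard, end_age, end_hazard)`` interpolated
    linearly (zero before start_age, flat after end_age).  Competing
    survival follows a Gompertz all-cause mortality curve
    ``3.5e-5 * exp(0.09 * age)`` — roughly the shape of adult female
    mortality — unless ``gompertz_mortality`` is False (survival 1).
    """
    ages = np.arange(min_age, max_age + 1)
    if isinstance(hazard, tuple):
        a0, h0, a1, h1 = hazard
        if not (a0 < a1 and h0 >= 0 and h1 >= 0):
            raise ValidationError(f"invalid hazard ramp {hazard!r}")
        haz = np.interp(ages, [a0, a1], [h0, h1], left=0.0, right=h1)
    else:
        if hazard < 0:
            raise ValidationError("flat hazard must be >= 0")
        haz = np.full_like(ages, hazard, dtype=float)
    if gompertz_mortality:
        mort = 3.5e-5 * np.exp(0.09 * ages)
        surv = np.exp(-mort)
    else:
        surv = np.ones_like(ages, dtype=float)
    return RateTable(
        ages=ages,
        incidence_hazard=haz,
        competing_survival=surv,
        ethnicity_label=ethnicity_label,
    )


# ---------------------------------------------------------------------------
# Case-control cohorts
# ---------------------------------------------------------------------------

def _abs_risk_vector(
    ages: np.ndarray, rr: np.ndarray, table: RateTable
) -> np.ndarray:
    """Vectorized absolute 5-year risk for per-subject relative risks."""
    cum = table._cum_hazard
    i = ages - table.min_age
    incid_b = cum[np.maximum(i, 0)]
    incid_b5 = cum[np.maximum(i + 5, 0)]
    cumul_b = -np.expm1(-rr * incid_b)
    cumul_b5 = -np.expm1(-rr * incid_b5)
    log_surv = np.log(table.competing_survival)
    cum_log_surv = np.concatenate([[0.0], np.cumsum(log_surv)])
    mortsurv = np.exp(cum_log_surv[i + 5] - cum_log_surv[i])
    return (cumul_b5 - cumul_b) * mortsurv / (1.0 - cumul_b)


def _simulate_batch(
    panel: SnpPanel,
    config: SimulationConfig,
    table: RateTable,
    rng: np.random.Generator,
    n: int,
    start_index: int,
) -> tuple[pd.DataFrame, float]:
    ages = rng.integers(config.age_range[0], config.age_range[1], size=n)
    fh = rng.random(n) < config.fh_prevalence
    counts = simulate_genotype_matrix(panel, n, rng)
    prs, _ = compute_prs_matrix(counts, panel)
    fh_rr = np.where(fh, config.fh_rr, 1.0)

    baseline5 = _abs_risk_vector(ages, np.ones(n), table)
    raw = fh_rr * prs * baseline5
    scale = config.case_fraction / raw.mean()
    p_case = np.minimum(scale * raw, 0.99)
    if (scale * raw > 0.99).mean() > 0.10:
        raise ValidationError(
            "requested case fraction unattainable at a feasible baseline "
            "(over 10% of disease probabilities hit the cap); lower "
            "case_fraction, fh_rr or or_log_sd"
        )
    status = (rng.random(n) < p_case).astype(int)

    frame = pd.DataFrame(
        {
            "subject_id": [f"cc{start_index + j + 1:07d}" for j in range(n)],
            "status": status,
            "age": ages,
            "ethnicity": config.ethnicity_label,
            "fh": fh.astype(int),
            "prs": prs,
            "fh_only": _abs_risk_vector(ages, fh_rr, table),
            "prs_only": _abs_risk_vector(ages, prs, table),
            "combined": _abs_risk_vector(ages, fh_rr * prs, table),
        }
    )
    return frame, float(scale)


def simulate_case_control(
    panel: SnpPanel,
    config: SimulationConfig,
    rate_table: RateTable | None = None,
) -> CaseControlDataset:
    """Simulate a case-control cohort with known generative truth.

    Subjects receive HWE genotypes, Bernoulli family history and uniform
    baseline ages; disease is assigned with probability proportional to
    ``fh_rr^FH * PRS * baseline_5yr(age)`` (capped at 0.99), scaled so the
    expected case fraction matches the configuration.  Model score columns
    are the absolute 5-year risks from family history alone (``fh_only``),
    PRS alone (``prs_only``) and both (``combined``).

    When ``n_cases``/``n_controls`` quotas are set, batches of
    ``n_subjects`` are drawn until both quotas fill (error after 50
    batches).  The returned dataset's ``truth`` records the generative
    parameters for recovery tests.
    """
    table = rate_table if rate_table is not None else make_rate_table(
        config.baseline_hazard, ethnicity_label=config.ethnicity_label
    )
    if config.age_range[1] + 5 > table.max_age + 1:
        raise ValidationError(
            f"age_range {config.age_range} cannot be projected 5 years in {table!r}"
        )
    rng = np.random.default_rng(config.seed)
    quotas = config.n_cases is not None or config.n_controls is not None
    if quotas and (config.n_cases is None or config.n_controls is None):
        raise ValidationError("set both n_cases and n_controls, or neither")

    frames: list[pd.DataFrame] = []
    scale = float("nan")
    if not quotas:
        frame, scale = _simulate_batch(panel, config, table, rng, config.n_subjects, 0)
        frames.append(frame)
    else:
        got_cases = got_controls = drawn = 0
        for batch in range(50):
            frame, scale = _simulate_batch(
                panel, config, table, rng, config.n_subjects, drawn
            )
            frames.append(frame)
            drawn += len(frame)
            got_cases += int(frame["status"].sum())
            got_controls += int((1 - frame["status"]).sum())
            if got_cases >= config.n_cases and got_controls >= config.n_controls:
                break
        else:
            raise ValidationError(
                f"could not reach {config.n_cases} cases / {config.n_controls} "
                f"controls in 50 batches of {config.n_subjects}; the requested "
                "design is unattainable at a feasible baseline — raise "
                "case_fraction or n_subjects"
            )
        pooled = pd.concat(frames, ignore_index=True)
        cases = pooled[pooled.status == 1].head(config.n_cases)
        controls = pooled[pooled.status == 0].head(config.n_controls)
        frames = [pd.concat([cases, controls], ignore_index=True)]

    data = CaseControlDataset(
        pd.concat(frames, ignore_index=True),
        model_names=("fh_only", "prs_only", "combined"),
    )
    data.truth = {
        "fh_rr": config.fh_rr,
        "fh_prevalence": config.fh_prevalence,
        "or_log_sd": config.or_log_sd,
        "case_scale": scale,
        "config": config,
    }
    return data


def simulate_score_cohort(
    n: int,
    log_sd: float,
    prevalence: float,
    seed: int,
    model_name: str = "score",
    informative: bool = True,
) -> CaseControlDataset:
    """Cohort whose single risk score is the true relative risk.

    The log score is N(0, log_sd^2); disease probability is
    ``b * score`` with ``b`` chosen so the expected prevalence matches.
    Under this rare-disease model the theoretical OPERA per control SD is
    ``exp(log_sd)`` and the binormal AUC is ``Phi(log_sd / sqrt(2))``,
    giving closed-form targets for calibration tests.  With
    ``informative=False`` disease is independent of the score (constant
    probability), the null case where OPERA is 1 and AUC is 0.5.
    """
    if log_sd < 0 or not (0 < prevalence < 1):
        raise ValidationError("need log_sd >= 0 and prevalence in (0, 1)")
    rng = np.random.default_rng(seed)
    log_score = rng.normal(0.0, log_sd, size=n)
    score = np.exp(log_score)
    if informative:
        b = prevalence / np.exp(log_sd**2 / 2)
        p = np.minimum(b * score, 0.99)
    else:
        p = np.full(n, prevalence)
    status = (rng.random(n) < p).astype(int)
    ages = rng.integers(40, 70, size=n)
    frame = pd.DataFrame(
        {
            "subject_id": [f"sc{i + 1:07d}" for i in range(n)],
            "status": status,
            "age": ages,
            model_name: score,
        }
    )
    data = CaseControlDataset(frame, model_names=(model_name,))
    data.truth = {"log_sd": log_sd, "prevalence": prevalence, "informative": informative}
    return data


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

def simulate_questionnaires(
    n: int,
    missingness: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical risk questionnaires with per-question independent
    missingness.

    Columns: age, age_menarche, age_first_birth, family_history,
    biopsy_ever, biopsy_count, atypical_hyperplasia, ethnicity.  Missing
    answers are written as empty strings or the literal ``unknown`` (half
    each, at the stated rate); age and ethnicity are never missing.
    """
    rates = dict(DEFAULT_MISSINGNESS if missingness is None else missingness)
    for q, r in rates.items():
        if not (0.0 <= r <= 1.0):
            raise ValidationError(f"missingness rate for '{q}' must lie in [0, 1], got {r!r}")
    for protected in ("age", "ethnicity"):
        if rates.pop(protected, 0.0):
            logger.warning("%s is never missing; its missingness rate is ignored", protected)

    rng = np.random.default_rng(seed)
    yesno = lambda p: np.where(rng.random(n) < p, "yes", "no")
    biopsy = yesno(_POSITIVE_RATES["biopsy_ever"])
    df = pd.DataFrame(
        {
            "age": rng.integers(30, 76, size=n),
            "age_menarche": rng.integers(10, 17, size=n).astype(object),
            "age_first_birth": rng.integers(16, 41, size=n).astype(object),
            "family_history": yesno(_POSITIVE_RATES["family_history"]),
            "biopsy_ever": biopsy,
            "biopsy_count": np.where(
                biopsy == "yes", rng.integers(1, 4, size=n), 0
            ).astype(object),
            "atypical_hyperplasia": yesno(_POSITIVE_RATES["atypical_hyperplasia"]),
            "ethnicity": rng.choice(_ETHNICITIES, size=n),
        }
    )
    for question, rate in rates.items():
        if question not in df.columns:
            raise ValidationError(f"unknown questionnaire column '{question}'")
        miss = rng.random(n) < rate
        as_unknown = rng.random(n) < 0.5
        col = df[question].astype(object)
        col[miss & as_unknown] = "unknown"
        col[miss & ~as_unknown] = ""
        df[question] = col
    return df
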