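"""Absolute 5-year risk projection with competing mortality.

A subject's combined relative risk ``rr = fh * snp`` (family-history
relative risk times the polygenic risk score) scales age-specific
breast-cancer incidence.  With ``incid_b`` the cumulative incidence from
birth to baseline age, ``incid_b_5`` the same to baseline + 5, the
cumulative risks are

    cumul_b   = 1 - exp(-fh * snp * incid_b)
    cumul_b_5 = 1 - exp(-fh * snp * incid_b_5)

and the absolute 5-year risk, conditioned on being disease-free at
baseline and discounted for the competing risk of death from other
causes over the next 5 years, is

    abs_risk_5 = (cumul_b_5 - cumul_b) * mortsurv_5 / (1 - cumul_b)

Rate tables carry annual incidence hazards (piecewise-constant over
single years of age) and annual competing-mortality survival
probabilities; cumulative incidence is the sum of hazards over completed
years and 5-year competing survival the product of five annual survival
probabilities, both over half-open age intervals ``[a, a+5)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import RangeError, ValidationError
from .panel_prs import GenotypeVector, PrsScore, SnpPanel, compute_prs

logger = logging.getLogger("streamrisk.absolute_risk")

#: Absolute 5-year risk thresholds commonly used to flag elevated risk:
#: 1.67% (chemoprevention discussion threshold) and 3.0% (USPSTF).
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.0167, 0.030)

RATE_COLUMNS = ["age", "bc_incidence_per_100k", "competing_survival"]


# ---------------------------------------------------------------------------
# Rate tables
# ---------------------------------------------------------------------------

class RateTable:
    """Age-indexed annual breast-cancer incidence and competing-mortality
    survival for one population.

    Parameters
    ----------
    ages : contiguous integer ages (completed years).
    incidence_hazard : per-person annual incidence hazard at each age.
    competing_survival : annual probability of surviving death from causes
        other than breast cancer, in (0, 1].
    """

    def __init__(
        self,
        ages: Sequence[int],
        incidence_hazard: Sequence[float],
        competing_survival: Sequence[float],
        ethnicity_label: str = "",
    ) -> None:
        ages_arr = np.asarray(ages, dtype=int)
        haz = np.asarray(incidence_hazard, dtype=float)
        surv = np.asarray(competing_survival, dtype=float)
        if ages_arr.size == 0:
            raise ValidationError("rate table must contain at least one age")
        if not (len(ages_arr) == len(haz) == len(surv)):
            raise ValidationError("rate table columns must have equal length")
        if np.any(np.diff(ages_arr) != 1):
            gaps = ages_arr[:-1][np.diff(ages_arr) != 1]
            raise ValidationError(
                f"rate table '{ethnicity_label}' has non-contiguous ages after "
                f"{gaps.tolist()}; interior gaps are not interpolated"
            )
        if np.any(~np.isfinite(haz)) or np.any(haz < 0):
            raise ValidationError("incidence hazards must be finite and >= 0")
        if np.any(~np.isfinite(surv)) or np.any(surv <= 0) or np.any(surv > 1):
            raise ValidationError("competing survival probabilities must lie in (0, 1]")
        self.ages = ages_arr
        self.incidence_hazard = haz
        self.competing_survival = surv
        self.ethnicity_label = ethnicity_label
        # cumulative hazard from the table's first age up to each age boundary
        self._cum_hazard = np.concatenate([[0.0], np.cumsum(haz)])

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def __repr__(self) -> str:
        return (
            f"RateTable({self.ethnicity_label or 'unlabelled'}, "
            f"ages {self.min_age}-{self.max_age})"
        )

    def hazard_at(self, age: int) -> float:
        self._check_age(age)
        return float(self.incidence_hazard[age - self.min_age])

    def survival_at(self, age: int) -> float:
        self._check_age(age)
        return float(self.competing_survival[age - self.min_age])

    def _check_age(self, age: int) -> None:
        if not (self.min_age <= age <= self.max_age):
            raise RangeError(
                f"age {age} outside rate table '{self.ethnicity_label}' "
                f"range [{self.min_age}, {self.max_age}]"
            )

    @classmethod
    def constant(
        cls,
        hazard: float,
        survival: float = 1.0,
        min_age: int = 0,
        max_age: int = 89,
        ethnicity_label: str = "constant",
    ) -> "RateTable":
        """Flat-hazard table, mainly for testing and closed-form checks."""
        n = max_age - min_age + 1
        return cls(
            ages=np.arange(min_age, max_age + 1),
            incidence_hazard=np.full(n, hazard),
            competing_survival=np.full(n, survival),
            ethnicity_label=ethnicity_label,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ethnicity_label: str = "") -> "RateTable":
        missing = set(RATE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(
                f"rate table lacks required columns: {', '.join(sorted(missing))}"
            )
        df = df.sort_values("age")
        return cls(
            ages=df["age"].to_numpy(),
            incidence_hazard=df["bc_incidence_per_100k"].to_numpy() / 1e5,
            competing_survival=df["competing_survival"].to_numpy(),
            ethnicity_label=ethnicity_label,
        )

    @classmethod
    def from_csv(cls, path: str | Path, ethnicity_label: str = "") -> "RateTable":
        """Read ``age,bc_incidence_per_100k,competing_survival``; incidence
        is converted to a per-person hazard (divided by 100,000)."""
        return cls.from_frame(pd.read_csv(path), ethnicity_label=ethnicity_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "bc_incidence_per_100k": self.incidence_hazard * 1e5,
                "competing_survival": self.competing_survival,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_bundled_rates(ethnicity_label: str = "synthetic") -> RateTable:
    """Illustrative SYNTHETIC rate table bundled with the package.

    The values follow the broad age shape of US female breast-cancer
    incidence and all-cause mortality but are generated, not registry
    extractions; use real rates for any substantive analysis.
    """
    from importlib.resources import files

    path = files("streamrisk.data").joinpath("rates_synthetic_us_female.csv")
    with path.open("rb") as fh:
        return RateTable.from_frame(pd.read_csv(fh), ethnicity_label=ethnicity_label)


def competing_survival_from_mortality(
    all_cause_hazard: float, bc_mortality_hazard: float = 0.0
) -> float:
    """Annual competing-mortality survival ``exp(-(all_cause - breast))``
    from annual mortality hazards, removing breast-cancer deaths so the
    projection does not double-count the disease."""
    if not (all_cause_hazard >= bc_mortality_hazard >= 0):
        raise ValidationError(
            "need all_cause_hazard >= bc_mortality_hazard >= 0, got "
            f"{all_cause_hazard!r}, {bc_mortality_hazard!r}"
        )
    return math.exp(-(all_cause_hazard - bc_mortality_hazard))


# ---------------------------------------------------------------------------
# Subject profile and result types
# ---------------------------------------------------------------------------

@dataclass
class RiskProfile:
    """A subject's questionnaire inputs for the streamlined model."""

    subject_id: str
    age: int
    family_history: str = "no"  # 'yes' | 'no' | 'unknown'
    ethnicity_label: str = ""
    prs: PrsScore | None = None

    def __post_init__(self) -> None:
        if isinstance(self.age, float):
            if not self.age.is_integer():
                logger.warning(
                    "subject %s: fractional age %.2f truncated to %d (ages are "
                    "integer years at last birthday)",
                    self.subject_id, self.age, int(self.age),
                )
            self.age = int(self.age)
        if self.age < 0:
            raise ValidationError(f"subject {self.subject_id}: negative age {self.age}")
        fh = str(self.family_history).strip().lower()
        if fh not in ("yes", "no", "unknown"):
            raise ValidationError(
                f"subject {self.subject_id}: family_history must be "
                f"'yes', 'no' or 'unknown', got {self.family_history!r}"
            )
        self.family_history = fh


@dataclass(frozen=True)
class FiveYearRisk:
    """Absolute 5-year risk with its intermediate components and flags."""

    subject_id: str
    abs_risk_5: float
    components: Mapping[str, float] = field(default_factory=dict)
    flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.abs_risk_5 <= 1.0):
            raise ValidationError(
                f"subject {self.subject_id}: abs_risk_5 {self.abs_risk_5!r} "
                "outside [0, 1]"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.abs_risk_5


def _flag_name(threshold: float) -> str:
    s = f"{100 * threshold:g}".replace(".", "_")
    if "_" not in s:
        s += "_0"
    return f"flag_{s}"


# ---------------------------------------------------------------------------
# Projection operations
# ---------------------------------------------------------------------------

def cumulative_incidence(table: RateTable, to_age: int) -> float:
    """Cumulative breast-cancer incidence (integrated hazard) from birth to
    ``to_age`` under piecewise-constant annual hazards: the sum of annual
    hazards over completed years ``[0, to_age)``.  Ages below the table's
    first age contribute zero hazard."""
    to_age = int(to_age)
    if not (0 <= to_age <= table.max_age + 1):
        raise RangeError(
            f"to_age {to_age} outside [0, {table.max_age + 1}] for {table!r}"
        )
    k = max(0, to_age - table.min_age)
    return float(table._cum_hazard[k])


def cumulative_risk(incid: float, fh: float, snp: float) -> float:
    """Cumulative risk 1 - exp(-fh * snp * incid) for cumulative incidence
    ``incid`` scaled by the family-history and SNP relative risks."""
    if not (math.isfinite(incid) and incid >= 0):
        raise ValidationError(f"cumulative incidence must be finite and >= 0, got {incid!r}")
    for name, rr in (("fh", fh), ("snp", snp)):
        if not (math.isfinite(rr) and rr > 0):
            raise ValidationError(f"{name} relative risk must be positive, got {rr!r}")
    return -math.expm1(-fh * snp * incid)


def competing_survival_5(table: RateTable, age: int) -> float:
    """Probability of surviving competing (non-breast-cancer) mortality from
    baseline ``age`` to ``age + 5``: the product of the five annual survival
    probabilities over ``[age, age+5)``."""
    age = int(age)
    if age < table.min_age or age + 5 > table.max_age + 1:
        raise RangeError(
            f"ages [{age}, {age + 5}) not fully covered by {table!r}"
        )
    i = age - table.min_age
    return float(np.prod(table.competing_survival[i : i + 5]))


def family_history_rr(
    status: str, rr_yes: float = 2.0, strict: bool = True
) -> float:
    """Relative risk for first-degree family history of breast cancer.

    'yes' maps to ``rr_yes`` (default 2.0 — an affected first-degree
    relative roughly doubles risk), 'no' to 1.0.  'unknown' raises in
    strict mode (validation cohorts exclude unknown family history because
    the factor is central to the model); lenient mode treats it as 'no'
    with a logged warning.
    """
    if not (math.isfinite(rr_yes) and rr_yes > 0):
        raise ValidationError(f"family-history RR must be positive, got {rr_yes!r}")
    s = str(status).strip().lower()
    if s == "yes":
        return rr_yes
    if s == "no":
        return 1.0
    if s == "unknown":
        if strict:
            raise ValidationError(
                "unknown first-degree family history cannot be scored in strict "
                "mode (subjects with unknown family history are excluded); "
                "use lenient mode to treat it as 'no'"
            )
        logger.warning("unknown family history treated as 'no' (lenient mode)")
        return 1.0
    raise ValidationError(f"family-history status must be yes/no/unknown, got {status!r}")


def five_year_risk(
    profile: RiskProfile,
    table: RateTable,
    fh_rr: float = 1.0,
    snp: float = 1.0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> FiveYearRisk:
    """Project combined relative risk ``fh_rr * snp`` onto the rate table.

    Computes cumul_b and cumul_b_5 from the cumulative incidences at
    baseline and baseline + 5, then

        abs_risk_5 = (cumul_b_5 - cumul_b) * mortsurv_5 / (1 - cumul_b)

    and flags the result against each absolute-risk threshold.
    """
    age = int(profile.age)
    if age + 5 > table.max_age + 1:
        raise RangeError(
            f"subject {profile.subject_id}: age {age} cannot be projected 5 "
            f"years within {table!r}"
        )
    incid_b = cumulative_incidence(table, age)
    incid_b_5 = cumulative_incidence(table, age + 5)
    cumul_b = cumulative_risk(incid_b, fh_rr, snp)
    cumul_b_5 = cumulative_risk(incid_b_5, fh_rr, snp)
    mortsurv_5 = competing_survival_5(table, age)
    abs_risk_5 = (cumul_b_5 - cumul_b) * mortsurv_5 / (1.0 - cumul_b)
    components = {
        "incid_b": incid_b,
        "incid_b_5": incid_b_5,
        "cumul_b": cumul_b,
        "cumul_b_5": cumul_b_5,
        "mortsurv_5": mortsurv_5,
        "fh": fh_rr,
        "snp": snp,
    }
    flags = {_flag_name(t): abs_risk_5 >= t for t in thresholds}
    return FiveYearRisk(
        subject_id=profile.subject_id,
        abs_risk_5=abs_risk_5,
        components=components,
        flags=flags,
    )


def streamlined_risk(
    profile: RiskProfile,
    panel: SnpPanel | None,
    genotype: GenotypeVector | None,
    table: RateTable,
    fh_rr_yes: float = 2.0,
    strict: bool = True,
    missing_policy: str = "population_mean",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    allow_ethnicity_mismatch: bool = False,
) -> FiveYearRisk:
    """Streamlined model (age + first-degree family history) plus PRS.

    Composes :func:`family_history_rr`, :func:`compute_prs` and
    :func:`five_year_risk`.  The PRS comes from ``genotype`` scored on
    ``panel``; if both are None, a precomputed ``profile.prs`` is used, and
    failing that the population-average score 1 (clinical-only risk).
    Ethnicity labels of profile, panel and table must agree where non-empty
    unless ``allow_ethnicity_mismatch`` is set.
    """
    labels = {
        lab
        for lab in (
            profile.ethnicity_label,
            panel.ethnicity_label if panel is not None else "",
            table.ethnicity_label,
        )
        if lab
    }
    if len(labels) > 1 and not allow_ethnicity_mismatch:
        raise ValidationError(
            f"ethnicity labels disagree across profile/panel/rate table: "
            f"{sorted(labels)}; pass allow_ethnicity_mismatch=True to override"
        )
    if panel is not None and genotype is not None:
        prs = compute_prs(genotype, panel, missing_policy=missing_policy)
    elif profile.prs is not None:
        prs = profile.prs
    else:
        prs = PrsScore(subject_id=profile.subject_id, value=1.0)
    fh = family_history_rr(profile.family_history, rr_yes=fh_rr_yes, strict=strict)
    return five_year_risk(
        profile, table, fh_rr=fh, snp=prs.value, thresholds=thresholds
    )


def write_risk_csv(results: Sequence[FiveYearRisk], path: str | Path) -> None:
    """Write per-subject risks: ``subject_id,abs_risk_5,abs_risk_5_pct,prs,
    fh_rr,<flag columns>`` with the percentage rendered to 2 decimals."""
    records = []
    for r in results:
        rec: dict[str, object] = {
            "subject_id": r.subject_id,
            "abs_risk_5": repr(r.abs_risk_5),
            "abs_risk_5_pct": f"{r.percent:.2f}",
            "prs": r.components.get("snp", ""),
            "fh_rr": r.components.get("fh", ""),
        }
        for name, value in r.flags.items():
            rec[name] = int(value)
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)
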