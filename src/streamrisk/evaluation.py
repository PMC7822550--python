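"""Risk-discrimination statistics for case-control cohorts.

Two complementary measures quantify how well a risk score separates cases
from controls:

* **OPERA** (odds per adjusted standard deviation): the log risk score is
  adjusted for covariates (by default age) by residualizing on a linear
  model fitted among controls, standardized to unit standard deviation
  among controls, and entered into a logistic regression of case status.
  OPERA is the exponentiated coefficient — the odds ratio per adjusted
  standard deviation of the score.  Fitting the adjustment and the SD among
  controls makes the standardization disease-free, so OPERA is comparable
  across scores and studies.

* **AUC**: the probability that a randomly chosen case outscores a randomly
  chosen control (ties count one half), estimated by the Mann-Whitney
  statistic with a DeLong variance for the confidence interval.

Improvement from adding a component (e.g. a PRS) to a base model is
summarized as the percentage increase in log OPERA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import EvaluationError, ValidationError

logger = logging.getLogger("streamrisk.evaluation")

#: Columns of a cohort CSV that are never treated as risk-score models.
RESERVED_COLUMNS = frozenset(
    {"subject_id", "status", "age", "ethnicity", "fh", "prs"}
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class CaseControlDataset:
    """Subjects with case status, age, ethnicity and one or more positive
    risk scores, backed by a DataFrame.

    Required columns: ``subject_id``, ``status`` (0/1), ``age``.  Optional:
    ``ethnicity`` plus covariate columns; every remaining column is treated
    as a risk-score model unless ``model_names`` is given explicitly.
    """

    def __init__(
        self, frame: pd.DataFrame, model_names: Sequence[str] | None = None
    ) -> None:
        missing = {"subject_id", "status", "age"} - set(frame.columns)
        if missing:
            raise ValidationError(
                f"cohort lacks required columns: {', '.join(sorted(missing))}"
            )
        frame = frame.reset_index(drop=True)
        status = frame["status"].to_numpy()
        if not np.isin(status, (0, 1)).all():
            raise ValidationError("status column must contain only 0 (control) and 1 (case)")
        if model_names is None:
            model_names = [c for c in frame.columns if c not in RESERVED_COLUMNS]
        else:
            model_names = list(model_names)
            absent = set(model_names) - set(frame.columns)
            if absent:
                raise ValidationError(
                    f"model columns not in cohort: {', '.join(sorted(absent))}"
                )
        for name in model_names:
            scores = frame[name].to_numpy(dtype=float)
            if not np.all(np.isfinite(scores) & (scores > 0)):
                raise ValidationError(
                    f"risk scores for model '{name}' must be positive and finite "
                    "(log-transformable)"
                )
        self.frame = frame
        self.models = tuple(model_names)
        self.truth: dict | None = None  # generative parameters, set by simulators

    # -- basic accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy(dtype=int)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def ethnicities(self) -> tuple[str, ...]:
        if "ethnicity" not in self.frame.columns:
            return ()
        return tuple(pd.unique(self.frame["ethnicity"].astype(str)))

    def scores(self, model_name: str) -> np.ndarray:
        if model_name not in self.frame.columns:
            raise ValidationError(f"unknown model column '{model_name}'")
        return self.frame[model_name].to_numpy(dtype=float)

    def subset(self, ethnicity: str) -> "CaseControlDataset":
        sub = self.frame[self.frame["ethnicity"].astype(str) == ethnicity]
        out = CaseControlDataset(sub.reset_index(drop=True), model_names=self.models)
        out.truth = self.truth
        return out

    def require_discriminable(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise EvaluationError(
                "discrimination analysis needs at least one case and one control "
                f"(got {self.n_cases} cases, {self.n_controls} controls)"
            )

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, model_names: Sequence[str] | None = None
    ) -> "CaseControlDataset":
        """Read ``subject_id,status,age,ethnicity,<model1>,<model2>,...``."""
        return cls(pd.read_csv(path, dtype={"subject_id": str}), model_names=model_names)


@dataclass(frozen=True)
class OperaEstimate:
    """Odds per adjusted standard deviation with Wald 95% CI."""

    model_name: str
    opera: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    log_opera: float = 0.0
    se_log: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.opera <= hi):
            raise ValidationError(
                f"OPERA {self.opera} outside its CI ({lo}, {hi})"
            )


@dataclass(frozen=True)
class AucEstimate:
    """Mann-Whitney AUC with DeLong 95% CI."""

    model_name: str
    auc: float
    ci95: tuple[float, float]
    n_cases: int
    n_controls: int
    se: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.auc <= hi):
            raise ValidationError(f"AUC {self.auc} outside its CI ({lo}, {hi})")


class LogRiskComparison(NamedTuple):
    t: float
    p: float
    mean_log_diff: float
    n: int


# ---------------------------------------------------------------------------
# OPERA
# ---------------------------------------------------------------------------

def adjusted_standardized_log_score(
    data: CaseControlDataset,
    model_name: str,
    adjusters: Sequence[str] = ("age",),
) -> np.ndarray:
    """Log-transform the score, residualize on the adjusters using a linear
    model fitted among controls, and scale to unit SD among controls.

    Fitting among controls only keeps the standardization free of any
    case-control sampling distortion; the fitted adjustment is then applied
    to all subjects.
    """
    for col in adjusters:
        if col not in data.frame.columns:
            raise ValidationError(f"adjuster column '{col}' not in cohort")
    log_score = np.log(data.scores(model_name))
    status = data.status
    controls = status == 0
    X = sm.add_constant(data.frame[list(adjusters)].to_numpy(dtype=float), has_constant="add")
    beta = sm.OLS(log_score[controls], X[controls]).fit().params
    resid = log_score - X @ beta
    sd = float(np.std(resid[controls], ddof=1))
    # sd of pure rounding noise from a constant score is ~1e-16, not 0
    if not (np.isfinite(sd) and sd > 1e-10 * max(1.0, float(np.abs(log_score).max()))):
        raise EvaluationError(
            f"model '{model_name}': zero residual variance among controls; "
            "the score is degenerate after adjustment"
        )
    return resid / sd


def opera(
    data: CaseControlDataset,
    model_name: str,
    adjusters: Sequence[str] = ("age",),
) -> OperaEstimate:
    """Odds per adjusted standard deviation of the log risk score.

    Logistic regression of case status on the adjusted, control-standardized
    log score; OPERA = exp(coefficient), with Wald CI and p-value.
    """
    data.require_discriminable()
    z = adjusted_standardized_log_score(data, model_name, adjusters)
    X = sm.add_constant(z, has_constant="add")
    try:
        fit = sm.Logit(data.status, X).fit(disp=0)
    except PerfectSeparationError as exc:
        raise EvaluationError(
            f"model '{model_name}': logistic regression did not converge "
            f"(perfect separation): {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise EvaluationError(
            f"model '{model_name}': logistic regression did not converge; "
            "scores may be degenerate or separating"
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    ci_lo, ci_hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return OperaEstimate(
        model_name=model_name,
        opera=math.exp(beta),
        ci95=(math.exp(ci_lo), math.exp(ci_hi)),
        p_value=float(fit.pvalues[1]),
        n=data.n,
        log_opera=beta,
        se_log=se,
    )


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney estimate, DeLong variance)
# ---------------------------------------------------------------------------

def _delong_auc(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from midranks.

    The structural components V10 (per case) and V01 (per control) estimate
    P(case > control) with ties counted one half; their empirical variances
    give the asymptotic variance of the AUC.
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    r_all = scipy.stats.rankdata(combined)
    r_cases = scipy.stats.rankdata(cases)
    r_controls = scipy.stats.rankdata(controls)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_cases) / n
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    else:
        var = float("nan")
    return float(auc), float(var)


def auc(data: CaseControlDataset, model_name: str) -> AucEstimate:
    """Probability that a random case outscores a random control (ties one
    half), with a DeLong 95% confidence interval."""
    data.require_discriminable()
    scores = data.scores(model_name)
    status = data.status
    cases = scores[status == 1]
    controls = scores[status == 0]
    estimate, var = _delong_auc(cases, controls)
    if np.all(scores == scores[0]):
        logger.warning(
            "model '%s': all scores tied; AUC 0.5 with degenerate CI", model_name
        )
        return AucEstimate(
            model_name=model_name,
            auc=0.5,
            ci95=(0.5, 0.5),
            n_cases=len(cases),
            n_controls=len(controls),
            se=0.0,
        )
    se = math.sqrt(var) if np.isfinite(var) else float("nan")
    if math.isfinite(se):
        lo = max(0.0, estimate - 1.959963984540054 * se)
        hi = min(1.0, estimate + 1.959963984540054 * se)
    else:
        lo, hi = 0.0, 1.0
    return AucEstimate(
        model_name=model_name,
        auc=estimate,
        ci95=(lo, hi),
        n_cases=len(cases),
        n_controls=len(controls),
        se=se,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def improvement_log_opera(
    base: OperaEstimate | float, full: OperaEstimate | float
) -> float:
    """Percentage increase in log OPERA from the base to the full model:
    ``100 * (ln(full) - ln(base)) / ln(base)``.

    Requires base OPERA > 1 (a base model with no discrimination has
    log OPERA 0 and no meaningful relative improvement).  The ratio is
    identical in any log base, so natural logs are used.
    """
    base_v = base.opera if isinstance(base, OperaEstimate) else float(base)
    full_v = full.opera if isinstance(full, OperaEstimate) else float(full)
    if not (math.isfinite(base_v) and base_v > 1.0):
        raise ValidationError(
            f"relative log-OPERA improvement is undefined for base OPERA "
            f"{base_v!r} (must exceed 1)"
        )
    if not (math.isfinite(full_v) and full_v > 0):
        raise ValidationError(f"full-model OPERA must be positive, got {full_v!r}")
    return 100.0 * (math.log(full_v) - math.log(base_v)) / math.log(base_v)


def compare_log_risks(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    paired: bool = True,
) -> LogRiskComparison:
    """Two-sided t-test on log-transformed risk scores.

    Paired mode (default) compares two models' risks for the same subjects;
    unpaired mode uses Welch's t-test for independent groups (e.g. PRS in
    subjects with atypical hyperplasia vs no biopsy history).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("risk scores must be positive for log transformation")
    if paired and len(a) != len(b):
        raise ValidationError(
            f"paired comparison needs equal lengths, got {len(a)} and {len(b)}"
        )
    if min(len(a), len(b)) < 3:
        raise ValidationError("need at least 3 observations per group")
    la, lb = np.log(a), np.log(b)
    mean_diff = float(la.mean() - lb.mean())
    if paired:
        if np.allclose(la, lb):
            return LogRiskComparison(t=0.0, p=1.0, mean_log_diff=0.0, n=len(a))
        t, p = scipy.stats.ttest_rel(la, lb)
    else:
        t, p = scipy.stats.ttest_ind(la, lb, equal_var=False)
    return LogRiskComparison(t=float(t), p=float(p), mean_log_diff=mean_diff, n=len(a))


# ---------------------------------------------------------------------------
# Stratified report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-stratum, per-model AUC and OPERA plus pairwise improvements."""

    metrics: pd.DataFrame
    improvements: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.metrics.to_csv(path, index=False)

    def improvements_to_csv(self, path: str | Path) -> None:
        self.improvements.to_csv(path, index=False)

    def to_text(self) -> str:
        fmt = lambda df: df.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        parts = ["AUC and OPERA by stratum and model", fmt(self.metrics)]
        if len(self.improvements):
            parts += ["", "Pairwise log-OPERA improvements (%)", fmt(self.improvements)]
        return "\n".join(parts)


def evaluation_report(
    data: CaseControlDataset,
    models: Sequence[str] | None = None,
    adjusters: Sequence[str] = ("age",),
) -> EvaluationReport:
    """AUC (CI) and OPERA (CI, p) per ethnicity stratum and model, with
    pairwise log-OPERA improvements between models in the listed order.

    Strata are analyzed separately (no pooling); a stratum without cases or
    without controls is skipped with a warning.
    """
    models = list(models) if models is not None else list(data.models)
    if not models:
        raise ValidationError("at least one model column is required")
    strata = data.ethnicities or ("all",)
    rows, improvement_rows = [], []
    for stratum in strata:
        sub = data.subset(stratum) if data.ethnicities else data
        if sub.n_cases == 0 or sub.n_controls == 0:
            logger.warning(
                "stratum '%s' skipped: %d cases / %d controls",
                stratum, sub.n_cases, sub.n_controls,
            )
            continue
        operas: dict[str, OperaEstimate] = {}
        for name in models:
            a = auc(sub, name)
            o = opera(sub, name, adjusters=adjusters)
            operas[name] = o
            rows.append(
                {
                    "ethnicity": stratum,
                    "model": name,
                    "n": sub.n,
                    "n_cases": sub.n_cases,
                    "auc": a.auc,
                    "auc_lo": a.ci95[0],
                    "auc_hi": a.ci95[1],
                    "opera": o.opera,
                    "opera_lo": o.ci95[0],
                    "opera_hi": o.ci95[1],
                    "p": o.p_value,
                }
            )
        for i, base_name in enumerate(models):
            for full_name in models[i + 1 :]:
                base, full = operas[base_name], operas[full_name]
                if base.opera <= 1.0:
                    continue  # relative improvement undefined
                improvement_rows.append(
                    {
                        "ethnicity": stratum,
                        "base": base_name,
                        "full": full_name,
                        "improvement_pct": improvement_log_opera(base, full),
                    }
                )
    if not rows:
        raise EvaluationError("no stratum had both cases and controls")
    return EvaluationReport(
        metrics=pd.DataFrame(rows),
        improvements=pd.DataFrame(
            improvement_rows,
            columns=["ethnicity", "base", "full", "improvement_pct"],
        ),
    )
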