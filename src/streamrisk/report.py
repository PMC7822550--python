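"""Questionnaire completeness reporting.

Clinical risk models fail silently in practice when patients cannot answer
their questions; quantifying per-question missingness is what motivates a
streamlined model that keeps only age and first-degree family history.
A cell counts as missing when it is empty/NaN or the literal ``unknown``
(case-insensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("streamrisk.report")

#: Recognized questionnaire columns, in report order, with display labels.
QUESTION_LABELS: dict[str, str] = {
    "age": "Patient age",
    "age_menarche": "Age at menarche",
    "age_first_birth": "Age at first live birth",
    "family_history": "First-degree family history",
    "biopsy_ever": "Ever had a breast biopsy",
    "biopsy_count": "Number of breast biopsies",
    "atypical_hyperplasia": "Atypical hyperplasia",
    "ethnicity": "Ethnicity",
}

_YESNO_QUESTIONS = {"family_history", "biopsy_ever", "atypical_hyperplasia"}


def _missing_mask(col: pd.Series) -> np.ndarray:
    as_str = col.astype(object).astype(str).str.strip().str.lower()
    return (col.isna() | (as_str == "") | (as_str == "unknown") | (as_str == "nan")).to_numpy()


def _positive_mask(question: str, col: pd.Series, missing: np.ndarray) -> np.ndarray:
    """'Positive response': yes for yes/no questions, a nonzero count for
    biopsy_count, any answer for the rest."""
    answered = ~missing
    if question in _YESNO_QUESTIONS:
        as_str = col.astype(object).astype(str).str.strip().str.lower()
        return answered & (as_str.isin(("yes", "y", "true", "1"))).to_numpy()
    if question == "biopsy_count":
        numeric = pd.to_numeric(col, errors="coerce").fillna(0)
        return answered & (numeric > 0).to_numpy()
    return answered


@dataclass
class CompletenessReport:
    """Per-question missingness plus two overall aggregates.

    ``overall_cell_missing_pct`` is the share of all question cells that are
    missing or unknown; ``women_any_missing_pct`` is the share of subjects
    with at least one gap.  Both are reported because 'percent of all
    answers missing' is ambiguous between the two readings.
    """

    per_question: pd.DataFrame
    overall_cell_missing_pct: float
    women_any_missing_pct: float
    n: int

    def to_csv(self, path) -> None:
        self.per_question.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [f"Questionnaire completeness (n = {self.n})", ""]
        width = max(len(label) for label in self.per_question["question"])
        lines.append(f"{'Question':<{width}}  {'% missing/unknown':>18}  {'% positive':>10}")
        for row in self.per_question.itertuples(index=False):
            lines.append(
                f"{row.question:<{width}}  {row.pct_missing:>17.1f}%  {row.pct_positive:>9.1f}%"
            )
        lines += [
            "",
            f"Share of all question cells missing or unknown: "
            f"{self.overall_cell_missing_pct:.1f}%",
            f"Share of women with at least one missing/unknown answer: "
            f"{self.women_any_missing_pct:.1f}%",
        ]
        return "\n".join(lines)


def completeness_report(questionnaires: pd.DataFrame) -> CompletenessReport:
    """Summarize per-question missing-or-unknown and positive-response
    rates over the recognized question columns.

    Unrecognized columns are ignored with a warning; an empty table is an
    error.
    """
    if len(questionnaires) == 0:
        raise ValidationError("cannot summarize an empty questionnaire table")
    known = [c for c in questionnaires.columns if c in QUESTION_LABELS]
    unknown = [c for c in questionnaires.columns if c not in QUESTION_LABELS]
    if unknown:
        logger.warning("ignoring unrecognized questionnaire columns: %s", ", ".join(unknown))
    if not known:
        raise ValidationError(
            "no recognized questionnaire columns; expected some of: "
            + ", ".join(QUESTION_LABELS)
        )

    n = len(questionnaires)
    rows = []
    missing_matrix = np.zeros((n, len(known)), dtype=bool)
    for j, question in enumerate(known):
        col = questionnaires[question]
        missing = _missing_mask(col)
        positive = _positive_mask(question, col, missing)
        missing_matrix[:, j] = missing
        rows.append(
            {
                "question": QUESTION_LABELS[question],
                "column": question,
                "pct_missing": 100.0 * missing.mean(),
                "pct_positive": 100.0 * positive.mean(),
            }
        )
    return CompletenessReport(
        per_question=pd.DataFrame(rows),
        overall_cell_missing_pct=100.0 * missing_matrix.mean(),
        women_any_missing_pct=100.0 * missing_matrix.any(axis=1).mean(),
        n=n,
    )
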