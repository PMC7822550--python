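"""OPERA, AUC, log-OPERA improvement and log-risk t-tests."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamrisk import (
    CaseControlDataset,
    EvaluationError,
    ValidationError,
    adjusted_standardized_log_score,
    auc,
    compare_log_risks,
    evaluation_report,
    improvement_log_opera,
    opera,
)
from conftest import random_cohort


def brute_force_auc(cases, controls):
    """Exhaustive pair counting: wins + half-ties over all case-control pairs."""
    wins = ties = 0
    for c in cases:
        for u in controls:
            if c > u:
                wins += 1
            elif c == u:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def make_cohort(cases, controls):
    scores = list(cases) + list(controls)
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(scores))],
            "status": [1] * len(cases) + [0] * len(controls),
            "age": [50] * len(scores),
            "m": scores,
        }
    )
    return CaseControlDataset(frame)


class TestAuc:
    def test_perfect_separation_is_one(self):
        d = make_cohort([10, 11, 12], [1, 2, 3])
        assert auc(d, "m").auc == 1.0

    def test_all_tied_is_half_with_degenerate_ci(self, caplog):
        d = make_cohort([2, 2], [2, 2, 2])
        with caplog.at_level(logging.WARNING, logger="streamrisk.evaluation"):
            est = auc(d, "m")
        assert est.auc == 0.5
        assert est.ci95 == (0.5, 0.5)
        assert "tied" in caplog.text

    def test_small_example_pair_counting(self):
        d = make_cohort([3, 5], [1, 2, 4])
        assert auc(d, "m").auc == pytest.approx(5 / 6, abs=1e-15)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        d = random_cohort(rng, n, tie_fraction=0.4 if seed % 2 else 0.0)
        scores = d.scores("score")
        expected = brute_force_auc(scores[d.status == 1], scores[d.status == 0])
        assert auc(d, "score").auc == pytest.approx(expected, abs=1e-12)

    @given(shift=st.floats(-3, 3), scale=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_monotone_transforms(self, shift, scale):
        rng = np.random.default_rng(17)
        d = random_cohort(rng, 60)
        base = auc(d, "score").auc
        transformed = d.frame.copy()
        transformed["score"] = np.exp(scale * np.log(transformed["score"]) + shift)
        assert auc(CaseControlDataset(transformed), "score").auc == pytest.approx(
            base, abs=1e-12
        )

    def test_ci_brackets_estimate(self):
        d = random_cohort(np.random.default_rng(3), 150)
        est = auc(d, "score")
        assert est.ci95[0] <= est.auc <= est.ci95[1]

    def test_needs_both_classes(self):
        frame = pd.DataFrame(
            {"subject_id": ["a", "b"], "status": [1, 1], "age": [50, 60], "m": [1.0, 2.0]}
        )
        with pytest.raises(EvaluationError, match="at least one case and one control"):
            auc(CaseControlDataset(frame), "m")


class TestOpera:
    def test_affine_rescaling_of_log_score_absorbed(self, toy_cohort):
        base = opera(toy_cohort, "risk")
        rescaled = toy_cohort.frame.copy()
        rescaled["risk"] = np.exp(2.5 * np.log(rescaled["risk"]) - 1.0)
        other = opera(CaseControlDataset(rescaled), "risk")
        assert other.opera == pytest.approx(base.opera, abs=1e-8)
        assert other.p_value == pytest.approx(base.p_value, abs=1e-8)

    def test_standardization_unit_sd_among_controls(self, toy_cohort):
        z = adjusted_standardized_log_score(toy_cohort, "risk")
        controls = toy_cohort.status == 0
        assert np.std(z[controls], ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_null_score_opera_near_one(self):
        rng = np.random.default_rng(29)
        n = 5000
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "status": rng.integers(0, 2, size=n),
                "age": rng.integers(40, 75, size=n),
                "m": rng.lognormal(0, 1, size=n),
            }
        )
        est = opera(CaseControlDataset(frame), "m")
        assert abs(est.log_opera) < 3 * est.se_log

    def test_degenerate_score_raises(self):
        frame = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "status": [1, 0, 1, 0],
                "age": [50, 52, 54, 56],
                "m": [2.0, 2.0, 2.0, 2.0],
            }
        )
        with pytest.raises(EvaluationError, match="degenerate"):
            opera(CaseControlDataset(frame), "m")

    def test_ci_and_p_consistent(self, toy_cohort):
        est = opera(toy_cohort, "risk")
        assert est.ci95[0] <= est.opera <= est.ci95[1]
        assert 0 <= est.p_value <= 1


class TestImprovement:
    def test_printed_table_values(self):
        assert improvement_log_opera(1.387, 1.614) == pytest.approx(46.3, abs=0.05)

    def test_no_change_is_zero(self):
        assert improvement_log_opera(1.5, 1.5) == 0.0

    def test_direct_evaluation(self):
        expected = 100 * (math.log(1.316) - math.log(1.203)) / math.log(1.203)
        assert improvement_log_opera(1.203, 1.316) == pytest.approx(expected, rel=1e-12)
        assert improvement_log_opera(1.203, 1.316) == pytest.approx(48.6, abs=0.05)

    def test_base_at_or_below_one_rejected(self):
        with pytest.raises(ValidationError, match="base"):
            improvement_log_opera(1.0, 1.5)

    def test_log_base_irrelevant(self):
        natural = improvement_log_opera(1.387, 1.614)
        base10 = 100 * (math.log10(1.614) - math.log10(1.387)) / math.log10(1.387)
        assert natural == pytest.approx(base10, rel=1e-12)


class TestCompareLogRisks:
    def test_identical_vectors(self):
        r = compare_log_risks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0 and r.mean_log_diff == 0.0

    def test_paired_t_matches_hand_computation(self):
        a = [1.2, 0.8, 1.5, 2.0, 0.9, 1.1, 1.7, 0.6]
        b = [1.0, 0.9, 1.2, 2.2, 0.7, 1.3, 1.4, 0.5]
        diffs = np.log(a) - np.log(b)
        t_hand = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
        r = compare_log_risks(a, b)
        assert r.t == pytest.approx(t_hand, abs=1e-8)
        assert r.mean_log_diff == pytest.approx(diffs.mean(), rel=1e-12)

    def test_welch_mode_for_unequal_groups(self):
        rng = np.random.default_rng(31)
        a = rng.lognormal(0.3, 0.5, size=40)
        b = rng.lognormal(0.0, 0.8, size=25)
        r = compare_log_risks(a, b, paired=False)
        assert r.p < 0.5  # genuinely shifted means should not look null

    def test_input_validation(self):
        with pytest.raises(ValidationError, match="equal lengths"):
            compare_log_risks([1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(ValidationError, match="at least 3"):
            compare_log_risks([1, 2], [1, 2])
        with pytest.raises(ValidationError, match="positive"):
            compare_log_risks([1, -2, 3], [1, 2, 3])


class TestEvaluationReport:
    def test_single_stratum_matches_direct_calls(self, toy_cohort):
        report = evaluation_report(toy_cohort, models=["risk"])
        row = report.metrics.iloc[0]
        assert row["auc"] == pytest.approx(auc(toy_cohort, "risk").auc, rel=1e-12)
        assert row["opera"] == pytest.approx(opera(toy_cohort, "risk").opera, rel=1e-12)

    def test_empty_model_list_rejected(self, toy_cohort):
        with pytest.raises(ValidationError, match="at least one model"):
            evaluation_report(toy_cohort, models=[])

    def test_added_signal_improves_nested_model(self):
        rng = np.random.default_rng(37)
        n = 4000
        log_a = rng.normal(0, 0.4, size=n)
        log_extra = rng.normal(0, 0.4, size=n)
        p = np.minimum(0.08 * np.exp(log_a + log_extra - 0.16), 0.95)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "status": (rng.random(n) < p).astype(int),
                "age": rng.integers(40, 75, size=n),
                "model_a": np.exp(log_a),
                "model_b": np.exp(log_a + log_extra),
            }
        )
        report = evaluation_report(CaseControlDataset(frame), models=["model_a", "model_b"])
        improvement = report.improvements.iloc[0]["improvement_pct"]
        assert improvement > 0

    def test_stratum_without_cases_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(41)
        frames = []
        for ethnicity, with_cases in (("caucasian", True), ("hispanic", False)):
            n = 200
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": [f"{ethnicity}{i}" for i in range(n)],
                        "status": rng.integers(0, 2, size=n) if with_cases else 0,
                        "age": rng.integers(40, 75, size=n),
                        "ethnicity": ethnicity,
                        "m": rng.lognormal(0, 0.5, size=n),
                    }
                )
            )
        data = CaseControlDataset(pd.concat(frames, ignore_index=True))
        with caplog.at_level(logging.WARNING, logger="streamrisk.evaluation"):
            report = evaluation_report(data, models=["m"])
        assert set(report.metrics["ethnicity"]) == {"caucasian"}
        assert "hispanic" in caplog.text

    def test_cohort_csv_round_trip(self, tmp_path, toy_cohort):
        path = tmp_path / "cohort.csv"
        toy_cohort.to_csv(path)
        back = CaseControlDataset.from_csv(path)
        np.testing.assert_allclose(
            back.scores("risk"), toy_cohort.scores("risk"), rtol=1e-12
        )
        assert back.n_cases == toy_cohort.n_cases
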