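"""Spearman machinery, correlation modes and divergent-thinking scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from motioncomplexity.creativity_analysis import (
    UndefinedCorrelationError,
    divergent_scores,
    rank_rank_analysis,
    significance_band,
    spearman,
    subjectwise_correlation,
    trialwise_correlation,
)


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 9.0])
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        rho, _ = spearman(x, -np.exp(x))
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_scipy_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 3.0, 5.0]
        rho, p = spearman(x, y)
        oracle = stats.spearmanr(x, y)
        assert rho == pytest.approx(oracle.statistic, abs=1e-12)
        assert p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_midrank_definition_brute_force(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [3.0, 3.0, 1.0, 9.0]
        # midranks by hand: x -> 1, 2.5, 2.5, 4 ; y -> 2.5, 2.5, 1, 4
        rx, ry = np.array([1, 2.5, 2.5, 4.0]), np.array([2.5, 2.5, 1.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_permutation_p_value_is_seeded_and_sane(self):
        rng = np.random.default_rng(0)
        x = np.arange(10.0)
        y = x + rng.normal(0, 1.0, 10)
        _, p1 = spearman(x, y, permutations=500, seed=1)
        _, p2 = spearman(x, y, permutations=500, seed=1)
        assert p1 == p2
        assert p1 < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def make_records_and_ranks(n_subjects=5, n_trials=8, seed=0, banded=False):
    """Records plus a jury that ranks by the measure itself (noiseless)."""
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(1, n_trials + 1):
        for i in range(n_subjects):
            value = i * 100.0 + rng.uniform(0, 1) if banded else rng.normal()
            rows.append((f"s{i}", trial, value))
    records = pd.DataFrame(rows, columns=["subject", "trial", "gp"])
    ranks = records.copy()
    ranks["average_rank"] = ranks.groupby("trial")["gp"].rank(method="first")
    return records, ranks[["subject", "trial", "average_rank"]]


class TestTrialwise:
    def test_banded_self_ranking_reaches_tie_ceiling(self):
        # with subject bands the pooled correlation equals the analytic
        # maximum sqrt((n^2 - K^2)/(n^2 - 1)) imposed by rank ties
        m, K = 5, 8
        records, ranks = make_records_and_ranks(m, K, banded=True)
        rho, p = trialwise_correlation(records, ranks, "gp")
        n = m * K
        ceiling = np.sqrt((n**2 - K**2) / (n**2 - 1))
        assert rho == pytest.approx(ceiling, abs=1e-12)
        assert p < 1e-10

    def test_random_jury_uncorrelated(self):
        rhos = []
        for seed in range(30):
            records, _ = make_records_and_ranks(10, 55, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            ranks = records.copy()
            ranks["average_rank"] = rng.permutation(len(ranks)) % 10 + 1
            rho, _ = trialwise_correlation(records, ranks[["subject", "trial", "average_rank"]], "gp")
            rhos.append(abs(rho))
        assert np.median(rhos) < 0.1

    def test_coverage_mismatch_rejected(self):
        records, ranks = make_records_and_ranks()
        with pytest.raises(ValueError, match="different"):
            trialwise_correlation(records.iloc[:-1], ranks, "gp")


class TestSubjectwise:
    def test_exchangeable_self_ranking_positive_everywhere(self):
        records, ranks = make_records_and_ranks(6, 40, seed=4)
        table = subjectwise_correlation(records, ranks, "gp")
        assert (table["rho"] > 0).all()
        assert table.attrs["n_significant"] >= 5

    def test_constant_measure_isolated(self):
        records, ranks = make_records_and_ranks(4, 10, seed=2)
        records.loc[records["subject"] == "s0", "gp"] = 3.14
        table = subjectwise_correlation(records, ranks, "gp")
        assert table.loc[table["subject"] == "s0", "band"].item() == "undefined"
        assert table.loc[table["subject"] != "s0", "rho"].notna().all()

    def test_bands(self):
        assert significance_band(0.0005) == "p<0.001"
        assert significance_band(0.005) == "p<0.01"
        assert significance_band(0.02) == "p<0.05"
        assert significance_band(0.5) == "ns"


class TestRankRank:
    def test_self_ranking_fills_diagonal_with_unit_correlations(self):
        # exchangeable records: each subject's rank varies across trials,
        # and the self-ranking jury matches the measure rank exactly
        records, ranks = make_records_and_ranks(5, 12, seed=3)
        result = rank_rank_analysis(records, ranks, "gp")
        assert np.trace(result.histogram) == result.histogram.sum() == 5 * 12
        assert np.allclose(result.per_subject["rho"], 1.0, atol=1e-12)

    def test_constant_rank_subject_flagged_undefined(self):
        records, ranks = make_records_and_ranks(5, 12, banded=True)
        result = rank_rank_analysis(records, ranks, "gp")
        assert np.trace(result.histogram) == result.histogram.sum() == 5 * 12
        assert (result.per_subject["band"] == "undefined").all()

    def test_margins_equal_trial_count(self):
        records, ranks = make_records_and_ranks(6, 9, seed=5)
        result = rank_rank_analysis(records, ranks, "gp")
        np.testing.assert_array_equal(result.histogram.sum(axis=0), 9)
        np.testing.assert_array_equal(result.histogram.sum(axis=1), 9)

    def test_independent_orderings_spread_mass(self):
        records, _ = make_records_and_ranks(5, 200, seed=6)
        rng = np.random.default_rng(9)
        ranks = records.copy()
        ranks["average_rank"] = np.concatenate(
            [rng.permutation(5) + 1 for _ in range(200)]
        )
        result = rank_rank_analysis(records, ranks[["subject", "trial", "average_rank"]], "gp")
        chi2 = ((result.histogram - 200 / 5) ** 2 / (200 / 5)).sum()
        # 24 df; 5% critical value ~36.4
        assert chi2 < 50


class TestDivergentScores:
    def test_single_subject_degenerate(self):
        table = divergent_scores({"a": ["hat", "boat", "kite"]})
        row = table.iloc[0]
        assert row["fluency"] == 3
        assert row["originality"] == 0
        assert row["mean_originality"] == 0.0

    def test_unique_response_among_ten_subjects(self):
        responses = {f"s{i}": ["newspaper hat"] for i in range(9)}
        responses["s9"] = ["umbrella"]
        table = divergent_scores(responses).set_index("subject")
        assert table.loc["s9", "originality"] == 1
        assert table.loc["s9", "percentage"] == 1.0
        assert table.loc["s9", "mean_originality"] == pytest.approx(0.9)
        # the common response is given by 90% of subjects: not original
        assert table.loc["s0", "originality"] == 0
        assert table.loc["s0", "mean_originality"] == pytest.approx(0.1)

    def test_identical_responses_score_zero(self):
        table = divergent_scores({s: ["Fire  Starter"] for s in "abcd"})
        assert (table["percentage"] == 0).all()
        assert (table["mean_originality"] == 0).all()

    def test_canonicalisation_merges_variants(self):
        responses = {f"s{i}": ["Paper Hat "] if i else ["paper  hat"] for i in range(6)}
        responses["u"] = ["boat"]
        t = divergent_scores(responses).set_index("subject")
        # 'paper hat' variants merge: 6/7 subjects -> not original
        assert t.loc["s0", "originality"] == 0
        assert t.loc["s0", "mean_originality"] == pytest.approx(1 - 6 / 7)
        # 'boat' is given by 1/7 < 20% of subjects -> original
        assert t.loc["u", "originality"] == 1

    def test_empty_list_flagged(self):
        table = divergent_scores({"a": [], "b": ["x"]}).set_index("subject")
        assert table.loc["a", "fluency"] == 0
        assert np.isnan(table.loc["a", "mean_originality"])
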