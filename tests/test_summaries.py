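import numpy as np
import pandas as pd
import pytest

from stressmodes.pattern_classifier import ModeAssignment
from stressmodes.summaries import (
    DEFAULT_BIN_EDGES,
    contingency_analysis,
    mode_frequencies,
    pct_increase,
    pearson_residuals,
    round_half_up,
    silhouette_scores,
    subset_frequency,
)


def _assignment(i, mode, f_swl=1.5):
    return ModeAssignment(
        feature_id=f"g{i}", mode=mode, f_st=1.0, f_wl=1.0, f_swl=f_swl,
        additive_expectation=2.0, d_st=0.5, d_wl=0.5, d_sum=-0.5,
        rule_path="test",
    )


class TestModeFrequencies:
    def test_simple_arithmetic(self):
        a = [_assignment(i, m) for i, m in
             enumerate(["neutral", "neutral", "minor", "additive"])]
        freq = mode_frequencies(a)
        assert freq.counts["neutral"] == 2
        assert freq.percentages["neutral"] == pytest.approx(50.0)
        assert freq.percentages["minor"] == pytest.approx(25.0)

    def test_empty_input_flagged(self):
        freq = mode_frequencies([])
        assert freq.total == 0
        assert all(v == 0.0 for v in freq.percentages.values())

    def test_half_neutral_like_metabolite_panel(self):
        # 32 classified features, 16 neutral -> 50.0%
        modes = ["neutral"] * 16 + ["synergistic"] * 8 + ["antagonistic"] * 8
        freq = mode_frequencies([_assignment(i, m) for i, m in enumerate(modes)])
        assert freq.percentages["neutral"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(11)
        modes = rng.choice(["neutral", "minor", "additive", "dominant"], size=57)
        freq = mode_frequencies([_assignment(i, m) for i, m in enumerate(modes)])
        assert sum(freq.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_include_na_changes_denominator(self):
        a = [_assignment(0, "neutral"), _assignment(1, "non_assigned")]
        without = mode_frequencies(a, include_na=False)
        with_na = mode_frequencies(a, include_na=True)
        assert without.total == 1 and with_na.total == 2
        assert with_na.percentages["neutral"] == pytest.approx(50.0)


class TestPearsonResiduals:
    def test_diagonal_example(self):
        res = pearson_residuals([[10, 0], [0, 10]])
        expected = np.full((2, 2), 5.0)
        np.testing.assert_allclose(res.expected.to_numpy(), expected)
        np.testing.assert_allclose(
            res.residuals.to_numpy(),
            [[2.2361, -2.2361], [-2.2361, 2.2361]],
            atol=1e-4,
        )
        assert res.chi2 == pytest.approx(20.0)
        assert res.dof == 1

    def test_uniform_table_independent(self):
        res = pearson_residuals([[5, 5], [5, 5]])
        assert np.all(res.residuals.to_numpy() == 0)
        assert res.chi2 == 0.0

    def test_single_nonempty_row_degenerate(self):
        res = pearson_residuals([[3, 4], [0, 0]])
        assert res.dof == 0
        assert res.chi2 == 0.0

    def test_margins_preserved(self):
        rng = np.random.default_rng(5)
        obs = rng.integers(0, 20, size=(4, 3)).astype(float)
        res = pearson_residuals(obs)
        np.testing.assert_allclose(res.expected.sum(axis=1), obs.sum(axis=1))
        np.testing.assert_allclose(res.expected.sum(axis=0), obs.sum(axis=0))
        assert res.chi2 >= 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pearson_residuals([[1, -2], [0, 3]])


class TestContingencyAnalysis:
    def test_bins_by_swl_log2fc(self):
        a = [
            _assignment(0, "neutral", f_swl=1.5),
            _assignment(1, "neutral", f_swl=-1.5),
            _assignment(2, "minor", f_swl=0.5),
        ]
        res = contingency_analysis(a, DEFAULT_BIN_EDGES)
        assert res.observed.to_numpy().sum() == 3
        assert res.observed.loc["neutral", "[1, 2)"] == 1
        assert res.observed.loc["neutral", "[-2, -1)"] == 1
        assert res.observed.loc["minor", "[0, 1)"] == 1

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            contingency_analysis([], [1.0, 0.0, 2.0])


class TestPctIncrease:
    @pytest.mark.parametrize(
        "combined, single, expected",
        [(14053, 4111, 241.8), (14053, 2670, 426.3), (5, 5, 0.0)],
    )
    def test_printed_values(self, combined, single, expected):
        assert pct_increase(combined, single) == expected

    def test_raw_value_recovers_count(self):
        pct = pct_increase(14053, 4111, ndigits=None)
        assert 4111 * (1 + pct / 100) == pytest.approx(14053)

    def test_zero_single_rejected(self):
        with pytest.raises(ValueError):
            pct_increase(10, 0)


class TestSubsetFrequency:
    def test_eight_of_fortynine(self):
        annotations = {f"g{i}": ("L" if i < 8 else "other") for i in range(49)}
        omega = subset_frequency(annotations, set(annotations), "L")
        assert omega == 16.33

    def test_no_matches(self):
        assert subset_frequency({"g0": "A"}, {"g0"}, "B") == 0.0

    def test_all_match(self):
        annotations = {f"g{i}": "A" for i in range(5)}
        assert subset_frequency(annotations, set(annotations), "A") == 100.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            subset_frequency({}, set(), "A")


class TestRoundHalfUp:
    def test_ties_away_from_zero(self):
        assert round_half_up(2.5, 0) == 3.0
        assert round_half_up(0.125, 2) == 0.13


class TestSilhouetteScores:
    def test_two_tight_far_pairs(self):
        points = np.array([[0, 0], [0, 0.1], [10, 10], [10, 10.1]])
        scores, means = silhouette_scores(points, ["a", "a", "b", "b"])
        assert np.all(scores > 0.9)
        assert set(means.index) == {"a", "b"}

    def test_misplaced_point_scores_negative(self):
        points = np.array([[0, 0], [0.1, 0], [10, 10], [10.1, 10], [9.9, 10]])
        labels = ["a", "a", "b", "b", "a"]
        scores, _ = silhouette_scores(points, labels)
        assert scores[4] < 0

    def test_singleton_group_scores_zero(self):
        points = np.array([[0, 0], [0.1, 0], [5, 5]])
        scores, _ = silhouette_scores(points, ["a", "a", "b"])
        assert scores[2] == 0.0

    def test_scores_in_range_and_permutation_equivariant(self):
        rng = np.random.default_rng(9)
        points = rng.normal(size=(30, 4))
        labels = rng.choice(["a", "b", "c"], size=30)
        scores, _ = silhouette_scores(points, labels)
        assert np.all((scores >= -1) & (scores <= 1))
        perm = rng.permutation(30)
        scores_perm, _ = silhouette_scores(points[perm], labels[perm])
        np.testing.assert_allclose(scores_perm, scores[perm], atol=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            silhouette_scores(np.zeros((3, 2)), ["a", "a", "a"])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            silhouette_scores(np.array([[np.nan, 0], [1, 1]]), ["a", "b"])
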