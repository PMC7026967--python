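"""Correspondence analysis, Friedman/Nemenyi, major OTUs, removal rates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from otupipe.stats import (
    blocks_by_replicate,
    compact_letters,
    correspondence_analysis,
    friedman_test,
    nemenyi_posthoc,
    removal_rate,
    select_major_otus,
    studentized_range_sf,
    compare_features,
)
from oracles import chi_square_over_n, friedman_permutation_p, friedman_statistic


class TestCorrespondenceAnalysis:
    def test_rank_one_table_has_zero_inertia(self):
        r = np.array([1.0, 2.0, 3.0])
        c = np.array([4.0, 1.0, 2.0, 3.0])
        table = pd.DataFrame(np.outer(r, c))
        res = correspondence_analysis(table)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_total_inertia_equals_chi2_over_n_oracle(self, rng):
        for _ in range(25):
            m = rng.integers(1, 40, size=(5, 7)).astype(float)
            res = correspondence_analysis(pd.DataFrame(m))
            assert res.total_inertia == pytest.approx(
                chi_square_over_n(m.tolist()), abs=1e-9
            )

    def test_block_diagonal_groups_separate_in_sign_on_axis_1(self):
        m = np.array(
            [
                [30, 25, 1, 0],
                [28, 30, 0, 1],
                [1, 0, 40, 35],
                [0, 2, 38, 30],
            ],
            dtype=float,
        )
        res = correspondence_analysis(pd.DataFrame(m, index=list("abcd")))
        ax1 = res.row_coordinates["CA1"]
        assert np.sign(ax1["a"]) == np.sign(ax1["b"])
        assert np.sign(ax1["c"]) == np.sign(ax1["d"])
        assert np.sign(ax1["a"]) != np.sign(ax1["c"])

    def test_transition_formula_rows_from_columns(self, rng):
        """Row principal coordinates are the profile-weighted averages
        of column standard coordinates."""
        m = rng.integers(1, 30, size=(6, 5)).astype(float)
        table = pd.DataFrame(m)
        res = correspondence_analysis(table)
        profiles = m / m.sum(axis=1, keepdims=True)
        col_std = res.col_coordinates.values / res.singular_values
        np.testing.assert_allclose(
            res.row_coordinates.values, profiles @ col_std, atol=1e-8
        )

    def test_zero_row_or_column_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[1.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[1.0, 0.0], [2.0, 0.0]]))


class TestFriedman:
    def test_identical_groups_give_zero_statistic_p_one(self):
        m = np.tile([3.0, 3.0, 3.0], (5, 1))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_on_tie_free_data(self, rng):
        m = rng.normal(size=(12, 4))
        res = friedman_test(m)
        ref = sps.friedmanchisquare(*m.T)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_tie_corrected_statistic_matches_oracle(self, rng):
        m = rng.integers(0, 4, size=(8, 3)).astype(float)  # heavy ties
        res = friedman_test(m)
        assert res.statistic == pytest.approx(friedman_statistic(m.tolist()), abs=1e-9)

    def test_small_instance_p_close_to_exhaustive_permutation(self, rng):
        """n = 4 blocks, k = 3: the chi-square p is within the
        chi-square approximation's own worst-case error of the
        exhaustive (3!)^4 permutation p.  Enumerating the full
        tie-free null at this size gives max |p_chi2 - p_exact| =
        0.181, so 0.19 is the documented bound."""
        m = rng.normal(size=(4, 3))
        res = friedman_test(m)
        p_exact = friedman_permutation_p(m.tolist())
        assert abs(res.p_value - p_exact) < 0.19

    def test_two_groups_reduces_to_sign_test_chi2(self, rng):
        """k = 2, no ties: statistic = (n_+ - n_-)^2 / n, the
        chi-square form of the sign test, computed directly."""
        m = rng.normal(size=(15, 2))
        wins = int((m[:, 0] > m[:, 1]).sum())
        expected = (2 * wins - 15) ** 2 / 15
        assert friedman_test(m).statistic == pytest.approx(expected, abs=1e-9)

    def test_rejects_degenerate_layouts(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            friedman_test([[1.0, 2.0], [3.0]])


class TestStudentizedRange:
    @pytest.mark.parametrize("q,k", [(0.5, 3), (2.0, 4), (3.63, 4), (5.0, 6)])
    def test_matches_scipy_reference(self, q, k):
        mine = studentized_range_sf(q, k)
        ref = sps.studentized_range.sf(q, k, 1e7)  # effectively infinite df
        assert mine == pytest.approx(ref, abs=1e-5)

    def test_monotone_decreasing_in_q(self):
        qs = np.linspace(0.1, 6.0, 25)
        vals = [studentized_range_sf(q, 4) for q in qs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestNemenyi:
    def test_identical_groups_single_letter(self):
        m = np.tile([1.0, 1.0, 1.0, 1.0], (6, 1))
        res = nemenyi_posthoc(m, ["a", "b", "c", "d"])
        assert (res.p_matrix.values >= 0.999).all()
        assert set(res.letters.values()) == {"a"}

    def test_strongly_separated_group_gets_distinct_letter(self, rng):
        """One group larger than every other in all 15 blocks earns a
        letter no other group shares."""
        m = rng.normal(size=(15, 4))
        m[:, 2] += 40.0
        res = nemenyi_posthoc(m, ["g1", "g2", "BIG", "g4"])
        big = set(res.letters["BIG"])
        for g in ("g1", "g2", "g4"):
            assert not big & set(res.letters[g])

    def test_p_matrix_symmetric_unit_diagonal(self, rng):
        m = rng.normal(size=(8, 3))
        res = nemenyi_posthoc(m)
        p = res.p_matrix.values
        np.testing.assert_allclose(p, p.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(p), 1.0)

    def test_p_monotone_in_rank_sum_difference(self, rng):
        """Larger mean-rank separation never yields a larger p-value."""
        ranks = nemenyi_posthoc(np.random.default_rng(3).normal(size=(10, 4)))
        n, k = 10, 4
        se = np.sqrt(k * (k + 1) / (12 * n))
        diffs = np.linspace(0.0, 3.0, 20)
        ps = [studentized_range_sf(d / se, k) for d in diffs]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestCompactLetters:
    def test_all_similar_one_letter(self):
        p = pd.DataFrame(np.ones((3, 3)), index=list("xyz"), columns=list("xyz"))
        assert set(compact_letters(p).values()) == {"a"}

    def test_chain_structure_shares_middle_letter(self):
        # x != z, but y indistinguishable from both -> y gets both letters
        p = pd.DataFrame(
            [[1.0, 0.5, 0.01], [0.5, 1.0, 0.5], [0.01, 0.5, 1.0]],
            index=list("xyz"),
            columns=list("xyz"),
        )
        letters = compact_letters(p)
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])

    def test_letters_consistent_with_p_matrix(self, rng):
        for _ in range(20):
            k = 4
            p = np.ones((k, k))
            iu = np.triu_indices(k, 1)
            vals = rng.uniform(0, 0.2, size=len(iu[0]))
            p[iu] = vals
            p.T[iu] = vals
            pm = pd.DataFrame(p, index=list("abcd"), columns=list("abcd"))
            letters = compact_letters(pm, alpha=0.05)
            for i, gi in enumerate("abcd"):
                for gj in "abcd"[i + 1:]:
                    share = bool(set(letters[gi]) & set(letters[gj]))
                    assert share == (pm.loc[gi, gj] > 0.05)


class TestBlocking:
    def test_unequal_group_sizes_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=["a1", "a2", "b1"])
        groups = pd.Series(["A", "A", "B"], index=["a1", "a2", "b1"])
        with pytest.raises(ValueError, match="unequal"):
            blocks_by_replicate(values, groups)

    def test_feature_table_wrapper_runs_both_methods(self, rng):
        samples = [f"s{i}" for i in range(12)]
        groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=samples)
        ab = pd.DataFrame(
            {"f1": rng.normal(size=12), "f2": rng.normal(size=12)}, index=samples
        )
        fr = compare_features(ab, groups)
        kw = compare_features(ab, groups, method="kruskal")
        assert [t.feature for t in fr] == ["f1", "f2"]
        assert all(0 <= t.p_value <= 1 for t in fr + kw)


class TestMajorOtus:
    def test_threshold_is_on_group_means(self):
        samples = ["a1", "a2", "b1", "b2"]
        groups = pd.Series(["A", "A", "B", "B"], index=samples)
        rel = pd.DataFrame(
            {
                "below": [0.9, 0.9, 0.9, 0.9],
                "exactly_one_group": [1.5, 0.5, 0.0, 0.0],  # mean 1.0 in A
                "big": [10.0, 12.0, 8.0, 9.0],
            },
            index=samples,
        )
        assert select_major_otus(rel, groups) == ["exactly_one_group", "big"]

    def test_planted_major_taxa_all_selected(self, rng):
        samples = [f"s{i}" for i in range(8)]
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
        major = {f"M{j}": rng.uniform(2, 10, 8) for j in range(5)}
        minor = {f"m{j}": rng.uniform(0.0, 0.4, 8) for j in range(7)}
        rel = pd.DataFrame({**major, **minor}, index=samples)
        assert select_major_otus(rel, groups) == list(major)


class TestRemovalRate:
    @pytest.mark.parametrize(
        "removed,started,expected",
        [(36, 360, 10.0), (35, 383, 9.1), (26, 360, 7.2), (0, 99, 0.0)],
    )
    def test_printed_trial_arithmetic(self, removed, started, expected):
        assert removal_rate(removed, started) == expected

    def test_input_validation(self):
        with pytest.raises(ValueError):
            removal_rate(1, 0)
        with pytest.raises(ValueError):
            removal_rate(5, 4)
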