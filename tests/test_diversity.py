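"""Rarefaction, alpha estimators, Bray-Curtis, PCoA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis, pdist, squareform

from otupipe.cluster import CountTable
from otupipe.diversity import (
    DistanceMatrix,
    ace,
    bray_curtis,
    chao1,
    distance_matrix,
    goods_coverage,
    pcoa,
    rarefy,
    rarefy_table,
    shannon,
    simpson,
)
from oracles import (
    ace_oracle,
    bray_curtis_oracle,
    chao1_oracle,
    coverage_oracle,
    shannon_oracle,
    simpson_oracle,
)


class TestRarefy:
    def test_sum_equals_depth_exactly(self, rng):
        v = rng.integers(0, 500, 40)
        v[0] += 3000
        out = rarefy(v, 3000, seed=1)
        assert out.sum() == 3000
        assert (out <= v).all()

    def test_total_equal_to_depth_is_identity(self):
        v = np.array([5, 10, 85])
        assert (rarefy(v, 100, seed=0) == v).all()

    def test_below_depth_raises(self):
        with pytest.raises(ValueError, match="fewer than"):
            rarefy([10, 20], 100)

    def test_reproducible_under_seed(self, rng):
        v = rng.integers(0, 800, 30)
        v[0] += 3000
        assert (rarefy(v, 3000, seed=7) == rarefy(v, 3000, seed=7)).all()

    def test_hypergeometric_mean_within_3_se(self):
        """E[out_i] = depth * c_i / N; check over 10,000 draws."""
        v = np.array([500, 300, 150, 50])
        depth = 200
        rng = np.random.default_rng(5)
        draws = np.array([rarefy(v, depth, rng=rng) for _ in range(10_000)])
        n = v.sum()
        expect = depth * v / n
        # hypergeometric variance per category
        var = depth * (v / n) * (1 - v / n) * (n - depth) / (n - 1)
        se = np.sqrt(var / 10_000)
        assert (np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-9).all()

    def test_rarefaction_never_increases_richness(self, rng):
        for _ in range(20):
            v = rng.integers(0, 60, 50)
            if v.sum() < 100:
                continue
            out = rarefy(v, 100, rng=rng)
            assert (out[v == 0] == 0).all()
            assert (out > 0).sum() <= (v > 0).sum()


class TestAlphaExamples:
    def test_chao1_hand_computed_values(self):
        assert chao1([1, 1, 2]) == pytest.approx(3.5)
        assert chao1([1, 1]) == pytest.approx(3.0)
        assert chao1([3, 4, 5]) == pytest.approx(3.0)  # no singletons -> S_obs

    def test_ace_no_rare_classes_equals_observed(self):
        assert ace([11, 25, 300]) == pytest.approx(3.0)

    def test_ace_all_singletons_falls_back_to_observed(self):
        assert ace([1, 1, 1]) == pytest.approx(3.0)

    def test_shannon_uniform_is_log_s(self):
        assert shannon([7, 7, 7, 7]) == pytest.approx(np.log(4))

    def test_single_otu_degenerate_values(self):
        assert shannon([42]) == pytest.approx(0.0)
        assert simpson([42]) == pytest.approx(1.0)
        assert goods_coverage([42]) == pytest.approx(100.0)

    def test_mixed_vector_coverage_and_simpson(self):
        # counts {1,1,2}: coverage = 1 - 2/4 = 50%; D = 2*1/(4*3) = 1/6
        assert goods_coverage([1, 1, 2]) == pytest.approx(50.0)
        assert simpson([1, 1, 2]) == pytest.approx(1 / 6)

    def test_shannon_invariant_to_zero_count_otus(self, rng):
        v = rng.integers(1, 50, 20)
        padded = np.concatenate([v, np.zeros(30, dtype=int)])
        assert shannon(padded) == pytest.approx(shannon(v), abs=1e-12)


def test_all_estimators_match_naive_oracles_on_random_vectors(rng):
    """100 random count vectors: every estimator agrees with the
    independently coded textbook formula to 1e-9."""
    for _ in range(100):
        v = rng.integers(0, 30, int(rng.integers(3, 40)))
        assert chao1(v) == pytest.approx(chao1_oracle(v), abs=1e-9)
        assert ace(v) == pytest.approx(ace_oracle(v), abs=1e-9)
        assert shannon(v) == pytest.approx(shannon_oracle(v), abs=1e-9)
        assert simpson(v) == pytest.approx(simpson_oracle(v), abs=1e-9)
        assert goods_coverage(v) == pytest.approx(coverage_oracle(v), abs=1e-9)


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        assert bray_curtis([3, 4], [3, 4]) == 0.0
        assert bray_curtis([3, 0], [0, 4]) == 1.0

    def test_hand_computed_example(self):
        assert bray_curtis([6, 2], [2, 2]) == pytest.approx(1 / 3)

    def test_matches_oracle_and_scipy(self, rng):
        for _ in range(100):
            x = rng.integers(0, 50, 12)
            y = rng.integers(0, 50, 12)
            if x.sum() + y.sum() == 0:
                continue
            mine = bray_curtis(x, y)
            assert mine == pytest.approx(bray_curtis_oracle(x, y), abs=1e-9)
            assert mine == pytest.approx(scipy_braycurtis(x, y), abs=1e-9)

    def test_bounded_and_symmetric(self, rng):
        x = rng.integers(0, 9, 6)
        y = rng.integers(0, 9, 6)
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))


class TestPcoa:
    def test_planar_points_roundtrip_distances(self, rng):
        """Euclidean distances of known 2-D points are reconstructed
        from the positive axes to 1e-8."""
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(tuple(f"s{i}" for i in range(7)), d))
        coords = res.coordinates.values
        rebuilt = squareform(pdist(coords))
        np.testing.assert_allclose(rebuilt, d, atol=1e-8)
        assert (res.eigenvalues[2:] < 1e-8).all()  # planar: 2 informative axes

    def test_identical_samples_identical_coordinates(self):
        d = np.array(
            [[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        res = pcoa(DistanceMatrix(("a", "b", "c"), d))
        np.testing.assert_allclose(
            res.coordinates.loc["a"].values, res.coordinates.loc["b"].values, atol=1e-10
        )

    def test_collinear_points_put_all_variance_on_pc1(self):
        x = np.array([0.0, 1.0, 2.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(("a", "b", "c"), d))
        assert res.proportions[0] == pytest.approx(1.0)
        assert res.coordinates.shape[1] == 1

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), bad)

    def test_agrees_with_skbio_on_bray_curtis(self, rng):
        skbio = pytest.importorskip("skbio")
        counts = pd.DataFrame(
            rng.integers(0, 200, size=(6, 15)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"o{j}" for j in range(15)],
        )
        table = CountTable(counts, {f"s{i}": "g" for i in range(6)})
        dm = distance_matrix(table)
        res = pcoa(dm)
        sk = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm.data, list(dm.ids)))
        n_pos = res.coordinates.shape[1]
        for k in range(min(n_pos, 3)):
            mine = res.coordinates.iloc[:, k].values
            theirs = sk.samples.iloc[:, k].values
            assert np.allclose(mine, theirs, atol=1e-6) or np.allclose(mine, -theirs, atol=1e-6)
        np.testing.assert_allclose(
            res.eigenvalues[:n_pos], sk.eigvals.values[:n_pos], atol=1e-8
        )


def test_rarefy_table_drops_or_raises_on_short_samples(rng):
    counts = pd.DataFrame(
        {"o1": [500, 5], "o2": [600, 5]}, index=["deep", "shallow"]
    )
    table = CountTable(counts, {"deep": "g", "shallow": "g"})
    with pytest.raises(ValueError, match="shallow"):
        rarefy_table(table, 100, seed=0)
    kept = rarefy_table(table, 100, seed=0, on_short="drop")
    assert kept.samples == ["deep"]
    assert kept.sample_sums().tolist() == [100]
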