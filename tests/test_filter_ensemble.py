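import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfsof.filter_ensemble import (
    build_rank_table,
    chi_square_scores,
    discretize,
    fit_discretizer,
    information_gain_scores,
    mean_fuse,
    median_fuse,
    rank_features,
    select_candidate_pool,
    symmetrical_uncertainty_scores,
)
from hfsof.synthetic_data import PlantedFeatureSpec, generate_planted_features


class TestDiscretizer:
    def test_equal_width_halves(self):
        Z = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = fit_discretizer(Z, n_bins=2)
        D = discretize(model, Z)
        assert D[:, 0].tolist() == [0, 0, 1, 1]

    def test_constant_feature_single_bin(self):
        Z = np.full((5, 1), 3.3)
        model = fit_discretizer(Z, n_bins=4)
        D = discretize(model, Z)
        assert np.all(D == 0)

    def test_out_of_range_clamps(self):
        Z = np.array([[0.0], [10.0]])
        model = fit_discretizer(Z, n_bins=5)
        D = discretize(model, np.array([[-5.0], [50.0]]))
        assert D[0, 0] == 0
        assert D[1, 0] == 4

    def test_bad_bin_count(self):
        with pytest.raises(ValueError):
            fit_discretizer(np.zeros((3, 1)), n_bins=1)


def _label_identical_feature():
    y = np.array([0] * 10 + [1] * 10)
    D = y.reshape(-1, 1).copy()
    return D, y


class TestInformationGain:
    def test_deterministic_relation_gives_ln2(self):
        D, y = _label_identical_feature()
        ig = information_gain_scores(D, y)
        assert ig[0] == pytest.approx(np.log(2.0))

    def test_constant_feature_zero(self):
        y = np.array([0] * 5 + [1] * 5)
        D = np.zeros((10, 1), dtype=np.int64)
        assert information_gain_scores(D, y)[0] == pytest.approx(0.0)

    def test_bounded_by_entropies(self, rng):
        y = rng.integers(0, 3, size=50)
        D = rng.integers(0, 4, size=(50, 6))
        ig = information_gain_scores(D, y)
        py = np.bincount(y) / 50
        hy = -(py[py > 0] * np.log(py[py > 0])).sum()
        for j in range(6):
            px = np.bincount(D[:, j]) / 50
            hx = -(px[px > 0] * np.log(px[px > 0])).sum()
            assert -1e-12 <= ig[j] <= min(hx, hy) + 1e-12


class TestChiSquare:
    def test_diagonal_table_value(self):
        # counts [[10,0],[0,10]]: all expected counts are 5, chi2 = 4*25/5 = 20
        D, y = _label_identical_feature()
        assert chi_square_scores(D, y)[0] == pytest.approx(20.0)

    def test_proportional_counts_zero(self):
        y = np.array([0, 0, 1, 1] * 5)
        D = np.array([0, 1, 0, 1] * 5).reshape(-1, 1)
        assert chi_square_scores(D, y)[0] == pytest.approx(0.0)

    def test_doubling_counts_doubles_statistic(self, rng):
        y = rng.integers(0, 2, size=30)
        D = rng.integers(0, 3, size=(30, 2))
        base = chi_square_scores(D, y)
        doubled = chi_square_scores(np.vstack([D, D]), np.concatenate([y, y]))
        np.testing.assert_allclose(doubled, 2.0 * base)


class TestSymmetricalUncertainty:
    def test_label_identical_feature_is_one(self):
        D, y = _label_identical_feature()
        assert symmetrical_uncertainty_scores(D, y)[0] == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        y = np.array([0] * 5 + [1] * 5)
        D = np.zeros((10, 1), dtype=np.int64)
        assert symmetrical_uncertainty_scores(D, y)[0] == pytest.approx(0.0)

    def test_unit_interval_bound(self, rng):
        y = rng.integers(0, 4, size=80)
        D = rng.integers(0, 5, size=(80, 10))
        su = symmetrical_uncertainty_scores(D, y)
        assert np.all(su >= 0.0) and np.all(su <= 1.0 + 1e-12)


class TestRankFeatures:
    def test_basic_ordering(self):
        np.testing.assert_array_equal(
            rank_features(np.array([0.9, 0.1, 0.5])), [1.0, 3.0, 2.0]
        )

    def test_average_rank_ties(self):
        np.testing.assert_array_equal(
            rank_features(np.array([0.5, 0.5, 0.1])), [1.5, 1.5, 3.0]
        )

    def test_full_tie(self):
        ranks = rank_features(np.full(7, 0.3))
        np.testing.assert_allclose(ranks, 4.0)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_rank_sum_conservation(self, scores):
        p = len(scores)
        ranks = rank_features(np.array(scores))
        assert ranks.sum() == pytest.approx(p * (p + 1) / 2)


class TestFusion:
    def test_median_of_three(self):
        out = median_fuse(np.array([3.0]), np.array([7.0]), np.array([4.0]))
        assert out[0] == pytest.approx(4.0)

    def test_identical_triples_unchanged(self):
        r = np.array([2.0, 5.0, 1.0])
        np.testing.assert_array_equal(median_fuse(r, r, r), r)

    def test_order_invariance(self, rng):
        a, b, c = (rng.uniform(1, 10, size=8) for _ in range(3))
        np.testing.assert_array_equal(median_fuse(a, b, c), median_fuse(c, a, b))

    def test_mean_of_three(self):
        out = mean_fuse(np.array([3.0]), np.array([7.0]), np.array([4.0]))
        assert out[0] == pytest.approx(14.0 / 3.0)

    def test_mean_vs_median_on_outlier(self):
        a, b, c = np.array([1.0]), np.array([1.0]), np.array([10.0])
        assert median_fuse(a, b, c)[0] == pytest.approx(1.0)
        assert mean_fuse(a, b, c)[0] == pytest.approx(4.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            median_fuse(np.zeros(2), np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError):
            mean_fuse(np.zeros(2), np.zeros(3), np.zeros(2))


class TestCandidatePool:
    def test_smallest_two(self):
        pool = select_candidate_pool(np.array([5.0, 1.0, 3.0, 2.0]), m=2)
        assert sorted(pool.tolist()) == [1, 3]

    def test_identity(self):
        fused = np.array([4.0, 2.0, 3.0])
        assert sorted(select_candidate_pool(fused, 3).tolist()) == [0, 1, 2]

    def test_tie_break_by_index(self):
        pool = select_candidate_pool(np.array([2.0, 1.0, 2.0]), m=2)
        assert pool.tolist() == [1, 0]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            select_candidate_pool(np.array([1.0, 2.0]), m=3)


class TestRankTable:
    def test_planted_feature_ranks_first(self):
        ds, truth = generate_planted_features(
            PlantedFeatureSpec(n_samples=300, n_features=20, n_informative=1,
                               delta=4.0, n_classes=2, seed=3)
        )
        table = build_rank_table(ds.X, ds.y)
        j = truth[0]
        assert table.r_fused[j] <= 1.5
        # rank-sum conservation for every rank column
        p = table.n_features
        for ranks in (table.r_ig, table.r_cs, table.r_su):
            assert ranks.sum() == pytest.approx(p * (p + 1) / 2)

    def test_single_filter_modes_reproduce_filter_ranks(self, planted_small):
        ds, _ = planted_small
        fused_table = build_rank_table(ds.X, ds.y, mode="fusion_median")
        for mode, column in (
            ("ig_only", "r_ig"), ("cs_only", "r_cs"), ("su_only", "r_su")
        ):
            table = build_rank_table(ds.X, ds.y, mode=mode)
            np.testing.assert_array_equal(table.r_fused, getattr(fused_table, column))

    def test_monotone_bin_relabeling_invariance(self, rng):
        # scores depend only on the contingency table, so applying a strictly
        # monotone map to the bin ids leaves all three scores unchanged
        y = rng.integers(0, 3, size=60)
        D = rng.integers(0, 4, size=(60, 3))
        D2 = D * 3 + 1  # strictly monotone relabeling
        for fn in (information_gain_scores, chi_square_scores,
                   symmetrical_uncertainty_scores):
            np.testing.assert_allclose(fn(D, y), fn(D2, y), atol=1e-12)

    def test_unknown_mode(self, planted_small):
        ds, _ = planted_small
        with pytest.raises(ValueError, match="unknown filter mode"):
            build_rank_table(ds.X, ds.y, mode="nope")

    def test_table_round_trip(self, tmp_path, planted_small):
        ds, _ = planted_small
        table = build_rank_table(ds.X, ds.y)
        path = tmp_path / "ranks.tsv"
        table.save(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["feature_id", "ig", "chi2", "su", "r_ig", "r_cs",
                          "r_su", "r_fused"]
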