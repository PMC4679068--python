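"""Pseudo-matrix construction, re-ordered jackknife, K-fold projack."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import projack as pj
from projack.containers import FoldPartition, PseudoMatrix
from projack.resampling import DegenerateSubsetError


def explicit_score_z(X, y):
    n = X.shape[1]
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    return np.sqrt(n) * (xc @ yc) / np.sqrt((xc * xc).sum(axis=1) * (yc @ yc))


class TestRowMeans:
    @pytest.mark.parametrize(
        "mat, expected",
        [([[1.0, 3.0]], [2.0]), ([[0.0, 0.0], [5.0, 5.0]], [0.0, 5.0])],
    )
    def test_arithmetic(self, mat, expected):
        np.testing.assert_allclose(pj.row_means(np.array(mat)), expected)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pj.row_means(np.empty((0, 0)))


class TestBuildPseudoMatrix:
    def test_one_sample_closed_form_is_sqrt_n_times_data(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0]])
        C = pj.build_pseudo_matrix(X, statistic="one_sample_z")
        np.testing.assert_allclose(C.values, 2.0 * X, atol=1e-12)

    def test_row_means_reproduce_z_exactly_for_mean_statistic(self, rng):
        X = rng.normal(size=(7, 12))
        C = pj.build_pseudo_matrix(X, statistic="one_sample_z")
        z = np.sqrt(12) * X.mean(axis=1)
        np.testing.assert_allclose(pj.row_means(C), z, atol=1e-12)

    def test_constant_row_yields_constant_pseudo_values(self):
        X = np.vstack([np.full(6, 3.5), np.arange(6.0)])
        C = pj.build_pseudo_matrix(X, statistic="one_sample_z")
        np.testing.assert_allclose(C.values[0], np.sqrt(6) * 3.5, atol=1e-12)

    @pytest.mark.parametrize("statistic", ["linear_score_z", "trend_z"])
    def test_closed_form_loo_matches_explicit_recomputation(self, statistic, rng):
        X = rng.normal(size=(2, 10))
        if statistic == "trend_z":
            y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1], dtype=float)
        else:
            y = rng.normal(size=10)
        C_closed = pj.build_pseudo_matrix(X, y, statistic)
        C_explicit = pj.build_pseudo_matrix(X, y, explicit_score_z)
        np.testing.assert_allclose(C_closed.values, C_explicit.values, atol=1e-10)

    def test_generic_mean_statistic_matches_builtin(self, rng):
        X = rng.normal(size=(3, 8))
        C1 = pj.build_pseudo_matrix(X, statistic="one_sample_z")
        C2 = pj.build_pseudo_matrix(
            X, statistic=lambda Xs, ys: np.sqrt(Xs.shape[1]) * Xs.mean(axis=1)
        )
        np.testing.assert_allclose(C1.values, C2.values, atol=1e-10)

    def test_degenerate_loo_subset_names_feature_and_sample(self):
        # removing the last sample leaves row "snpA" constant
        X = np.vstack([np.r_[np.full(7, 2.0), 9.0], np.arange(8.0)])
        y = np.arange(8.0)
        with pytest.raises(DegenerateSubsetError) as exc:
            pj.build_pseudo_matrix(X, y, "linear_score_z", ids=["snpA", "snpB"])
        assert exc.value.feature == "snpA"
        assert exc.value.sample == 7

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            pj.build_pseudo_matrix(np.ones((2, 5)), statistic="wilcoxon")

    def test_missing_outcome_rejected(self):
        with pytest.raises(ValueError, match="requires an outcome"):
            pj.build_pseudo_matrix(np.ones((2, 5)), statistic="linear_score_z")

    def test_trend_requires_binary_outcome(self):
        with pytest.raises(ValueError, match="binary"):
            pj.build_pseudo_matrix(
                np.random.default_rng(0).normal(size=(2, 6)),
                np.arange(6.0),
                "trend_z",
            )

    def test_covariate_residualization_removes_confounding(self, rng):
        # x depends on y only through the covariate; residualizing kills the z
        v = rng.normal(size=40)
        y = v + 0.01 * rng.normal(size=40)
        X = np.atleast_2d(v + 0.01 * rng.normal(size=40))
        z_raw = pj.row_means(pj.build_pseudo_matrix(X, y, "linear_score_z"))
        z_adj = pj.row_means(
            pj.build_pseudo_matrix(X, y, "linear_score_z", covariates=v)
        )
        assert abs(z_adj[0]) < abs(z_raw[0]) / 5


class TestReorderedJackknife:
    @pytest.mark.parametrize(
        "mat, expected_D, expected_delta",
        [
            # LOO rankings agree with the full ranking, D = C
            ([[0.0, 2.0], [4.0, 6.0]], [[0.0, 2.0], [4.0, 6.0]], [1.0, 5.0]),
            # j=1 ranks by column 2 (0 < 4), j=2 ranks by column 1 (1 < 5)
            ([[5.0, 0.0], [1.0, 4.0]], [[5.0, 4.0], [1.0, 0.0]], [4.5, 0.5]),
        ],
    )
    def test_hand_traced_examples(self, mat, expected_D, expected_delta):
        D, delta = pj.reordered_jackknife(np.array(mat))
        np.testing.assert_allclose(D, expected_D)
        np.testing.assert_allclose(delta, expected_delta)

    def test_constant_matrix_unchanged(self):
        D, delta = pj.reordered_jackknife(np.full((4, 6), 2.5))
        np.testing.assert_allclose(delta, 2.5)

    @given(st.integers(0, 2**32 - 1), st.integers(2, 8), st.integers(2, 9))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_each_column_of_D_permutes_the_matching_column_of_C(self, seed, m, n):
        C = np.random.default_rng(seed).normal(size=(m, n))
        D, delta = pj.reordered_jackknife(C)
        for j in range(n):
            np.testing.assert_allclose(np.sort(D[:, j]), np.sort(C[:, j]))
        np.testing.assert_allclose(delta.mean(), C.mean(), atol=1e-12)


class TestRandomPartition:
    @pytest.mark.parametrize("n, K, sizes", [(4, 2, {2}), (5, 2, {2, 3}), (10, 5, {2})])
    def test_fold_sizes_as_equal_as_possible(self, n, K, sizes):
        part = pj.random_partition(n, K, seed=3)
        assert set(part.sizes.tolist()) == sizes
        assert part.sizes.sum() == n

    def test_deterministic_given_seed(self):
        a = pj.random_partition(20, 3, seed=11)
        b = pj.random_partition(20, 3, seed=11)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    @pytest.mark.parametrize("n, K", [(5, 1), (5, 6), (3, 0)])
    def test_invalid_fold_counts_rejected(self, n, K):
        with pytest.raises(ValueError):
            pj.random_partition(n, K)


class TestKFoldCollapse:
    def test_fold_means_match_paper_formula_for_equal_folds(self):
        C = np.array([[1.0, 2.0, 3.0, 4.0]])
        part = FoldPartition(assignments=np.array([0, 0, 1, 1]), K=2)
        np.testing.assert_allclose(pj.kfold_collapse(C, part), [[1.5, 3.5]])

    def test_constant_row_collapses_to_constant(self):
        C = np.full((2, 6), 7.0)
        part = pj.random_partition(6, 3, seed=0)
        np.testing.assert_allclose(pj.kfold_collapse(C, part), 7.0)

    def test_row_means_preserved_for_equal_folds(self, rng):
        C = rng.normal(size=(5, 12))
        part = pj.random_partition(12, 4, seed=9)
        np.testing.assert_allclose(
            pj.kfold_collapse(C, part).mean(axis=1), C.mean(axis=1), atol=1e-12
        )

    def test_partition_must_cover_columns(self):
        part = pj.random_partition(6, 2, seed=0)
        with pytest.raises(ValueError):
            pj.kfold_collapse(np.ones((2, 8)), part)

    def test_empty_fold_rejected_at_construction(self):
        with pytest.raises(ValueError, match="at least one column"):
            FoldPartition(assignments=np.array([0, 0, 0, 0]), K=2)


class TestProjack:
    def test_constant_matrix_estimates_constant(self):
        est = pj.projack(np.full((3, 12), -1.5), K=4, n_partitions=5, seed=2)
        np.testing.assert_allclose(est.delta_hat, -1.5, atol=1e-12)

    def test_bit_identical_given_seed(self, rng):
        C = PseudoMatrix(values=rng.normal(size=(6, 20)))
        a = pj.projack(C, K=5, n_partitions=10, seed=42)
        b = pj.projack(C, K=5, n_partitions=10, seed=42)
        np.testing.assert_array_equal(a.delta_hat, b.delta_hat)
        np.testing.assert_array_equal(a.rank_to_feature, b.rank_to_feature)

    @given(st.integers(0, 2**32 - 1), st.sampled_from([2, 4, 5, 10, 20]))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_mean_estimate_equals_grand_mean_when_k_divides_n(self, seed, K):
        g = np.random.default_rng(seed)
        C = g.normal(size=(8, 20))
        est = pj.projack(C, K=K, n_partitions=4, seed=g)
        np.testing.assert_allclose(est.delta_hat.mean(), C.mean(), atol=1e-12)

    def test_well_separated_rows_are_not_shrunk(self, rng):
        # mu = (-10, +10): consistent ordering, so the outliers keep their value
        mu = np.array([-10.0, 10.0])
        est_sum = np.zeros(2)
        reps = 200
        for _ in range(reps):
            C = pj.simulate_pseudo_matrix(mu, 20, 0.0, rng)
            est_sum += pj.projack(C, K=5, n_partitions=10, seed=rng).delta_hat
        np.testing.assert_allclose(est_sum / reps, mu, atol=0.15)

    def test_rank_map_sorts_observed_row_means(self, rng):
        C = PseudoMatrix(values=rng.normal(size=(9, 15)))
        est = pj.projack(C, K=3, n_partitions=2, seed=0)
        z = pj.row_means(C)
        assert np.all(np.diff(z[est.rank_to_feature]) >= 0)

    def test_invalid_k_rejected(self, rng):
        C = rng.normal(size=(3, 10))
        with pytest.raises(ValueError):
            pj.projack(C, K=1, n_partitions=5, seed=0)
        with pytest.raises(ValueError):
            pj.projack(C, K=11, n_partitions=5, seed=0)


class TestNullBehaviour:
    def test_exactly_unbiased_under_constant_mean(self):
        from conftest import collect_delta_hats

        vals = collect_delta_hats(
            np.zeros(10), n=20, K=5, n_partitions=20, n_sims=2000, seed=99
        )
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0])
        assert np.all(np.abs(mean) <= 4 * se)

    def test_top_rank_shrinks_relative_to_naive_statistic(self, rng):
        top_hat, top_naive = [], []
        for _ in range(400):
            C = pj.simulate_pseudo_matrix(np.zeros(10), 20, 0.0, rng)
            top_hat.append(pj.projack(C, K=5, n_partitions=10, seed=rng).delta_hat[-1])
            top_naive.append(np.max(pj.row_means(C)))
        assert np.mean(np.abs(top_hat)) < np.mean(top_naive)
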