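"""Discretization, entropy and mutual-information estimation."""

import numpy as np
import pytest

from cbbgwo.encoding import FeatureMatrix, N_FEATURES
from cbbgwo.mi import (discretize, discretize_matrix, entropy,
                       mi_from_joint, mutual_information,
                       pairwise_mi_matrix, relevance_to_label)


def brute_force_mi(table):
    """Direct cell-by-cell evaluation of the MI double sum (bits)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            p = table[i, j] / n
            if p > 0:
                px = table[i].sum() / n
                py = table[:, j].sum() / n
                total += p * np.log2(p / (px * py))
    return total


def _matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    full = np.zeros((values.shape[0], N_FEATURES))
    full[:, :values.shape[1]] = values
    if labels is None:
        labels = np.array(["a", "b"] * (values.shape[0] // 2 + 1)
                          )[:values.shape[0]]
    return FeatureMatrix(values=full, labels=labels,
                         ids=[f"s{i}" for i in range(values.shape[0])])


class TestDiscretize:
    def test_constant_vector_single_code(self):
        with pytest.warns(UserWarning, match="clamping"):
            codes = discretize(np.zeros(4), 5)
        assert set(codes) == {0}

    def test_equal_frequency_split(self):
        codes = discretize(np.arange(10, dtype=float), 2)
        assert list(codes) == [0] * 5 + [1] * 5

    def test_ties_share_lower_bin(self):
        # the tied pair straddles a bin boundary and takes the lower bin
        codes = discretize(np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0]), 3)
        assert list(codes) == [0, 0, 0, 1, 2, 2]

    def test_matches_sort_based_oracle(self, rng):
        values = rng.random(97)
        n_bins = 5
        codes = discretize(values, n_bins)
        order = np.argsort(values)
        expected = np.empty(97, dtype=int)
        expected[order] = np.arange(97) * n_bins // 97
        assert np.array_equal(codes, expected)  # distinct values: no ties
        occupancy = np.bincount(codes)
        assert occupancy.max() - occupancy.min() <= 1

    def test_clamps_excess_bins_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            codes = discretize(np.array([1.0, 2.0, 3.0]), 10)
        assert codes.max() <= 2

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            discretize(np.array([1.0, np.nan]), 2)
        with pytest.raises(ValueError):
            discretize(np.arange(4.0), 1)


class TestEntropy:
    @pytest.mark.parametrize("p, expected", [
        ([0.5, 0.5], 1.0),
        ([1.0], 0.0),
        ([0.125] * 8, 3.0),
    ])
    def test_closed_forms(self, p, expected):
        assert entropy(np.array(p)) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_distribution(self):
        with pytest.raises(ValueError):
            entropy(np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            entropy(np.array([1.5, -0.5]))


class TestMutualInformation:
    def test_identity_equals_entropy(self):
        x = np.array([0, 1] * 8)
        assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_product_table_is_zero(self):
        # exact product-form joint counts: 20 samples, p(x)=1/2, p(y)=1/4
        table = np.array([[2, 2, 2, 2], [2, 2, 2, 2]], dtype=float)
        assert mi_from_joint(table) == pytest.approx(0.0, abs=1e-12)

    def test_random_joint_matches_brute_force(self, rng):
        table = rng.integers(0, 20, size=(3, 3)).astype(float)
        table[0, 0] += 1  # non-empty
        assert mi_from_joint(table) == pytest.approx(
            brute_force_mi(table), abs=1e-12)

    def test_three_forms_agree(self, rng):
        for _ in range(20):
            table = rng.integers(0, 30, size=(4, 3)).astype(float) + 0.0
            table[1, 1] += 1
            direct = mi_from_joint(table, "direct")
            assert mi_from_joint(table, "entropy") == pytest.approx(
                direct, abs=1e-10)
            assert mi_from_joint(table, "pmi") == pytest.approx(
                direct, abs=1e-10)
            assert direct >= -1e-12

    def test_merging_bins_never_increases_mi(self, rng):
        """Coarsening one variable (data-processing) cannot add information."""
        for _ in range(10):
            table = rng.integers(0, 15, size=(4, 4)).astype(float)
            table[0, 0] += 1
            merged = np.vstack([table[0] + table[1], table[2] + table[3]])
            assert mi_from_joint(merged) <= mi_from_joint(table) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))


class TestPairwiseMatrix:
    def test_matches_per_pair_estimates(self, rng):
        values = rng.random((30, 6))
        matrix = _matrix(values)
        mim = pairwise_mi_matrix(matrix, n_bins=3)
        codes, _ = discretize_matrix(matrix, n_bins=3)
        d = codes.shape[1]
        for i in range(d):
            for j in range(d):
                expected = mutual_information(codes[:, i], codes[:, j])
                assert mim.values[i, j] == pytest.approx(expected, abs=1e-5)

    def test_symmetry_and_nonnegativity(self, rng):
        mim = pairwise_mi_matrix(_matrix(rng.random((25, 8))), n_bins=4)
        assert np.array_equal(mim.values, mim.values.T)
        assert (mim.values >= 0).all()

    def test_diagonal_equals_feature_entropy(self, rng):
        matrix = _matrix(rng.random((40, 5)))
        mim = pairwise_mi_matrix(matrix, n_bins=4)
        codes, _ = discretize_matrix(matrix, n_bins=4)
        for k in range(codes.shape[1]):
            counts = np.bincount(codes[:, k])
            h = entropy(counts / counts.sum())
            assert mim.values[k, k] == pytest.approx(h, abs=1e-5)

    def test_duplicated_feature_attains_row_maximum(self, rng):
        base = rng.random(40)
        values = np.column_stack([base, base, rng.random((40, 3))])
        mim = pairwise_mi_matrix(_matrix(values), n_bins=4)
        # I(f0; f1) = H(f0) and is the largest off-diagonal entry of row 0
        row = mim.values[0].copy()
        assert row[1] == pytest.approx(mim.values[0, 0], abs=1e-5)
        row[0] = -1
        assert np.argmax(row) == 1

    def test_permutation_equivariance(self, rng):
        values = rng.random((20, 6))
        perm = rng.permutation(6)
        a = pairwise_mi_matrix(_matrix(values), n_bins=3).values
        b = pairwise_mi_matrix(_matrix(values[:, perm]), n_bins=3).values
        assert np.allclose(a[np.ix_(perm, perm)], b, atol=1e-6)

    def test_constant_nonzero_features_have_zero_mi(self):
        values = np.column_stack([np.full(10, 0.5), np.full(10, 0.2),
                                  np.arange(10) / 10 + 0.01])
        mim = pairwise_mi_matrix(_matrix(values), n_bins=3)
        # float32 accumulator: zero only up to single-precision round-off
        assert mim.values[0, 1] == pytest.approx(0.0, abs=1e-6)
        assert mim.values[0, 2] == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_columns_screened_out(self, rng):
        values = np.zeros((12, 5))
        values[:, 2] = rng.random(12)
        mim = pairwise_mi_matrix(_matrix(values), n_bins=3)
        assert list(mim.feature_indices) == [3]  # 1-based original index

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pairwise_mi_matrix(_matrix(np.ones((1, 4))))


class TestRelevance:
    def test_feature_identical_to_label(self):
        labels = np.array(["a", "b"] * 10)
        values = np.column_stack([(labels == "a").astype(float) + 0.1,
                                  np.full(20, 0.3)])
        rel = relevance_to_label(_matrix(values, labels))
        assert rel.iloc[0] == pytest.approx(1.0, abs=1e-12)  # H(label)=1

    def test_constant_feature_is_irrelevant(self):
        labels = np.array(["a", "b"] * 10)
        values = np.column_stack([np.full(20, 0.3), np.arange(20.0) + 1])
        rel = relevance_to_label(_matrix(values, labels))
        assert rel.loc[1] == pytest.approx(0.0, abs=1e-12)

    def test_single_class_warns_and_zeroes(self):
        values = np.random.default_rng(0).random((8, 3))
        with pytest.warns(UserWarning, match="single class"):
            rel = relevance_to_label(_matrix(values, np.array(["a"] * 8)))
        assert (rel == 0).all()

    def test_planted_features_rank_above_background(self, tiny_dataset):
        matrix, truth, _ = tiny_dataset
        rel = relevance_to_label(matrix)
        planted = sorted(truth.all_indices)
        background = rel.drop(index=planted, errors="ignore")
        assert rel.reindex(planted).fillna(0).mean() \
            > background.median()
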