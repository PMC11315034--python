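"""Cleaning, scaling, splitting, partitioning and class balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgcascade import (
    BalancingPlan,
    TabularDataset,
    apply_balancing,
    apply_scaler,
    balance_search,
    clean,
    fit_scaler,
    partition_subsets,
    split_train_test,
)
from kgcascade.preprocess import EmptyAfterCleaningError


class TestClean:
    def test_fixture_counts(self, dirty_fixture):
        out = clean(dirty_fixture)
        assert out.n_rows == 9
        assert out.metadata["n_duplicates_dropped"] == 2
        assert out.metadata["n_missing_dropped"] == 1

    def test_identity_on_clean_data(self, toy_dataset):
        out = clean(toy_dataset)
        assert np.array_equal(out.features, toy_dataset.features)
        assert np.array_equal(out.labels, toy_dataset.labels)

    def test_keep_first_of_triplicate(self):
        row = np.array([[1.0, 2.0]])
        data = TabularDataset(np.vstack([row, row, row]), np.zeros(3), ["a", "b"])
        assert clean(data).n_rows == 1

    def test_idempotent(self, dirty_fixture):
        once = clean(dirty_fixture)
        twice = clean(once)
        assert np.array_equal(once.features, twice.features)

    def test_all_rows_removed_raises(self):
        data = TabularDataset(np.full((3, 2), np.nan), np.zeros(3), ["a", "b"])
        with pytest.raises(EmptyAfterCleaningError):
            clean(data)


class TestScaler:
    def test_standard_worked_example(self):
        data = TabularDataset(np.array([[1.0], [3.0]]), np.array([0, 1]), ["x"])
        s = fit_scaler(data, "standard")
        assert s.location[0] == pytest.approx(2.0)
        assert s.scale[0] == pytest.approx(1.0)  # population std

    def test_constant_column_minmax_maps_to_zero(self):
        data = TabularDataset(np.full((4, 1), 7.0), np.tile([0, 1], 2), ["x"])
        s = fit_scaler(data, "minmax")
        assert s.scale[0] == 0.0
        assert np.all(apply_scaler(data, s).features == 0.0)

    def test_standardized_columns_after_transform(self, toy_dataset):
        s = fit_scaler(toy_dataset, "standard")
        out = apply_scaler(toy_dataset, s)
        assert np.allclose(out.features.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.features.std(axis=0), 1, atol=1e-9)

    def test_test_set_uses_train_statistics(self, toy_dataset):
        s = fit_scaler(toy_dataset, "standard")
        shifted = TabularDataset(
            toy_dataset.features + 10.0, toy_dataset.labels, toy_dataset.feature_names
        )
        out = apply_scaler(shifted, s)
        assert np.allclose(out.features.mean(axis=0), 10 / s.scale, atol=1e-6)

    def test_missing_cells_direct_to_clean(self, dirty_fixture):
        with pytest.raises(ValueError, match="clean"):
            fit_scaler(dirty_fixture)

    def test_width_mismatch(self, toy_dataset):
        s = fit_scaler(toy_dataset)
        narrow = TabularDataset(np.ones((2, 2)), np.array([0, 1]), ["a", "b"])
        with pytest.raises(ValueError):
            apply_scaler(narrow, s)


class TestSplit:
    @pytest.mark.parametrize("n,frac,n_train", [(100, 0.8, 80), (5, 0.8, 4)])
    def test_sizes(self, n, frac, n_train):
        data = TabularDataset(
            np.arange(n, dtype=float)[:, None], np.tile([0, 1], n)[:n], ["x"]
        )
        train, test = split_train_test(data, frac, seed=0)
        assert (train.n_rows, test.n_rows) == (n_train, n - n_train)
        combined = np.sort(np.concatenate([train.features[:, 0], test.features[:, 0]]))
        assert np.array_equal(combined, np.arange(n))

    def test_deterministic(self, toy_dataset):
        a, _ = split_train_test(toy_dataset, 0.8, seed=5)
        b, _ = split_train_test(toy_dataset, 0.8, seed=5)
        assert np.array_equal(a.features, b.features)

    def test_empty_side_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            split_train_test(toy_dataset, 0.01, seed=0)


class TestPartition:
    def test_equal_sizes(self, toy_dataset):
        plan = partition_subsets(toy_dataset, 4, seed=0)
        assert [len(s) for s in plan.subsets] == [10, 10, 10, 10]

    def test_remainder_spread(self):
        data = TabularDataset(np.ones((102, 1)), np.tile([0, 1], 51), ["x"])
        plan = partition_subsets(data, 4, seed=0)
        assert sorted(len(s) for s in plan.subsets) == [25, 25, 26, 26]

    def test_single_subset_is_all_rows_in_order(self, toy_dataset):
        plan = partition_subsets(toy_dataset, 1, seed=3)
        assert np.array_equal(plan.subsets[0], np.arange(40))

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(2, 60), k=st.integers(1, 8), seed=st.integers(0, 99))
    def test_disjoint_exhaustive(self, n, k, seed):
        k = min(k, n)
        data = TabularDataset(np.ones((n, 1)), np.tile([0, 1], n)[:n], ["x"])
        plan = partition_subsets(data, k, seed)
        merged = np.concatenate(plan.subsets)
        assert len(merged) == n
        assert np.array_equal(np.sort(merged), np.arange(n))
        assert max(len(s) for s in plan.subsets) - min(len(s) for s in plan.subsets) <= 1

    def test_too_many_subsets(self, toy_dataset):
        with pytest.raises(ValueError):
            partition_subsets(toy_dataset, 41, seed=0)


def _imbalanced(n_neg, n_pos, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.standard_normal((n_neg, d)), rng.standard_normal((n_pos, d)) + 1.5]
    )
    y = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    return TabularDataset(X, y, [f"f{i}" for i in range(d)])


class TestBalancing:
    def test_hybrid_920_80_to_500_each(self):
        out = apply_balancing(_imbalanced(920, 80), BalancingPlan(500, seed=1))
        assert np.bincount(out.labels).tolist() == [500, 500]

    def test_already_balanced_fixed_point_counts(self):
        out = apply_balancing(_imbalanced(500, 500), BalancingPlan(500, seed=1))
        assert np.bincount(out.labels).tolist() == [500, 500]

    def test_both_classes_oversampled_above_majority(self):
        out = apply_balancing(_imbalanced(10, 10), BalancingPlan(15, seed=1))
        assert np.bincount(out.labels).tolist() == [15, 15]

    @pytest.mark.parametrize("version", [1, 2, 3])
    def test_nearmiss_versions_hit_target(self, version):
        out = apply_balancing(
            _imbalanced(300, 60), BalancingPlan(60, nearmiss_version=version, seed=2)
        )
        assert np.bincount(out.labels).tolist() == [60, 60]

    def test_minority_too_small_names_minimum(self):
        with pytest.raises(ValueError, match="6"):
            apply_balancing(_imbalanced(50, 3), BalancingPlan(20, seed=1))

    def test_smote_rows_interpolate_minority(self):
        data = _imbalanced(100, 20)
        out = apply_balancing(data, BalancingPlan(100, seed=3))
        minority = data.features[data.labels == 1]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        synth = out.features[out.labels == 1]
        assert np.all(synth >= lo - 1e-9) and np.all(synth <= hi + 1e-9)

    @settings(deadline=None, max_examples=15)
    @given(
        n_neg=st.integers(20, 80),
        n_pos=st.integers(10, 40),
        m=st.integers(8, 60),
        seed=st.integers(0, 50),
    )
    def test_counts_exact_for_random_toys(self, n_neg, n_pos, m, seed):
        out = apply_balancing(_imbalanced(n_neg, n_pos, seed=seed), BalancingPlan(m, seed=seed))
        assert np.bincount(out.labels).tolist() == [m, m]


class TestBalanceSearch:
    def test_contract_and_membership(self):
        train = _imbalanced(900, 120, seed=4)
        result = balance_search(train, [60, 120, 240], eval_seed=7)
        assert len(result.records) == 3
        assert result.chosen.target_per_class in [60, 120, 240]

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            balance_search(_imbalanced(100, 30), [200, 100], eval_seed=0)

    def test_failed_value_recorded_not_fatal(self):
        # the tiny minority cannot be SMOTEd up to 50, but undersampling to 2
        # still works, so the search degrades gracefully
        train = _imbalanced(200, 5, seed=1)
        result = balance_search(train, [2, 50], eval_seed=0)
        failed = [r for r in result.records if r["failed"]]
        assert len(failed) == 1 and failed[0]["m"] == 50
        assert result.chosen.target_per_class == 2

    def test_all_values_failing_is_fatal(self):
        train = _imbalanced(200, 5, seed=1)
        with pytest.raises(ValueError, match="every grid value"):
            balance_search(train, [50, 80], eval_seed=0)
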