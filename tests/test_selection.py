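"""Tests for wrapper fitness, mask repair and the selection harness."""

import itertools

import numpy as np
import pytest

from mantisfs.optimize import ConfigurationError, OptimizerConfig
from mantisfs.selection import (
    FeatureTable,
    FitnessSpec,
    compare_optimizers,
    repair_mask,
    select_features,
    wrapper_fitness,
)


class TestRepairMask:
    def test_all_zero_becomes_one_hot(self, rng):
        repaired = repair_mask(np.zeros(4, dtype=np.int8), rng)
        assert repaired.sum() == 1

    def test_valid_mask_untouched(self, rng):
        mask = np.array([0, 1, 0], dtype=np.int8)
        assert np.array_equal(repair_mask(mask, rng), mask)

    def test_repair_bit_is_uniform(self):
        counts = np.zeros(4)
        for seed in range(10_000):
            rng = np.random.default_rng(seed)
            counts += repair_mask(np.zeros(4, dtype=np.int8), rng)
        freq = counts / 10_000
        assert np.all(np.abs(freq - 0.25) < 0.02)


class TestWrapperFitness:
    def test_all_ones_alpha_zero_is_plain_cv_accuracy(self, small_table):
        table, _ = small_table
        spec = FitnessSpec(alpha=0.0, seed=0)
        fit = wrapper_fitness(table, np.ones(table.n_features), spec)
        # recompute by hand with the same folds and classifier
        from sklearn.model_selection import StratifiedKFold
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        correct = 0
        for tr, te in skf.split(table.values, table.labels):
            pipe = make_pipeline(
                StandardScaler(), KNeighborsClassifier(n_neighbors=5, metric="euclidean")
            )
            pipe.fit(table.values[tr], table.labels[tr])
            correct += np.sum(pipe.predict(table.values[te]) == table.labels[te])
        assert fit == pytest.approx(correct / table.n_samples)

    def test_planted_mask_beats_noise_mask(self, small_table, knn_spec):
        table, planted = small_table
        noise_idx = np.flatnonzero(planted == 0)[: int(planted.sum())]
        noise_mask = np.zeros_like(planted)
        noise_mask[noise_idx] = 1
        assert wrapper_fitness(table, planted, knn_spec) > wrapper_fitness(
            table, noise_mask, knn_spec
        )

    def test_penalty_arithmetic(self, small_table):
        """Two masks with equal CV accuracy differ by alpha*size difference."""
        table, _ = small_table
        mask4 = np.zeros(64, dtype=np.int8)
        mask4[:4] = 1
        spec0 = FitnessSpec(alpha=0.0, seed=0)
        spec5 = FitnessSpec(alpha=0.5, seed=0)
        base = wrapper_fitness(table, mask4, spec0)
        assert wrapper_fitness(table, mask4, spec5) == pytest.approx(
            base - 0.5 * 4 / 64
        )

    def test_permutation_equivariance(self, small_table, knn_spec, rng):
        table, planted = small_table
        perm = rng.permutation(table.n_features)
        permuted = FeatureTable(
            values=table.values[:, perm],
            labels=table.labels,
            feature_ids=table.feature_ids[perm],
            sample_ids=table.sample_ids,
        )
        assert wrapper_fitness(table, planted, knn_spec) == pytest.approx(
            wrapper_fitness(permuted, planted[perm], knn_spec)
        )

    def test_all_zero_mask_rejected(self, small_table, knn_spec):
        table, _ = small_table
        with pytest.raises(ValueError, match="all-zero"):
            wrapper_fitness(table, np.zeros(table.n_features), knn_spec)

    def test_single_class_rejected(self, knn_spec):
        values = np.random.default_rng(0).normal(size=(20, 4))
        table = FeatureTable(
            values=values,
            labels=np.zeros(20, dtype=int),
            feature_ids=np.array([f"f{i}" for i in range(4)]),
            sample_ids=np.array([f"s{i}" for i in range(20)]),
        )
        with pytest.raises(ValueError, match="class"):
            wrapper_fitness(table, np.ones(4), knn_spec)


class TestSelectFeatures:
    def test_two_feature_exhaustive(self, two_feature_table):
        """Matches brute-force enumeration of all three valid masks."""
        spec = FitnessSpec(alpha=0.1, n_folds=4, seed=0)
        fits = {
            mask: wrapper_fitness(two_feature_table, np.array(mask), spec)
            for mask in [(0, 1), (1, 0), (1, 1)]
        }
        best_mask = max(fits, key=fits.get)
        cfg = OptimizerConfig(algorithm="FMO", pop_size=10, max_iter=15, seed=1)
        result = select_features(two_feature_table, cfg, spec)
        assert tuple(result.best_mask) == best_mask == (0, 1)
        assert result.best_fitness == pytest.approx(fits[best_mask])
        # separating feature alone: perfect CV accuracy minus the penalty
        assert result.best_fitness == pytest.approx(1.0 - 0.1 * 1 / 2)

    def test_best_fitness_reproducible_from_mask(self, small_table, knn_spec):
        table, _ = small_table
        cfg = OptimizerConfig(algorithm="GA", pop_size=10, max_iter=10, seed=2)
        result = select_features(table, cfg, knn_spec)
        assert wrapper_fitness(table, result.best_mask, knn_spec) == pytest.approx(
            result.best_fitness
        )
        assert result.n_selected == result.best_mask.sum() >= 1

    def test_max_iter_zero_is_best_of_initial_population(self, two_feature_table):
        spec = FitnessSpec(alpha=0.01, n_folds=4, seed=0)
        cfg = OptimizerConfig(algorithm="FMO", pop_size=6, max_iter=0, seed=3)
        result = select_features(two_feature_table, cfg, spec)
        assert len(result.history) == 1
        assert result.best_fitness == result.history[0]

    def test_all_ones_baseline_disclosed(self, two_feature_table):
        spec = FitnessSpec(alpha=0.01, n_folds=4, seed=0)
        cfg = OptimizerConfig(pop_size=6, max_iter=5, seed=0)
        result = select_features(two_feature_table, cfg, spec)
        assert "all_ones_baseline_fitness" in result.config_echo

    def test_single_feature_table_rejected(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(
            values=rng.normal(size=(20, 1)),
            labels=np.array([0, 1] * 10),
            feature_ids=np.array(["f0"]),
            sample_ids=np.array([f"s{i}" for i in range(20)]),
        )
        with pytest.raises(ConfigurationError):
            select_features(table, OptimizerConfig(), FitnessSpec())


class TestCompareOptimizers:
    def test_single_algorithm_matches_direct_run(self, small_table):
        table, _ = small_table
        cfg = OptimizerConfig(pop_size=8, max_iter=5, seed=0)
        spec = FitnessSpec(seed=0)
        frame = compare_optimizers(table, ["FMO"], cfg, spec, n_seeds=1)
        frame2 = compare_optimizers(table, ["FMO"], cfg, spec, n_seeds=1)
        assert len(frame) == 1
        assert frame.equals(frame2)  # deterministic rerun
        for col in ("sensitivity_mean", "specificity_mean", "accuracy_mean", "f1_mean"):
            assert 0.0 <= frame[col].iloc[0] <= 100.0

    def test_report_shape_over_algorithms(self, small_table):
        table, _ = small_table
        cfg = OptimizerConfig(pop_size=6, max_iter=3, seed=0)
        frame = compare_optimizers(
            table, ["FMO", "GA"], cfg, FitnessSpec(seed=0), n_seeds=2
        )
        assert list(frame["algorithm"]) == ["FMO", "GA"]
        assert {"sensitivity_mean", "specificity_mean", "accuracy_mean", "f1_mean",
                "sensitivity_sd", "specificity_sd", "accuracy_sd", "f1_sd"} <= set(frame.columns)

    def test_empty_algorithm_list_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ConfigurationError):
            compare_optimizers(table, [], OptimizerConfig(), FitnessSpec())

    def test_unknown_algorithm_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ConfigurationError):
            compare_optimizers(table, ["SA"], OptimizerConfig(), FitnessSpec())


class TestFeatureTableValidation:
    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureTable(
                values=np.array([[1.0, np.nan]]),
                labels=np.array([1]),
                feature_ids=np.array(["a", "b"]),
                sample_ids=np.array(["s"]),
            )

    def test_duplicate_feature_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureTable(
                values=np.ones((2, 2)),
                labels=np.array([0, 1]),
                feature_ids=np.array(["a", "a"]),
                sample_ids=np.array(["s1", "s2"]),
            )

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            FeatureTable(
                values=np.ones((2, 2)),
                labels=np.array([0, 2]),
                feature_ids=np.array(["a", "b"]),
                sample_ids=np.array(["s1", "s2"]),
            )
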