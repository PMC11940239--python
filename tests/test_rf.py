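"""Random Forest validation scaffold: splits, AUC, importance, arms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mucomet.preprocess import preprocess
from mucomet.rf import (
    RFConfig,
    RFGrid,
    RFValidationError,
    SklearnForest,
    bootstrap_ci,
    compute_auc,
    default_grid,
    grid_search,
    permutation_importance,
    run_validation,
    scramble_labels,
    stratified_split,
)
from mucomet.synthetic import PlantedEffect, SyntheticSpec, generate_feature_table

CASE, CTRL = "IBS", "control"


def _labels(n_case, n_control):
    return np.array([CASE] * n_case + [CTRL] * n_control)


class TestStratifiedSplit:
    def test_study_sizes_give_31_48_training(self, rng):
        train, test = stratified_split(_labels(44, 69), 0.7, rng)
        y = _labels(44, 69)
        assert (y[train] == CASE).sum() == 31
        assert (y[train] == CTRL).sum() == 48
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 113

    def test_symmetric_half_split(self, rng):
        train, test = stratified_split(_labels(10, 10), 0.5, rng)
        y = _labels(10, 10)
        for part in (train, test):
            assert (y[part] == CASE).sum() == 5 and (y[part] == CTRL).sum() == 5

    def test_fraction_emptying_a_partition_is_an_error(self, rng):
        with pytest.raises(RFValidationError, match="empties"):
            stratified_split(_labels(2, 10), 0.9, rng)

    def test_split_is_random_but_stratified(self, rng):
        seen = {tuple(stratified_split(_labels(6, 8), 0.5, rng)[0]) for _ in range(20)}
        assert len(seen) > 1


class TestComputeAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.7, 0.6], _labels(2, 2), CASE) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.5] * 6, _labels(3, 3), CASE) == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert compute_auc([0.9, 0.4, 0.8, 0.3], _labels(2, 2), CASE) == 0.75

    def test_single_class_is_an_error(self):
        with pytest.raises(RFValidationError, match="single class"):
            compute_auc([0.1, 0.2], np.array([CASE, CASE]), CASE)

    def test_matches_roc_integration_exhaustively(self):
        """Pair counting equals trapezoidal ROC area on all small cases."""
        score_grid = (0.1, 0.5, 0.9)
        for n in (2, 3, 4):
            for labels in itertools.product((0, 1), repeat=n):
                if len(set(labels)) < 2:
                    continue
                for scores in itertools.product(score_grid, repeat=n):
                    mine = compute_auc(np.array(scores), np.array(labels), 1)
                    ref = roc_auc_score(labels, scores)
                    assert mine == pytest.approx(ref, abs=1e-12), (labels, scores)


class TestScramble:
    def test_identical_labels_unchanged(self, rng):
        np.testing.assert_array_equal(
            scramble_labels(np.array([CASE] * 5), rng), [CASE] * 5
        )

    def test_class_counts_preserved(self, rng):
        y = _labels(31, 48)
        s = scramble_labels(y, rng)
        assert (s == CASE).sum() == 31 and (s == CTRL).sum() == 48

    def test_fixed_point_fraction_matches_expectation(self, rng):
        # P(position keeps its label) = sum_c (n_c/n)^2 for a uniform
        # permutation of the multiset
        y = _labels(6, 14)
        expected = (6 / 20) ** 2 + (14 / 20) ** 2
        fracs = [np.mean(scramble_labels(y, rng) == y) for _ in range(3000)]
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)


class TestBootstrapCI:
    def test_constant_vector_collapses(self, rng):
        assert bootstrap_ci([3.0] * 7, 200, rng=rng) == (3.0, 3.0)

    def test_two_point_sample_brackets_the_median(self, rng):
        lo, hi = bootstrap_ci([0.0, 1.0], 2000, rng=rng)
        assert 0.0 <= lo <= 0.5 <= hi <= 1.0

    def test_shared_rng_oracle(self, rng):
        values = np.array([0.3, 0.9, 0.1, 0.55, 0.42, 0.8, 0.05, 0.66, 0.71, 0.2])
        lo, hi = bootstrap_ci(values, 500, rng=np.random.default_rng(99))
        ref_rng = np.random.default_rng(99)
        idx = ref_rng.integers(0, len(values), size=(500, len(values)))
        medians = np.median(values[idx], axis=1)
        ref = np.percentile(medians, [2.5, 97.5])
        med = float(np.median(values))
        assert (lo, hi) == (min(ref[0], med), max(ref[1], med))

    def test_empty_input_is_an_error(self, rng):
        with pytest.raises(RFValidationError):
            bootstrap_ci([], 10, rng=rng)


class _FirstFeatureModel:
    """Contract stub: scores are feature 0; every other feature ignored."""

    def __init__(self, positive_label):
        self.positive_label = positive_label

    def fit(self, X, y, params, seed):
        return self

    def predict_scores(self, X):
        return X[:, 0]


class TestPermutationImportance:
    def test_ignored_features_leave_auc_unchanged(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 0] + rng.normal(0, 0.5, 30) > 0, CASE, CTRL)
        if len(np.unique(y)) < 2:
            y[0] = CASE if (y == CTRL).all() else CTRL
        model = _FirstFeatureModel(CASE).fit(X, y, {}, 0)
        baseline = 1.0 - compute_auc(model.predict_scores(X), y, CASE)
        one_minus = permutation_importance(model, X, y, CASE, rng)
        np.testing.assert_allclose(one_minus[1:], baseline, atol=1e-12)
        assert one_minus[0] != pytest.approx(baseline, abs=1e-6)

    def test_constant_column_permutation_is_identity(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 2] = 7.0
        y = _labels(10, 10)
        model = _FirstFeatureModel(CASE).fit(X, y, {}, 0)
        baseline = 1.0 - compute_auc(model.predict_scores(X), y, CASE)
        one_minus = permutation_importance(model, X, y, CASE, rng)
        assert one_minus[2] == baseline

    def test_permuting_the_signal_moves_one_minus_auc_toward_half(self, rng):
        X = np.r_[np.full((10, 1), 2.0), np.full((10, 1), -2.0)]
        y = _labels(10, 10)
        model = _FirstFeatureModel(CASE).fit(X, y, {}, 0)
        vals = [
            permutation_importance(model, X, y, CASE, rng)[0] for _ in range(40)
        ]
        assert 1.0 - compute_auc(model.predict_scores(X), y, CASE) == 0.0
        assert np.median(vals) == pytest.approx(0.5, abs=0.15)


class TestGridSearch:
    def test_single_point_grid_returns_it(self, rng):
        X = rng.normal(size=(20, 5))
        y = _labels(10, 10)
        grid = RFGrid((2,), (20,), (4,), (2,))
        point = grid_search(X, y, grid, 2, rng, CASE)
        assert point == {
            "features_per_split": 2, "n_trees": 20, "max_depth": 4, "min_leaf": 2,
        }

    def test_matches_brute_force_enumeration(self):
        """Selection equals manual evaluation of every grid point with the
        same folds and fold seeds."""
        data_rng = np.random.default_rng(7)
        X = data_rng.normal(size=(24, 6))
        X[:, 0] += np.r_[np.ones(12), -np.ones(12)]
        y = _labels(12, 12)
        grid = RFGrid((2, 4), (15,), (None,), (1, 2))

        chosen = grid_search(X, y, grid, 2, np.random.default_rng(42), CASE)

        # replay the RNG consumption: one fold-shuffle seed, then fold seeds
        replay = np.random.default_rng(42)
        from sklearn.model_selection import StratifiedKFold

        splitter = StratifiedKFold(
            n_splits=2, shuffle=True, random_state=int(replay.integers(2**31))
        )
        folds = list(splitter.split(X, y))
        fold_seeds = replay.integers(2**31, size=2)
        best = None
        for point in grid.points():
            aucs = []
            for (tr, va), seed in zip(folds, fold_seeds):
                model = SklearnForest(CASE).fit(X[tr], y[tr], point, int(seed))
                aucs.append(compute_auc(model.predict_scores(X[va]), y[va], CASE))
            mean = float(np.mean(aucs))
            if best is None or mean > best[0]:
                best = (mean, point)
        assert chosen == best[1]

    def test_dominant_point_wins_on_separable_data(self, rng):
        X = rng.normal(size=(30, 4))
        X[:15, 0] += 6.0
        y = _labels(15, 15)
        grid = RFGrid((1, 4), (25,), (None,), (1,))
        point = grid_search(X, y, grid, 2, rng, CASE)
        assert point["features_per_split"] in (1, 4)  # both can separate; sanity
        assert point["n_trees"] == 25


def _separable_dataset(seed=0):
    spec = SyntheticSpec(
        n_case=16,
        n_control=20,
        n_features=6,
        effects=(PlantedEffect("signal", 3.0, cv=0.3),),
        seed=seed,
    )
    table, metadata = generate_feature_table(spec)
    return preprocess(table)["scaled"], metadata["group"]


_TINY_GRID = RFGrid((2,), (30,), (None,), (1,))


class TestRunValidation:
    def test_degenerate_single_iteration_summaries(self):
        table, groups = _separable_dataset(1)
        config = RFConfig(n_iterations=1, n_bootstrap=1, grid=_TINY_GRID, seed=5)
        result = run_validation(table, groups, CASE, config)
        real_auc = result.iterations.loc[
            result.iterations["arm"] == "real", "test_auc"
        ].iloc[0]
        row = result.auc_summary.set_index("arm").loc["real"]
        assert row["median_auc"] == real_auc
        assert row["ci_low"] == real_auc and row["ci_high"] == real_auc

    def test_separable_signal_beats_scrambled_arm_and_ranks_first(self):
        table, groups = _separable_dataset(2)
        config = RFConfig(n_iterations=12, n_bootstrap=300, grid=_TINY_GRID, seed=3)
        result = run_validation(table, groups, CASE, config)
        summary = result.auc_summary.set_index("arm")
        assert summary.loc["real", "median_auc"] > summary.loc["scrambled", "ci_high"]
        assert result.ranking[0] == "signal"
        imp = result.importance.set_index(["feature", "arm"])
        assert bool(imp.loc[("signal", "real"), "significant"])

    def test_seed_determinism(self):
        table, groups = _separable_dataset(3)
        config = RFConfig(n_iterations=3, n_bootstrap=50, grid=_TINY_GRID, seed=11)
        r1 = run_validation(table, groups, CASE, config)
        r2 = run_validation(table, groups, CASE, config)
        pd.testing.assert_frame_equal(r1.iterations, r2.iterations)
        pd.testing.assert_frame_equal(r1.importance, r2.importance)
        for arm in ("real", "scrambled"):
            pd.testing.assert_frame_equal(
                r1.permuted_one_minus_auc[arm], r2.permuted_one_minus_auc[arm]
            )

    def test_null_data_calibration_both_arms(self):
        """Effect-free data: both arms are unbiased around AUC 0.5.

        On a single small dataset the repeated splits converge to that
        dataset's conditional AUC, which scatters around 0.5, so
        calibration is checked in aggregate over several generated
        datasets: the across-dataset mean of median AUCs sits near 0.5
        for both arms and significance calls are at most sporadic."""
        medians = {"real": [], "scrambled": []}
        covered = {"real": 0, "scrambled": 0}
        n_calls = 0
        n_datasets = 6
        for seed in range(n_datasets):
            spec = SyntheticSpec(n_case=20, n_control=25, n_features=30, seed=seed)
            table, metadata = generate_feature_table(spec)
            scaled = preprocess(table)["scaled"]
            config = RFConfig(
                n_iterations=15, n_bootstrap=300,
                grid=RFGrid((5,), (40,), (None,), (1,)), seed=100 + seed,
            )
            result = run_validation(scaled, metadata["group"], CASE, config)
            for _, row in result.auc_summary.iterrows():
                medians[row["arm"]].append(row["median_auc"])
                covered[row["arm"]] += row["ci_low"] <= 0.5 <= row["ci_high"]
            n_calls += int(result.importance["significant"].sum())
        for arm in ("real", "scrambled"):
            assert abs(np.mean(medians[arm]) - 0.5) < 0.08, (arm, medians[arm])
            assert covered[arm] >= n_datasets // 2, (arm, medians[arm])
        # 30 features x 2 arms x 6 datasets = 360 possible calls
        assert n_calls <= 0.02 * 360

    def test_summary_invariants(self):
        table, groups = _separable_dataset(4)
        config = RFConfig(n_iterations=4, n_bootstrap=100, grid=_TINY_GRID, seed=2)
        result = run_validation(table, groups, CASE, config)
        # CI lower <= median <= CI upper everywhere
        for frame, col in (
            (result.auc_summary, "median_auc"),
            (result.baseline, "median_one_minus_auc"),
            (result.importance, "median_one_minus_auc"),
        ):
            assert (frame["ci_low"] <= frame[col]).all()
            assert (frame[col] <= frame["ci_high"]).all()
        # ranking is a permutation of all features
        assert sorted(result.ranking) == sorted(table.metabolite_names)
        # AUCs and permuted 1-AUC complements live in [0, 1]
        assert result.iterations["test_auc"].between(0, 1).all()
        for arm_frame in result.permuted_one_minus_auc.values():
            assert ((arm_frame >= 0) & (arm_frame <= 1)).all().all()
        # baseline is exactly 1 - AUC of the unpermuted model
        for arm in ("real", "scrambled"):
            aucs = result.iterations.loc[
                result.iterations["arm"] == arm, "test_auc"
            ].to_numpy()
            base = result.baseline.set_index("arm").loc[arm, "median_one_minus_auc"]
            assert base == pytest.approx(float(np.median(1.0 - aucs)), abs=1e-12)

    def test_config_validation_errors(self):
        table, groups = _separable_dataset(5)
        with pytest.raises(RFValidationError, match="train_fraction"):
            run_validation(table, groups, CASE, RFConfig(train_fraction=1.5))
        with pytest.raises(RFValidationError, match="classes"):
            run_validation(table, np.array(["a"] * table.n_samples), "a", RFConfig())
        with pytest.raises(RFValidationError, match="positive label"):
            run_validation(table, groups, "missing", RFConfig(grid=_TINY_GRID))


def test_default_grid_spans_the_field_heuristics():
    grid = default_grid(300)
    assert grid.features_per_split == (18, 100)
    assert len(grid.points()) == 16
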