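"""Random Forest validation scaffold with a Y-scrambled null arm.

The procedure evaluates how well a forest separates cases from controls
while guarding against overfitting and selection optimism:

1. Repeat ``n_iterations`` times: draw a stratified 70/30 train/test
   split; on the training data run a 2-fold grid search over the four
   forest hyperparameters (features per split, number of trees, maximum
   depth, minimum leaf size); refit the winning configuration on the
   full training set and record the rank-based test AUC.
2. Feature importance: permute each feature once in the test data,
   re-score the fitted model, and record the resulting 1-AUC.  A feature
   whose permutation hurts the model has a high 1-AUC.
3. A Y-scrambled arm repeats the entire procedure per iteration with the
   training labels randomly permuted (test labels intact), giving a
   no-signal reference whose AUC should sit near 0.5.
4. Medians over iterations are summarised with percentile bootstrap 95%
   confidence intervals; a feature is called significant when its 1-AUC
   CI does not overlap the baseline (unpermuted) 1-AUC CI of its arm.

The forest learner is consumed behind a two-method contract
(``fit(X, y, params, seed)`` / ``predict_scores(X)``) so any conforming
implementation can be plugged in; the default wraps scikit-learn's
``RandomForestClassifier``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .tables import FeatureTable

REAL = "real"
SCRAMBLED = "scrambled"

HYPERPARAMS = ("features_per_split", "n_trees", "max_depth", "min_leaf")


class RFValidationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RFGrid:
    """Hyperparameter grid over the four tuned forest settings.

    ``max_depth`` entries may be ``None`` (unlimited).  Grid points are
    enumerated in axis-product order with the listed value order.
    """

    features_per_split: tuple[int, ...]
    n_trees: tuple[int, ...] = (50, 100)
    max_depth: tuple[int | None, ...] = (None, 8)
    min_leaf: tuple[int, ...] = (1, 5)

    def validate(self) -> None:
        for axis in HYPERPARAMS:
            values = getattr(self, _AXIS_FIELDS[axis])
            if len(values) == 0:
                raise RFValidationError(f"grid axis {axis!r} is empty")
            for v in values:
                if v is None and axis == "max_depth":
                    continue
                if not (isinstance(v, (int, np.integer)) and v > 0):
                    raise RFValidationError(
                        f"grid axis {axis!r} has non-positive value {v!r}"
                    )

    def points(self) -> list[dict]:
        return [
            dict(zip(HYPERPARAMS, combo))
            for combo in itertools.product(
                self.features_per_split, self.n_trees, self.max_depth, self.min_leaf
            )
        ]


_AXIS_FIELDS = {
    "features_per_split": "features_per_split",
    "n_trees": "n_trees",
    "max_depth": "max_depth",
    "min_leaf": "min_leaf",
}


def default_grid(n_features: int) -> RFGrid:
    """Default grid for an ``n_features``-wide table.

    Features per split spans the two common forest heuristics (square
    root and one third of the feature count).  Tree counts are kept
    modest: with ~10^2 training samples the forest AUC plateaus well
    below 100 trees, and the grid is refit thousands of times across
    iterations and folds.
    """
    root = max(1, math.isqrt(n_features - 1) + 1 if n_features > 1 else 1)
    third = max(1, -(-n_features // 3))
    fps = (root,) if root == third else (root, third)
    return RFGrid(features_per_split=fps)


@dataclass(frozen=True)
class RFConfig:
    """Configuration of the repeated nested-CV validation."""

    train_fraction: float = 0.7
    inner_folds: int = 2
    n_iterations: int = 100
    n_bootstrap: int = 1000
    grid: RFGrid | None = None  # None: default_grid(n_features) at run time
    seed: int = 0

    def validate(self, class_counts: Sequence[int] | None = None) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise RFValidationError("train_fraction must be in (0, 1)")
        if self.inner_folds < 2:
            raise RFValidationError("inner_folds must be >= 2")
        if self.n_iterations < 1 or self.n_bootstrap < 1:
            raise RFValidationError("n_iterations and n_bootstrap must be >= 1")
        if self.grid is not None:
            self.grid.validate()
        if class_counts is not None:
            for count in class_counts:
                n_train = int(np.floor(self.train_fraction * count + 0.5))
                if n_train < self.inner_folds:
                    raise RFValidationError(
                        f"train_fraction {self.train_fraction} leaves a class with "
                        f"{n_train} training samples, fewer than inner_folds="
                        f"{self.inner_folds}"
                    )


class SklearnForest:
    """Default forest learner: scikit-learn RandomForestClassifier.

    Scores are predicted probabilities of the positive class.
    """

    def __init__(self, positive_label):
        self.positive_label = positive_label
        self._model: RandomForestClassifier | None = None
        self._pos_col: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, params: Mapping, seed: int):
        model = RandomForestClassifier(
            n_estimators=int(params["n_trees"]),
            max_features=int(params["features_per_split"]),
            max_depth=None if params["max_depth"] is None else int(params["max_depth"]),
            min_samples_leaf=int(params["min_leaf"]),
            random_state=int(seed),
            n_jobs=1,
        )
        model.fit(X, y)
        self._model = model
        self._pos_col = list(model.classes_).index(self.positive_label)
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RFValidationError("predict_scores called before fit")
        return self._model.predict_proba(X)[:, self._pos_col]


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test split by index.

    Per class, ``round(train_fraction * class size)`` samples go to
    training; a fraction that would empty either partition for some
    class is an error.
    """
    labels = np.asarray(labels)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise RFValidationError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(np.floor(train_fraction * idx.size + 0.5))
        if n_train < 1 or n_train >= idx.size:
            raise RFValidationError(
                f"train_fraction {train_fraction} empties a partition for class "
                f"{cls!r} (size {idx.size})"
            )
        shuffled = rng.permutation(idx)
        train.append(shuffled[:n_train])
        test.append(shuffled[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def compute_auc(scores: np.ndarray, labels: np.ndarray, positive_label) -> float:
    """Rank-based (Mann-Whitney) AUC: the fraction of (positive,
    negative) pairs where the positive scores higher, ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise RFValidationError("AUC undefined: test labels contain a single class")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def scramble_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the label multiset (class counts kept)."""
    labels = np.asarray(labels)
    if labels.size < 2:
        raise RFValidationError("need at least 2 labels to scramble")
    return labels[rng.permutation(labels.size)]


def bootstrap_ci(
    values,
    n_bootstrap: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the median.

    The interval is widened, if necessary, to contain the sample median
    so that summaries always satisfy lower <= median <= upper.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise RFValidationError("bootstrap_ci needs a nonempty sample")
    rng = rng or np.random.default_rng()
    idx = rng.integers(0, values.size, size=(n_bootstrap, values.size))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(medians, [100 * alpha, 100 * (1 - alpha)])
    med = float(np.median(values))
    return min(float(lo), med), max(float(hi), med)


def _tie_break_key(point: dict, order: int):
    depth = point["max_depth"]
    return (
        point["n_trees"],
        math.inf if depth is None else depth,
        -point["min_leaf"],
        point["features_per_split"],
        order,
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: RFGrid,
    inner_folds: int,
    rng: np.random.Generator,
    positive_label,
    model_factory=SklearnForest,
) -> dict:
    """Inner stratified k-fold search maximising mean validation AUC.

    Ties are broken toward the more parsimonious model: fewer trees,
    shallower depth, larger leaves, fewer candidate features per split,
    then first in grid order.  A degenerate (single-class) fold is
    refolded with a fresh shuffle, at most 10 times.
    """
    grid.validate()
    y = np.asarray(y)
    folds = None
    for _ in range(10):
        splitter = StratifiedKFold(
            n_splits=inner_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        candidate = list(splitter.split(X, y))
        if all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2
            for tr, va in candidate
        ):
            folds = candidate
            break
    if folds is None:
        raise RFValidationError("could not build two-class inner folds in 10 attempts")
    fold_seeds = rng.integers(2**31, size=inner_folds)
    best_key, best_auc, best_point = None, -np.inf, None
    for order, point in enumerate(grid.points()):
        aucs = []
        for (tr, va), seed in zip(folds, fold_seeds):
            model = model_factory(positive_label).fit(X[tr], y[tr], point, int(seed))
            aucs.append(compute_auc(model.predict_scores(X[va]), y[va], positive_label))
        mean_auc = float(np.mean(aucs))
        key = _tie_break_key(point, order)
        if mean_auc > best_auc or (mean_auc == best_auc and key < best_key):
            best_auc, best_key, best_point = mean_auc, key, point
    return dict(best_point)


def permutation_importance(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    positive_label,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature 1-AUC after a single within-test-set permutation.

    Each feature's column is permuted independently (one draw per
    feature, all other columns intact), the model re-scored, and
    1 - AUC recorded.  All permuted copies are scored in one batched
    prediction call.
    """
    n, m = X_test.shape
    stacked = np.repeat(X_test[None, :, :], m, axis=0)
    for j in range(m):
        stacked[j, :, j] = X_test[rng.permutation(n), j]
    scores = model.predict_scores(stacked.reshape(m * n, m)).reshape(m, n)
    return np.array(
        [1.0 - compute_auc(scores[j], y_test, positive_label) for j in range(m)]
    )


@dataclass
class RFValidationResult:
    """Everything the repeated validation produced.

    ``iterations``: one row per iteration x arm with the chosen
    hyperparameters and test AUC.  ``permuted_one_minus_auc``: per-arm
    (iterations x features) frames of permuted 1-AUC values.
    ``auc_summary`` / ``baseline``: per-arm medians with bootstrap CIs.
    ``importance``: per-feature per-arm median 1-AUC, CI, significance
    call (CI disjoint from the arm's baseline CI) and real-arm rank
    (1 = most important).
    """

    iterations: pd.DataFrame
    permuted_one_minus_auc: dict[str, pd.DataFrame]
    auc_summary: pd.DataFrame
    baseline: pd.DataFrame
    importance: pd.DataFrame
    config: RFConfig = field(repr=False)

    @property
    def ranking(self) -> list[str]:
        real = self.importance[self.importance["arm"] == REAL]
        return real.sort_values("rank")["feature"].tolist()


def run_validation(
    table: FeatureTable,
    labels,
    positive_label,
    config: RFConfig | None = None,
    model_factory=SklearnForest,
) -> RFValidationResult:
    """Run both arms of the repeated nested-CV validation.

    ``labels`` is a per-sample two-class vector aligned with the table
    (a pandas Series indexed by sample id or a plain array).
    Reproducible from ``config.seed`` alone: a master seed sequence
    spawns independent per-iteration, per-arm streams.
    """
    config = config or RFConfig()
    if isinstance(labels, pd.Series):
        labels = labels.reindex(table.sample_ids).to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != table.n_samples:
        raise RFValidationError("labels are not aligned with the table")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise RFValidationError(f"need exactly 2 classes, got {list(classes)}")
    if positive_label not in classes:
        raise RFValidationError(f"positive label {positive_label!r} not in labels")
    config.validate(class_counts=counts)
    grid = config.grid or default_grid(table.n_features)
    grid.validate()

    X = table.values()
    feature_names = list(table.metabolite_names)
    master = np.random.SeedSequence(config.seed)
    iter_seeds = master.spawn(config.n_iterations + 1)
    boot_rng = np.random.default_rng(iter_seeds[-1])

    rows = []
    permuted = {REAL: [], SCRAMBLED: []}
    for i in range(config.n_iterations):
        try:
            split_ss, real_ss, scr_ss = iter_seeds[i].spawn(3)
            train, test = stratified_split(
                labels, config.train_fraction, np.random.default_rng(split_ss)
            )
            y_train, y_test = labels[train], labels[test]
            for arm, arm_ss in ((REAL, real_ss), (SCRAMBLED, scr_ss)):
                arm_rng = np.random.default_rng(arm_ss)
                y_fit = (
                    y_train if arm == REAL else scramble_labels(y_train, arm_rng)
                )
                point = grid_search(
                    X[train],
                    y_fit,
                    grid,
                    config.inner_folds,
                    arm_rng,
                    positive_label,
                    model_factory,
                )
                model = model_factory(positive_label).fit(
                    X[train], y_fit, point, int(arm_rng.integers(2**31))
                )
                auc = compute_auc(model.predict_scores(X[test]), y_test, positive_label)
                one_minus = permutation_importance(
                    model, X[test], y_test, positive_label, arm_rng
                )
                rows.append({"iteration": i, "arm": arm, **point, "test_auc": auc})
                permuted[arm].append(one_minus)
        except RFValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with iteration index
            raise RFValidationError(f"iteration {i} failed: {exc}") from exc

    iterations = pd.DataFrame(rows)
    permuted_frames = {
        arm: pd.DataFrame(np.vstack(vals), columns=feature_names)
        for arm, vals in permuted.items()
    }

    auc_rows, base_rows, imp_rows = [], [], []
    baseline_ci: dict[str, tuple[float, float]] = {}
    for arm in (REAL, SCRAMBLED):
        aucs = iterations.loc[iterations["arm"] == arm, "test_auc"].to_numpy()
        lo, hi = bootstrap_ci(aucs, config.n_bootstrap, rng=boot_rng)
        auc_rows.append(
            {"arm": arm, "median_auc": float(np.median(aucs)), "ci_low": lo, "ci_high": hi}
        )
        base = 1.0 - aucs
        blo, bhi = bootstrap_ci(base, config.n_bootstrap, rng=boot_rng)
        base_rows.append(
            {
                "arm": arm,
                "median_one_minus_auc": float(np.median(base)),
                "ci_low": blo,
                "ci_high": bhi,
            }
        )
        baseline_ci[arm] = (blo, bhi)
        frame = permuted_frames[arm]
        for name in feature_names:
            vals = frame[name].to_numpy()
            flo, fhi = bootstrap_ci(vals, config.n_bootstrap, rng=boot_rng)
            imp_rows.append(
                {
                    "feature": name,
                    "arm": arm,
                    "median_one_minus_auc": float(np.median(vals)),
                    "ci_low": flo,
                    "ci_high": fhi,
                    "significant": bool(
                        flo > baseline_ci[arm][1] or fhi < baseline_ci[arm][0]
                    ),
                }
            )
    importance = pd.DataFrame(imp_rows)
    real_mask = importance["arm"] == REAL
    order = (
        importance.loc[real_mask]
        .sort_values("median_one_minus_auc", ascending=False, kind="mergesort")
        .index
    )
    importance["rank"] = pd.NA
    importance.loc[order, "rank"] = np.arange(1, real_mask.sum() + 1)
    importance["rank"] = importance["rank"].astype("Int64")

    return RFValidationResult(
        iterations=iterations,
        permuted_one_minus_auc=permuted_frames,
        auc_summary=pd.DataFrame(auc_rows),
        baseline=pd.DataFrame(base_rows),
        importance=importance,
        config=config,
    )
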