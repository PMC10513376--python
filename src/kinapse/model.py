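"""Balanced random forest, experiment-grouped validation, and metrics.

Each tree of the forest trains on a balanced bootstrap: the minority
class count m is drawn with replacement from every class, so per-tree
class counts are exactly equal regardless of the dataset's imbalance.
Predicted probabilities are tree-vote fractions.

Data splitting is always by experiment: an experiment's samples never
appear on both sides of a train/validation or train/test split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion, f1_score
from sklearn.tree import DecisionTreeClassifier

from kinapse.features import FeatureMatrix, WindowSpec, assemble_feature_matrix
from kinapse.selection import CVCurve, MRMRResult, choose_feature_count, mrmr_select
from kinapse.track_io import Dataset, map_labels

logger = logging.getLogger(__name__)


class LeakageError(ValueError):
    """Train and evaluation share an experiment."""


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    random_seed: int = 0
    class_scheme: str = "binary"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.class_scheme not in ("binary", "three_class"):
            raise ValueError(f"unknown class scheme {self.class_scheme!r}")


@dataclass(frozen=True)
class GroupedCVSpec:
    n_folds: int = 3
    group_key: str = "experiment_id"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")


def balanced_bootstrap(y, rng) -> np.ndarray:
    """Indices of a class-balanced bootstrap sample of y.

    Draws m indices with replacement from every class, where m is the
    minority class count; the result has exactly equal class counts.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balanced bootstrap needs >= 2 classes present")
    m = int(counts.min())
    picks = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        picks.append(rng.choice(idx, size=m, replace=True))
    return np.concatenate(picks)


class BalancedRandomForest:
    """Tree ensemble where every tree sees a balanced bootstrap sample.

    Thin, auditable wrapper around scikit-learn decision trees; the
    per-tree bootstrap indices are retained in ``bootstrap_indices_`` so
    the balancing can be inspected after fitting.
    """

    def __init__(self, config: ForestConfig):
        self.config = config
        self.trees_: list[DecisionTreeClassifier] = []
        self.bootstrap_indices_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X, y) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        self.classes_ = classes
        rng = np.random.default_rng(self.config.random_seed)
        self.trees_ = []
        self.bootstrap_indices_ = []
        for _ in range(self.config.n_trees):
            idx = balanced_bootstrap(y, rng)
            tree = DecisionTreeClassifier(
                max_features=self.config.max_features,
                max_depth=self.config.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.bootstrap_indices_.append(idx)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probability = fraction of trees voting for the class."""
        X = np.asarray(X, dtype=np.float64)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        pos = {c: j for j, c in enumerate(self.classes_)}
        for tree in self.trees_:
            pred = tree.predict(X)
            for j, c in enumerate(tree.classes_):
                votes[pred == c, pos[c]] += 1
        return votes / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def feature_importances_(self) -> np.ndarray:
        imps = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        total = imps.sum()
        return imps / total if total > 0 else imps


def fit_forest(X, y, config: ForestConfig | None = None) -> BalancedRandomForest:
    """Fit a balanced random forest on a plain feature array."""
    return BalancedRandomForest(config or ForestConfig()).fit(X, y)


@dataclass
class ForestModel:
    """A trained forest plus the ordered feature subset it expects."""

    forest: BalancedRandomForest
    selected_features: list[str]
    classes: list
    config: ForestConfig

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.data
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features if f not in X.columns]
            if missing:
                raise KeyError(f"missing feature column(s): {missing}")
            return X[self.selected_features].to_numpy(dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.selected_features):
            raise ValueError(
                f"expected {len(self.selected_features)} feature columns, got {X.shape[1]}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        return self.forest.predict(self._matrix(X))

    def predict_proba(self, X) -> pd.DataFrame:
        proba = self.forest.predict_proba(self._matrix(X))
        return pd.DataFrame(proba, columns=list(self.forest.classes_))

    def flag_uncertain(self, X, threshold: float) -> np.ndarray:
        """Boolean mask of rows whose top vote fraction is below threshold."""
        proba = self.forest.predict_proba(self._matrix(X))
        return proba.max(axis=1) < threshold

    def sidecar(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "classes": [str(c) for c in self.classes],
            "config": asdict(self.config),
        }


def predict(model: ForestModel, X) -> tuple[np.ndarray, pd.DataFrame]:
    """Labels and per-class vote-fraction probabilities."""
    return model.predict(X), model.predict_proba(X)


@dataclass
class EvalReport:
    """Paper-style evaluation: accuracy, macro F1, G-mean, confusion matrix."""

    accuracy: float
    f1_macro: float
    gmean: float
    per_class_recall: dict
    confusion: pd.DataFrame          # row-normalized by true class
    confusion_counts: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1_macro": self.f1_macro,
            "gmean": self.gmean,
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
        }


def evaluate(y_true, y_pred) -> EvalReport:
    """Accuracy, macro F1, geometric mean of per-class recalls, confusion."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate empty predictions")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    labels = sorted(set(y_true) | set(y_pred))
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, np.nan)

    true_labels = [lab for lab, s in zip(labels, row_sums.ravel()) if s > 0]
    recalls = {
        lab: float(counts[i, i] / row_sums[i, 0])
        for i, lab in enumerate(labels)
        if row_sums[i, 0] > 0
    }
    rec = np.array([recalls[lab] for lab in true_labels])
    gmean = float(np.prod(rec) ** (1.0 / len(rec)))

    return EvalReport(
        accuracy=float(np.mean(y_true == y_pred)),
        f1_macro=float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        gmean=gmean,
        per_class_recall=recalls,
        confusion=pd.DataFrame(norm, index=labels, columns=labels),
        confusion_counts=pd.DataFrame(counts, index=labels, columns=labels),
    )


def grouped_kfold(groups, spec: GroupedCVSpec | int = 3, seed: int = 0):
    """Partition samples into folds by group (experiment).

    Groups are shuffled with the seed then dealt round-robin to folds, so
    fold sizes balance by group count.  Returns ``[(train_idx, val_idx),
    ...]``; every group's samples land in exactly one validation fold.
    """
    if isinstance(spec, int):
        spec = GroupedCVSpec(n_folds=spec)
    groups = np.asarray(groups)
    uniq = np.array(sorted(set(groups)))
    if len(uniq) < spec.n_folds:
        raise ValueError(
            f"{len(uniq)} group(s) but {spec.n_folds} folds requested"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of_group = {uniq[g]: i % spec.n_folds for i, g in enumerate(order)}
    folds = []
    sample_fold = np.array([fold_of_group[g] for g in groups])
    for f in range(spec.n_folds):
        va = np.flatnonzero(sample_fold == f)
        tr = np.flatnonzero(sample_fold != f)
        folds.append((tr, va))
    return folds


@dataclass
class RunResult:
    model: ForestModel
    curve: CVCurve
    report: EvalReport
    n_features: int
    selection: MRMRResult
    train_matrix: FeatureMatrix = field(repr=False, default=None)
    test_matrix: FeatureMatrix = field(repr=False, default=None)


def run_experiment(
    train: Dataset,
    test: Dataset,
    scheme: str = "binary",
    forest_config: ForestConfig | None = None,
    cv: GroupedCVSpec | None = None,
    window: WindowSpec | None = None,
    coast_threshold: float | None = None,
    grid_max: int = 21,
    grid_start: int = 3,
    grid_step: int = 2,
    stop_delta: float = 0.005,
    stop_horizon: int = 5,
    mrmr_scheme: str = "quotient",
    cv_forest_config: ForestConfig | None = None,
    seed: int = 0,
) -> RunResult:
    """Full pipeline: features -> CV feature-count search -> final mRMR -> fit -> test.

    Train and test experiments must be disjoint.  ``cv_forest_config``
    optionally uses a lighter forest during the feature-count search than
    for the final fit.
    """
    from kinapse.features import COAST_THRESHOLD

    overlap = set(train.experiment_ids) & set(test.experiment_ids)
    if overlap:
        raise LeakageError(f"experiments in both train and test: {sorted(overlap)}")

    forest_config = forest_config or ForestConfig(class_scheme=scheme, random_seed=seed)
    cv = cv or GroupedCVSpec()
    coast = COAST_THRESHOLD if coast_threshold is None else coast_threshold

    fm_train = assemble_feature_matrix(
        map_labels(train, scheme), spec=window, coast_threshold=coast, require_labels=True
    )
    fm_test = assemble_feature_matrix(
        map_labels(test, scheme), spec=window, coast_threshold=coast, require_labels=True
    )

    n_star, curve = choose_feature_count(
        fm_train,
        grid_max=grid_max,
        cv=cv,
        forest_config=cv_forest_config or forest_config,
        grid_start=grid_start,
        grid_step=grid_step,
        delta=stop_delta,
        horizon=stop_horizon,
        mrmr_scheme=mrmr_scheme,
        seed=seed,
    )
    logger.info("selected feature count n* = %d", n_star)

    selection = mrmr_select(fm_train, n=n_star, scheme=mrmr_scheme)
    cols = selection.ordered_features
    forest = fit_forest(
        fm_train.data[cols].to_numpy(dtype=np.float64), fm_train.y, forest_config
    )
    model = ForestModel(
        forest=forest,
        selected_features=cols,
        classes=list(forest.classes_),
        config=forest_config,
    )
    y_pred = model.predict(fm_test)
    report = evaluate(fm_test.y, y_pred)
    logger.info(
        "test accuracy %.3f, F1 %.3f, G-mean %.3f",
        report.accuracy, report.f1_macro, report.gmean,
    )
    return RunResult(
        model=model,
        curve=curve,
        report=report,
        n_features=n_star,
        selection=selection,
        train_matrix=fm_train,
        test_matrix=fm_test,
    )


def save_run(result: RunResult, out_dir, seed: int | None = None) -> None:
    """Persist metrics, confusion matrix, CV curve, selection and model sidecar."""
    import os

    import joblib

    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame([result.report.to_dict() | {"n_features": result.n_features}]).to_csv(
        os.path.join(out_dir, "metrics.csv"), index=False
    )
    result.report.confusion.to_csv(os.path.join(out_dir, "confusion_matrix.csv"))
    result.report.confusion_counts.to_csv(os.path.join(out_dir, "confusion_counts.csv"))
    result.curve.to_frame().to_csv(os.path.join(out_dir, "cv_curve.csv"), index=False)
    result.selection.to_frame().to_csv(os.path.join(out_dir, "selected_features.csv"), index=False)
    sidecar = result.model.sidecar()
    if seed is not None:
        sidecar["seed"] = seed
    with open(os.path.join(out_dir, "model_sidecar.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    joblib.dump(result.model, os.path.join(out_dir, "model.joblib"))
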