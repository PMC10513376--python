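"""mRMR feature ranking and the cross-validated choice of feature count.

Relevance is the one-way ANOVA F-statistic of a feature across classes;
redundancy is the mean absolute Pearson correlation with the features
already selected.  Selection is greedy: the first pick maximizes
relevance, every later pick maximizes relevance/redundancy (quotient
scheme, the default) or relevance - redundancy (difference scheme).

The number of features to keep is chosen on a grid (3, 5, 7, ...) inside
grouped 3-fold cross-validation: the smallest grid point whose mean CV
accuracy is approached within 0.5% (absolute) by each of the next five
grid points wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kinapse.features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class MRMRResult:
    """Greedy selection order with per-step diagnostics."""

    ordered_features: list[str]
    relevance: dict[str, float]
    score_at_selection: list[float]

    def __len__(self) -> int:
        return len(self.ordered_features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ordered_features) + 1),
                "feature": self.ordered_features,
                "relevance_F": [self.relevance[f] for f in self.ordered_features],
                "selection_score": self.score_at_selection,
            }
        )


@dataclass
class CVCurve:
    """Mean/min/max CV accuracy per candidate feature count."""

    grid: np.ndarray
    mean_acc: np.ndarray
    min_acc: np.ndarray
    max_acc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": self.grid,
                "mean_accuracy": self.mean_acc,
                "min_accuracy": self.min_acc,
                "max_accuracy": self.max_acc,
            }
        )


def _as_xy(X, y, feature_names=None):
    if isinstance(X, FeatureMatrix):
        names = list(X.feature_names)
        arr = X.X
        if y is None:
            y = X.y
    else:
        arr = np.asarray(X, dtype=np.float64)
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(arr.shape[1])
        ]
    y = np.asarray(y)
    if arr.shape[0] != len(y):
        raise ValueError(f"X has {arr.shape[0]} rows but y has {len(y)}")
    return arr, y, names


def f_relevance(X, y=None, feature_names=None) -> np.ndarray:
    """One-way ANOVA F-statistic of each feature across the classes of y.

    Constant features get F = 0 (the 0/0 case is guarded); features with
    zero within-class variance but non-zero between-class variance get
    F = inf.
    """
    arr, y, _ = _as_xy(X, y, feature_names)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("f_relevance needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError(
            f"every class needs >= 2 samples; got counts {dict(zip(classes, counts))}"
        )
    n, p = arr.shape
    k = len(classes)
    grand = arr.mean(axis=0)
    ss_between = np.zeros(p)
    ss_within = np.zeros(p)
    for c, nc in zip(classes, counts):
        sub = arr[y == c]
        mu = sub.mean(axis=0)
        ss_between += nc * (mu - grand) ** 2
        ss_within += ((sub - mu) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    F = np.full(p, np.inf)
    nz = ms_within > 0
    F[nz] = ms_between[nz] / ms_within[nz]
    F[(~nz) & (ms_between <= 1e-300)] = 0.0  # constant feature: 0/0 -> 0
    return F


def mrmr_select(
    X,
    y=None,
    n: int = 3,
    feature_names=None,
    scheme: str = "quotient",
) -> MRMRResult:
    """Greedy mRMR selection of ``n`` features.

    Deterministic: ties on the selection score break lexicographically by
    feature name.  Pearson correlations involving a constant feature are
    treated as zero redundancy.
    """
    if scheme not in ("quotient", "difference"):
        raise ValueError(f"unknown mrmr scheme {scheme!r}")
    arr, y, names = _as_xy(X, y, feature_names)
    p = arr.shape[1]
    if not 1 <= n <= p:
        raise ValueError(f"n must be in [1, {p}], got {n}")

    F = f_relevance(arr, y)

    # z-scored columns make r(f, s) a single dot product per pair;
    # constant columns z-score to 0 => r = 0 (no redundancy signal)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    nz = sd > 0
    Z = np.zeros_like(arr)
    Z[:, nz] = (arr[:, nz] - mu[nz]) / sd[nz]
    n_rows = arr.shape[0]

    name_order = np.argsort(np.argsort(names, kind="stable"))  # rank of each name

    def _pick(scores: np.ndarray, candidates: np.ndarray) -> int:
        best = candidates[scores[candidates] == scores[candidates].max()]
        return int(best[np.argmin(name_order[best])])

    selected: list[int] = []
    scores_at: list[float] = []
    abs_r_sum = np.zeros(p)
    remaining = np.arange(p)

    first = _pick(F, remaining)
    selected.append(first)
    scores_at.append(float(F[first]))
    remaining = remaining[remaining != first]

    while len(selected) < n:
        abs_r_sum += np.abs(Z.T @ Z[:, selected[-1]]) / (n_rows - 1)
        redundancy = abs_r_sum / len(selected)
        if scheme == "quotient":
            with np.errstate(divide="ignore", invalid="ignore"):
                crit = np.where(redundancy > 0, F / redundancy, np.inf)
            crit = np.where((redundancy == 0) & (F == 0), 0.0, crit)
        else:
            crit = F - redundancy
        nxt = _pick(crit, remaining)
        selected.append(nxt)
        scores_at.append(float(crit[nxt]))
        remaining = remaining[remaining != nxt]

    ordered = [names[i] for i in selected]
    return MRMRResult(
        ordered_features=ordered,
        relevance={names[i]: float(F[i]) for i in selected},
        score_at_selection=scores_at,
    )


def stop_rule(
    grid, mean_acc, delta: float = 0.005, horizon: int = 5
) -> tuple[int, bool]:
    """Pick the feature count where the CV accuracy curve flattens.

    Returns ``(n_star, rule_fired)``: the smallest grid point after which
    each of the next ``horizon`` successive increments raises the mean
    accuracy by less than ``delta`` (per-increment reading; a gain equal
    to ``delta`` within float tolerance counts as flat).  When no point
    qualifies, falls back to the argmax of the curve with
    ``rule_fired = False``.
    """
    grid = np.asarray(grid)
    mean_acc = np.asarray(mean_acc, dtype=np.float64)
    if len(grid) != len(mean_acc):
        raise ValueError("grid and mean_acc lengths differ")
    for i in range(len(grid) - horizon):
        gains = np.diff(mean_acc[i : i + horizon + 1])
        if np.all(gains < delta + 1e-9):
            return int(grid[i]), True
    return int(grid[int(np.argmax(mean_acc))]), False


def choose_feature_count(
    fm_train: FeatureMatrix,
    grid_max: int = 21,
    cv=None,
    forest_config=None,
    grid_start: int = 3,
    grid_step: int = 2,
    delta: float = 0.005,
    horizon: int = 5,
    mrmr_scheme: str = "quotient",
    seed: int = 0,
) -> tuple[int, CVCurve]:
    """Grouped-CV search for the number of mRMR features to keep.

    For each fold, mRMR runs on the fold's training portion once at
    ``grid_max`` (greedy nesting makes every smaller count a prefix); a
    forest is then fit per grid point and scored on the held-out fold.
    """
    from kinapse.model import ForestConfig, GroupedCVSpec, fit_forest, grouped_kfold

    cv = cv or GroupedCVSpec()
    forest_config = forest_config or ForestConfig()
    if grid_max < grid_start + horizon * grid_step:
        raise ValueError(
            f"grid_max={grid_max} leaves no candidate with {horizon} increments ahead"
        )
    grid = np.arange(grid_start, grid_max + 1, grid_step)

    X = fm_train.X
    y = fm_train.y
    if y is None:
        raise ValueError("training matrix has no labels")
    groups = fm_train.groups
    names = list(fm_train.feature_names)
    name_idx = {f: i for i, f in enumerate(names)}

    folds = grouped_kfold(groups, cv, seed=seed)
    acc = np.zeros((len(folds), len(grid)))
    for fi, (tr_idx, va_idx) in enumerate(folds):
        sel = mrmr_select(
            X[tr_idx], y[tr_idx], n=int(grid[-1]), feature_names=names, scheme=mrmr_scheme
        )
        order = [name_idx[f] for f in sel.ordered_features]
        for gi, n_feat in enumerate(grid):
            cols = order[:n_feat]
            model = fit_forest(X[tr_idx][:, cols], y[tr_idx], forest_config)
            pred = model.predict(X[va_idx][:, cols])
            acc[fi, gi] = float(np.mean(pred == y[va_idx]))
        logger.info("fold %d: accuracies %s", fi, np.round(acc[fi], 4))

    curve = CVCurve(
        grid=grid,
        mean_acc=acc.mean(axis=0),
        min_acc=acc.min(axis=0),
        max_acc=acc.max(axis=0),
    )
    n_star, fired = stop_rule(grid, curve.mean_acc, delta=delta, horizon=horizon)
    if not fired:
        logger.warning(
            "stop rule never fired on grid up to %d; falling back to argmax (%d)",
            grid_max,
            n_star,
        )
    return n_star, curve
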