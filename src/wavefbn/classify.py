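"""Nested leave-one-out evaluation of a gradient-boosted classifier.

The outer loop leaves one subject out; within each outer training set the
features are standardised with training statistics only, the top-k edge
features are re-selected by tree importance (no test leakage), and a
random search over the boosted-tree hyperparameter grid is scored by inner
cross-validation.  Pooled held-out predictions yield the confusion counts,
accuracy/precision/recall/F1, the ROC curve and its AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .errors import InvalidArgumentError
from .features import FeatureMatrix, combine_blocks, select_important_features

__all__ = [
    "HyperparameterGrid",
    "ClassificationReport",
    "compute_metrics",
    "roc_auc",
    "nested_loocv",
    "threshold_grid_sweep",
]


@dataclass
class HyperparameterGrid:
    """Random-search space of the boosted-tree classifier."""

    n_estimators: tuple[int, ...] = (100, 200, 300)
    max_depth: tuple[int, ...] = (3, 5, 7, 10)
    learning_rate: tuple[float, ...] = (0.01, 0.1, 0.2)
    subsample: tuple[float, ...] = (0.8, 0.9, 1.0)
    colsample: tuple[float, ...] = (0.8, 0.9, 1.0)
    gamma_min_split_loss: tuple[float, ...] = (0.0, 0.1, 0.2)
    n_random_draws: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_estimators",
            "max_depth",
            "learning_rate",
            "subsample",
            "colsample",
            "gamma_min_split_loss",
        ):
            if not getattr(self, name):
                raise InvalidArgumentError(f"hyperparameter list {name} must be non-empty")
        if self.n_random_draws < 1:
            raise InvalidArgumentError("n_random_draws must be >= 1")

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "n_estimators": int(rng.choice(self.n_estimators)),
            "max_depth": int(rng.choice(self.max_depth)),
            "learning_rate": float(rng.choice(self.learning_rate)),
            "subsample": float(rng.choice(self.subsample)),
            "colsample_bytree": float(rng.choice(self.colsample)),
            "gamma": float(rng.choice(self.gamma_min_split_loss)),
        }


@dataclass
class ClassificationReport:
    """Pooled LOOCV outcome: confusion counts, metrics, ROC and per-fold choices."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_points: np.ndarray
    auc: float
    per_fold_hyperparameters: list[dict] = field(default_factory=list)
    scores: np.ndarray | None = None
    predictions: np.ndarray | None = None
    labels: np.ndarray | None = None
    subject_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "roc_points": np.asarray(self.roc_points).tolist(),
            "per_fold_hyperparameters": self.per_fold_hyperparameters,
            "scores": None if self.scores is None else np.asarray(self.scores).tolist(),
            "predictions": None
            if self.predictions is None
            else np.asarray(self.predictions).astype(int).tolist(),
            "labels": None if self.labels is None else np.asarray(self.labels).astype(int).tolist(),
            "subject_ids": self.subject_ids,
        }


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from confusion counts.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R).  A zero denominator yields 0 with a warning.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise InvalidArgumentError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise InvalidArgumentError("all confusion counts are zero")

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=2)
            return 0.0
        return num / den

    accuracy = (tp + tn) / total
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "F1")
    return accuracy, precision, recall, f1


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all score thresholds, and the AUC.

    The AUC equals the Mann-Whitney U statistic normalised by
    (positives x negatives), with tied scores counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise InvalidArgumentError("both classes must be present for ROC/AUC")
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(labels, scores))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _fit_predict_proba(params: dict, X: np.ndarray, y: np.ndarray, Xt: np.ndarray, seed: int):
    from xgboost import XGBClassifier

    clf = XGBClassifier(
        tree_method="exact", n_jobs=1, random_state=seed, eval_metric="logloss", **params
    )
    clf.fit(X, y)
    return clf.predict_proba(Xt)[:, 1]


def _inner_score(
    params: dict, X: np.ndarray, y: np.ndarray, inner_cv: str, n_folds: int, seed: int
) -> float:
    """Mean inner-CV accuracy of one hyperparameter draw; -inf if unusable."""
    if inner_cv == "loo":
        splits = list(LeaveOneOut().split(X))
    else:
        n_splits = min(n_folds, int(np.bincount(y).min()))
        if n_splits < 2:
            return -np.inf
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    accs = []
    for tr, te in splits:
        if np.unique(y[tr]).size < 2:
            warnings.warn("inner fold skipped: single-class training split", stacklevel=2)
            continue
        proba = _fit_predict_proba(params, X[tr], y[tr], X[te], seed)
        accs.append(np.mean((proba >= 0.5).astype(int) == y[te]))
    return float(np.mean(accs)) if accs else -np.inf


def nested_loocv(
    fm: FeatureMatrix,
    grid: HyperparameterGrid | None = None,
    k_features: int = 25,
    seed: int = 0,
    inner_cv: str = "kfold",
    inner_folds: int = 5,
    selection_mode: str = "fold",
) -> ClassificationReport:
    """Nested leave-one-out cross-validation with random hyperparameter search.

    ``selection_mode="fold"`` (default) re-fits the tree-importance feature
    selection inside each outer training fold; ``"global"`` selects once on
    the full data, which is optimistic and logged as such.  ``inner_cv``
    is "kfold" (stratified, ``inner_folds`` splits) or "loo" for an exact
    inner leave-one-out.  Fully deterministic given ``seed``.
    """
    grid = grid or HyperparameterGrid()
    if fm.n_subjects < 10:
        raise InvalidArgumentError("need at least 10 subjects for nested LOOCV")
    classes = np.unique(fm.labels)
    if classes.size != 2:
        raise InvalidArgumentError("nested LOOCV requires exactly 2 classes")
    if selection_mode not in ("fold", "global"):
        raise InvalidArgumentError(f"unknown selection_mode {selection_mode!r}")
    if selection_mode == "global":
        warnings.warn(
            "selection_mode='global' fits feature selection on all subjects; "
            "reported performance is optimistic",
            stacklevel=2,
        )
    y = (fm.labels == classes[-1]).astype(int)
    X = fm.values
    n = fm.n_subjects

    root = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(n)]
    global_sel = None
    if selection_mode == "global":
        global_sel, _ = select_important_features(fm, k=k_features, seed=seed)

    scores = np.empty(n)
    chosen: list[dict] = []
    for held_out in range(n):
        train = np.setdiff1d(np.arange(n), [held_out])
        fseed = fold_seeds[held_out]
        Xtr, Xte = _standardize(X[train], X[held_out : held_out + 1])
        ytr = y[train]
        if global_sel is None:
            sel, _ = select_important_features(Xtr, k=k_features, seed=fseed, labels=ytr)
        else:
            sel = global_sel
        Xtr_s, Xte_s = Xtr[:, sel], Xte[:, sel]
        rng = np.random.default_rng(fseed)
        draws = [grid.sample(rng) for _ in range(grid.n_random_draws)]
        inner_scores = [
            _inner_score(p, Xtr_s, ytr, inner_cv, inner_folds, fseed) for p in draws
        ]
        if np.all(np.isneginf(inner_scores)):
            raise InvalidArgumentError("all inner folds degenerate; cannot tune hyperparameters")
        best = draws[int(np.argmax(inner_scores))]
        chosen.append(best)
        scores[held_out] = _fit_predict_proba(best, Xtr_s, ytr, Xte_s, fseed)[0]

    predictions = (scores >= 0.5).astype(int)
    tp = int(np.sum((predictions == 1) & (y == 1)))
    fp = int(np.sum((predictions == 1) & (y == 0)))
    tn = int(np.sum((predictions == 0) & (y == 0)))
    fn = int(np.sum((predictions == 0) & (y == 1)))
    accuracy, precision, recall, f1 = compute_metrics(tp, fp, tn, fn)
    roc_points, auc = roc_auc(scores, y)
    return ClassificationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        roc_points=roc_points,
        auc=auc,
        per_fold_hyperparameters=chosen,
        scores=scores,
        predictions=predictions,
        labels=y,
        subject_ids=list(fm.subject_ids),
    )


def threshold_grid_sweep(
    ccc_blocks: dict[float, FeatureMatrix],
    nmi_blocks: dict[float, FeatureMatrix],
    t1_grid: list[float] | None = None,
    t2_grid: list[float] | None = None,
    grid: HyperparameterGrid | None = None,
    k_features: int = 25,
    seed: int = 0,
    **loocv_kwargs,
) -> tuple[np.ndarray, tuple[float, float], dict[tuple[float, float], ClassificationReport]]:
    """Accuracy surface of nested LOOCV over (t1, t2) threshold combinations.

    t1 indexes the CCC-network threshold, t2 the MI-network threshold.
    Returns the accuracy matrix (rows = t1), the argmax cell (ties broken
    lexicographically) and the per-cell reports.
    """
    t1_grid = list(t1_grid) if t1_grid is not None else sorted(ccc_blocks)
    t2_grid = list(t2_grid) if t2_grid is not None else sorted(nmi_blocks)
    surface = np.zeros((len(t1_grid), len(t2_grid)))
    reports: dict[tuple[float, float], ClassificationReport] = {}
    for i, t1 in enumerate(t1_grid):
        for j, t2 in enumerate(t2_grid):
            fm = combine_blocks(ccc_blocks[t1], nmi_blocks[t2])
            rep = nested_loocv(fm, grid=grid, k_features=k_features, seed=seed, **loocv_kwargs)
            surface[i, j] = rep.accuracy
            reports[(t1, t2)] = rep
    flat = int(np.argmax(surface))  # row-major argmax = lexicographically smallest tie
    bi, bj = divmod(flat, surface.shape[1])
    return surface, (t1_grid[bi], t2_grid[bj]), reports
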