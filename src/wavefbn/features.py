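"""Edge-feature extraction and tree-importance feature selection.

FBNs are symmetric, so a subject's feature vector is the strict upper
triangle of its weight matrix.  Feature blocks from the CCC-based and
MI-based networks at chosen thresholds are concatenated column-wise
(CCC-NMI combination), and a gradient-boosted tree ensemble ranks the
columns by total gain, keeping the top k (25 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InvalidArgumentError
from .network import Fbn

__all__ = [
    "FeatureMatrix",
    "upper_triangle_features",
    "unflatten_upper_triangle",
    "feature_names_for",
    "stack_cohort_features",
    "combine_blocks",
    "select_important_features",
]


@dataclass
class FeatureMatrix:
    """Subjects x edge-features matrix with labels and provenance-bearing names."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise InvalidArgumentError("feature values must be 2-D")
        if not np.isfinite(self.values).all():
            raise InvalidArgumentError("non-finite feature values")
        if self.values.shape[1] != len(self.feature_names):
            raise InvalidArgumentError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InvalidArgumentError("feature names must be unique")
        if self.values.shape[0] != self.labels.shape[0]:
            raise InvalidArgumentError("labels length mismatch")
        if not self.subject_ids:
            self.subject_ids = [f"S{i + 1}" for i in range(self.values.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def upper_triangle_features(fbn: Fbn | np.ndarray) -> np.ndarray:
    """Strict upper triangle (i < j) flattened row-major: n(n-1)/2 values."""
    w = fbn.weights if isinstance(fbn, Fbn) else np.asarray(fbn, dtype=float)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu]


def unflatten_upper_triangle(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`upper_triangle_features`: rebuild the symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise InvalidArgumentError(f"vector length {vec.size} != {n}({n}-1)/2")
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    return out + out.T


def feature_names_for(method: str, t: float, roi_labels: list[str]) -> list[str]:
    """Names encoding (method, threshold, roi_i, roi_j) for each edge feature."""
    n = len(roi_labels)
    return [
        f"{method}_t{t:g}_{roi_labels[i]}_{roi_labels[j]}"
        for i in range(n)
        for j in range(i + 1, n)
    ]


def stack_cohort_features(
    fbns: list[Fbn], labels: np.ndarray, subject_ids: list[str] | None = None
) -> FeatureMatrix:
    """One row per subject FBN, columns = strict upper-triangle edges."""
    if not fbns:
        raise InvalidArgumentError("empty FBN list")
    values = np.vstack([upper_triangle_features(f) for f in fbns])
    first = fbns[0]
    names = feature_names_for(first.method, first.threshold_t, first.roi_labels)
    ids = subject_ids or [f.subject_id or f"S{i + 1}" for i, f in enumerate(fbns)]
    return FeatureMatrix(values=values, feature_names=names, labels=labels, subject_ids=ids)


def combine_blocks(ccc_block: FeatureMatrix, nmi_block: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of two feature blocks (CCC block first).

    Subjects must match in identity and order; duplicate names are
    disambiguated with a block suffix.
    """
    if ccc_block.subject_ids != nmi_block.subject_ids:
        raise AlignmentError("subject ids of the two blocks do not match")
    if not np.array_equal(ccc_block.labels, nmi_block.labels):
        raise AlignmentError("labels of the two blocks do not match")
    names = list(ccc_block.feature_names)
    other = [
        n if n not in set(names) else f"{n}_b2" for n in nmi_block.feature_names
    ]
    return FeatureMatrix(
        values=np.hstack([ccc_block.values, nmi_block.values]),
        feature_names=names + other,
        labels=ccc_block.labels.copy(),
        subject_ids=list(ccc_block.subject_ids),
    )


def select_important_features(
    fm: FeatureMatrix | np.ndarray,
    k: int = 25,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k feature indices by total-gain importance of a boosted-tree fit.

    Zero-variance columns (ubiquitous after thresholding) are dropped
    before the fit; importances of unused features are 0.  Ties are broken
    by the lower column index, and the result is deterministic given the
    seed.  Returns (indices into the original columns, their scores),
    ordered by decreasing importance.
    """
    from xgboost import XGBClassifier

    if isinstance(fm, FeatureMatrix):
        X, y = fm.values, fm.labels
    else:
        X = np.asarray(fm, dtype=float)
        if labels is None:
            raise InvalidArgumentError("labels required when passing a bare matrix")
        y = np.asarray(labels)
    if k < 1:
        raise InvalidArgumentError(f"k must be >= 1, got {k}")
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidArgumentError("need at least 2 classes for feature selection")
    y01 = (y == classes[-1]).astype(int)

    keep = np.flatnonzero(X.std(axis=0) > 0)
    scores = np.zeros(X.shape[1])
    if keep.size:
        clf = XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            # column subsampling spreads importance over correlated features
            # instead of crediting one arbitrary member of a redundant group
            colsample_bytree=0.5,
            tree_method="exact",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
        )
        clf.fit(X[:, keep], y01)
        gain = clf.get_booster().get_score(importance_type="total_gain")
        for name, value in gain.items():
            scores[keep[int(name[1:])]] = value  # names are f0, f1, ...
    order = np.lexsort((np.arange(scores.size), -scores))
    top = order[: min(k, scores.size)]
    return top, scores[top]
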