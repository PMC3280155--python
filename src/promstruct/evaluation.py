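"""Classifier evaluation, study metrics, feature ratios and TSS matching.

Metric conventions (deliberately kept as in the study being reproduced):
``Se = TP / (TP + FN)``; ``Sp = TP / (TP + FP)`` — note this "specificity"
is what is usually called precision; ``F = 2*Se*Sp / (Se + Sp)``.  The ROC
score is the area under the ROC curve via the rank (Mann-Whitney)
formulation with midranks for ties.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .datasets import TssRecord
from .features import FeatureMatrix, dims_for_feature
from .profiles import PropertyScale, average_profile
from .selection_filter import SelectedSubset
from .selection_wrapper import make_classifier

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "metrics_from_counts",
    "f_measure",
    "roc_score",
    "cross_validate",
    "feature_ratio",
    "correlate_features",
    "correlate_scales",
    "match_tss",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def f_measure(se: float, sp: float) -> float:
    """Harmonic combination 2*Se*Sp/(Se+Sp); 0 when both terms are 0."""
    if math.isnan(se) or math.isnan(sp):
        return float("nan")
    if se + sp == 0:
        return 0.0
    return 2.0 * se * sp / (se + sp)


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float]:
    """(Se, Sp, F) from confusion counts; undefined ratios propagate NaN."""
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    sp = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else float("nan")
    return se, sp, f_measure(se, sp)


@dataclass
class MetricsReport:
    se: float
    sp: float
    f: float
    roc: float
    counts: ConfusionCounts
    folds: int = 0
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "Se": self.se,
            "Sp": self.sp,
            "F": self.f,
            "ROC": self.roc,
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "TN": self.counts.tn,
            "folds": self.folds,
            "seed": self.seed,
            **self.params,
        }


def roc_score(scores: Sequence[float], y: Sequence[bool]) -> float:
    """Area under the ROC curve (rank formulation, midrank tie handling)."""
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(y, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a ROC score")
    ranks = rankdata(s, method="average")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _decision_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)


def cross_validate(
    fm: FeatureMatrix,
    subset: SelectedSubset | Sequence[int] | None = None,
    classifier: str = "svm",
    folds: int = 5,
    seed: int | None = None,
) -> MetricsReport:
    """Stratified k-fold CV with pooled held-out confusion counts.

    Metrics are computed once from the predictions pooled over all folds
    (micro pooling); the ROC score uses the pooled continuous decision
    scores.
    """
    if subset is None:
        dims = np.arange(fm.n_dims)
    elif isinstance(subset, SelectedSubset):
        dims = subset.dims
    else:
        dims = np.asarray(list(subset), dtype=int)
    X = fm.X[:, dims]
    y = fm.y.astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs at least {folds} members for {folds}-fold CV"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=int)
    dec = np.empty(len(y), dtype=float)
    for train_idx, test_idx in cv.split(X, y):
        clf = make_classifier(classifier, n_dims=X.shape[1], seed=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(X[test_idx])
        dec[test_idx] = _decision_scores(clf, X[test_idx])
    cc = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
    )
    se, sp, f = metrics_from_counts(cc)
    roc = roc_score(dec, y.astype(bool))
    return MetricsReport(
        se=se,
        sp=sp,
        f=f,
        roc=roc,
        counts=cc,
        folds=folds,
        seed=seed,
        params={"classifier": classifier.lower(), "n_dims": int(X.shape[1])},
    )


def feature_ratio(
    subset: SelectedSubset | Sequence[int], fm: FeatureMatrix
) -> dict[str, float]:
    """Percentage of the selected dimensions belonging to each feature."""
    dims = subset.dims if isinstance(subset, SelectedSubset) else np.asarray(list(subset))
    if dims.size == 0:
        raise ValueError("subset must be non-empty")
    ratios = {feat: 0.0 for feat in fm.feature_names}
    for d in dims:
        feat, _ = fm.index[int(d)]
        ratios[feat] += 1.0
    return {feat: 100.0 * count / dims.size for feat, count in ratios.items()}


def correlate_features(fm: FeatureMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise Pearson correlations between per-feature mean profiles.

    Each feature is summarized as its position-wise mean over all samples;
    the result is a symmetric unit-diagonal features x features matrix.
    """
    names = fm.feature_names
    profiles = np.stack(
        [fm.X[:, dims_for_feature(fm, feat)].mean(axis=0) for feat in names]
    )
    return names, np.corrcoef(profiles)


def correlate_scales(
    seqs: Sequence[str], scales: Sequence[PropertyScale]
) -> tuple[list[str], np.ndarray]:
    """Like :func:`correlate_features` but straight from sequences+scales."""
    names = [s.name for s in scales]
    profiles = np.stack([average_profile(seqs, s).values for s in scales])
    return names, np.corrcoef(profiles)


def _normalize_positions(
    items: Iterable, default_chrom: str = ""
) -> list[tuple[str, int]]:
    out = []
    for item in items:
        if isinstance(item, TssRecord):
            out.append((item.chrom, item.pos))
        elif isinstance(item, (tuple, list)):
            out.append((str(item[0]), int(item[1])))
        else:
            out.append((default_chrom, int(item)))
    return out


def match_tss(
    predictions: Iterable,
    annotated: Iterable,
    tol: int = 500,
) -> ConfusionCounts:
    """Greedy nearest-first one-to-one matching of predictions to TSSs.

    A prediction within *tol* bases (inclusive) of an unmatched annotated
    TSS on the same chromosome is a TP; leftover predictions are FPs and
    leftover TSSs are FNs.  Items may be ``TssRecord``s, ``(chrom, pos)``
    pairs, or bare integer positions.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    preds = _normalize_positions(predictions)
    truth = _normalize_positions(annotated)
    pairs = []
    for i, (pc, pp) in enumerate(preds):
        for j, (tc, tp_) in enumerate(truth):
            if pc == tc and abs(pp - tp_) <= tol:
                pairs.append((abs(pp - tp_), i, j))
    pairs.sort()
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    matches = 0
    for _, i, j in pairs:
        if i in used_pred or j in used_truth:
            continue
        used_pred.add(i)
        used_truth.add(j)
        matches += 1
    return ConfusionCounts(
        tp=matches,
        fp=len(preds) - matches,
        fn=len(truth) - matches,
        tn=0,
    )
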