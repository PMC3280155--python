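"""Filter-style feature (dimension) scoring and ranking.

Four criteria: information gain and chi-square on MDL-discretized columns,
ReliefF on the continuous [0, 1] matrix, and CFS merit (optimized with the
genetic search from :mod:`promstruct.selection_wrapper`).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DimensionScores",
    "SelectedSubset",
    "discretize_mdl",
    "ig_scores",
    "chi2_scores",
    "relieff_scores",
    "cfs_merit",
    "cfs_select",
    "top_k",
]

logger = logging.getLogger(__name__)


@dataclass
class DimensionScores:
    """Per-dimension scores from one filter criterion."""

    method: str
    scores: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class SelectedSubset:
    """An ordered set of selected dimension indices."""

    dims: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    scores: np.ndarray | None = None
    seed: int | None = None
    fitness: float | None = None
    trace: list[float] | None = None

    def __post_init__(self) -> None:
        self.dims = np.asarray(self.dims, dtype=int)
        if len(np.unique(self.dims)) != len(self.dims):
            raise ValueError("selected dimensions must be unique")

    @property
    def size(self) -> int:
        return len(self.dims)


# ---------------------------------------------------------------------------
# MDL (minimum description length) supervised discretization
# ---------------------------------------------------------------------------

def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray, n_classes: int):
    """Best single binary split of a sorted column, or None if MDL-rejected.

    *values* must be sorted ascending with *labels* aligned.  Returns
    ``(cut_index, cut_value)`` where ``cut_index`` is the size of the left
    partition.
    """
    n = len(values)
    if n < 2:
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), labels] = 1.0
    left = np.cumsum(onehot, axis=0)  # left[i] = class counts of values[:i+1]
    total = left[-1]

    # candidate cuts only between distinct adjacent values
    cand = np.flatnonzero(values[1:] > values[:-1])  # cut after index i
    if cand.size == 0:
        return None
    left_counts = left[cand]
    right_counts = total - left_counts
    nl = left_counts.sum(axis=1)
    nr = right_counts.sum(axis=1)

    def ent_rows(c):
        s = c.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(s > 0, c / np.maximum(s, 1), 0.0)
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -(p * logp).sum(axis=1)

    ent_total = _entropy_from_counts(total)
    cond = (nl * ent_rows(left_counts) + nr * ent_rows(right_counts)) / n
    gains = ent_total - cond
    best = int(np.argmax(gains))
    gain = float(gains[best])

    # Fayyad-Irani MDL acceptance criterion
    k0 = int((total > 0).sum())
    k1 = int((left_counts[best] > 0).sum())
    k2 = int((right_counts[best] > 0).sum())
    e0 = ent_total
    e1 = _entropy_from_counts(left_counts[best])
    e2 = _entropy_from_counts(right_counts[best])
    delta = np.log2(3.0**k0 - 2.0) - (k0 * e0 - k1 * e1 - k2 * e2)
    threshold = (np.log2(n - 1) + delta) / n
    if gain <= threshold:
        return None
    i = int(cand[best])
    cut_value = (values[i] + values[i + 1]) / 2.0
    return i + 1, cut_value


def _mdl_cuts(values: np.ndarray, labels: np.ndarray, n_classes: int) -> list[float]:
    cuts: list[float] = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        res = _best_cut(values[lo:hi], labels[lo:hi], n_classes)
        if res is None:
            continue
        split, cut_value = res
        cuts.append(cut_value)
        stack.append((lo, lo + split))
        stack.append((lo + split, hi))
    return sorted(cuts)


def discretize_mdl(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, list[list[float]]]:
    """Supervised recursive MDL binning of every column of *X*.

    Returns the integer bin matrix (bin 0 = lowest interval) and the cut
    points per column; columns with no accepted cut collapse to one bin.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 samples")
    _, labels = np.unique(y, return_inverse=True)
    n_classes = labels.max() + 1
    Xd = np.zeros(X.shape, dtype=np.int32)
    all_cuts: list[list[float]] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        cuts = _mdl_cuts(col[order], labels[order], n_classes)
        all_cuts.append(cuts)
        if cuts:
            Xd[:, j] = np.searchsorted(cuts, col, side="left")
    return Xd, all_cuts


# ---------------------------------------------------------------------------
# Univariate scores on discretized columns
# ---------------------------------------------------------------------------

def _contingency(col: np.ndarray, labels: np.ndarray, n_classes: int) -> np.ndarray:
    n_bins = int(col.max()) + 1
    table = np.zeros((n_bins, n_classes))
    np.add.at(table, (col, labels), 1.0)
    return table


def ig_scores(Xd: np.ndarray, y: np.ndarray) -> DimensionScores:
    """Information gain H(y) - H(y | X_d), in bits, per discretized column."""
    Xd = np.asarray(Xd)
    _, labels = np.unique(y, return_inverse=True)
    n_classes = labels.max() + 1
    n = len(labels)
    h_y = _entropy_from_counts(np.bincount(labels, minlength=n_classes).astype(float))
    scores = np.empty(Xd.shape[1])
    for j in range(Xd.shape[1]):
        table = _contingency(Xd[:, j], labels, n_classes)
        weights = table.sum(axis=1) / n
        cond = sum(
            w * _entropy_from_counts(row) for w, row in zip(weights, table) if w > 0
        )
        scores[j] = max(h_y - cond, 0.0)
    return DimensionScores(method="IG", scores=scores, params={"unit": "bits"})


def chi2_scores(Xd: np.ndarray, y: np.ndarray) -> DimensionScores:
    """Pearson chi-square statistic of each bin x label contingency table.

    No continuity correction; single-bin columns score 0.
    """
    Xd = np.asarray(Xd)
    _, labels = np.unique(y, return_inverse=True)
    n_classes = labels.max() + 1
    scores = np.empty(Xd.shape[1])
    for j in range(Xd.shape[1]):
        table = _contingency(Xd[:, j], labels, n_classes)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows * cols / table.sum()
        mask = expected > 0
        scores[j] = float(((table - expected)[mask] ** 2 / expected[mask]).sum())
    return DimensionScores(method="CHI", scores=scores, params={"correction": None})


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relieff_scores(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
    m_samples: int | None = None,
    seed: int | None = None,
) -> DimensionScores:
    """ReliefF weights with Manhattan per-dimension diff.

    For every sampled instance the mean diff to its *k* nearest hits is
    subtracted and the class-prior-weighted mean diff to the *k* nearest
    misses of each other class is added; weights are averaged over the
    sampled instances.  Diffs are normalized by each dimension's observed
    range, so weights lie in [-1, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    classes, labels = np.unique(y, return_inverse=True)
    class_counts = np.bincount(labels)
    priors = class_counts / n
    if np.any(class_counts < k_neighbors + 1):
        raise ValueError(
            f"every class needs at least k_neighbors+1={k_neighbors + 1} members"
        )
    ranges = X.max(axis=0) - X.min(axis=0)
    scale = np.where(ranges > 0, ranges, 1.0)
    Xn = X / scale
    zero_range = ranges == 0

    rng = np.random.default_rng(seed)
    if m_samples is None or m_samples >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = rng.choice(n, size=m_samples, replace=False)
    m = len(sample_idx)

    dist = cdist(Xn[sample_idx], Xn, metric="cityblock")
    weights = np.zeros(d)
    for row, i in enumerate(sample_idx):
        ci = labels[i]
        for c in range(len(classes)):
            members = np.flatnonzero(labels == c)
            if c == ci:
                members = members[members != i]
            order = members[np.argsort(dist[row, members], kind="stable")]
            nearest = order[:k_neighbors]
            diffs = np.abs(Xn[i] - Xn[nearest]).mean(axis=0)
            if c == ci:
                weights -= diffs
            else:
                weights += priors[c] / (1.0 - priors[ci]) * diffs
    weights /= m
    weights[zero_range] = 0.0
    return DimensionScores(
        method="ReliefF",
        scores=weights,
        params={"k_neighbors": k_neighbors, "m_samples": m, "seed": seed},
    )


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        logger.debug("zero-variance vector in correlation; treating r as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cfs_merit(X: np.ndarray, y: np.ndarray, subset: Sequence[int]) -> float:
    """Correlation-based merit of a dimension subset.

    ``merit = s * r_cf / sqrt(s + s(s-1) * r_ff)`` where ``r_cf`` is the
    mean |Pearson r| between subset dimensions and the class and ``r_ff``
    the mean |Pearson r| between subset dimension pairs.
    """
    subset = np.asarray(list(subset), dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    X = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    s = subset.size
    r_cf = np.mean([abs(_safe_pearson(X[:, j], yv)) for j in subset])
    if s == 1:
        return float(r_cf)
    r_ff_sum = 0.0
    for a in range(s):
        for b in range(a + 1, s):
            r_ff_sum += abs(_safe_pearson(X[:, subset[a]], X[:, subset[b]]))
    r_ff = r_ff_sum / (s * (s - 1) / 2)
    return float(s * r_cf / np.sqrt(s + s * (s - 1) * r_ff))


def cfs_select(
    X: np.ndarray,
    y: np.ndarray,
    ga_params=None,
) -> SelectedSubset:
    """Maximize CFS merit with the genetic subset search."""
    from .selection_wrapper import GAParams, genetic_search

    X = np.asarray(X, dtype=float)
    params = ga_params or GAParams()

    def fitness(dims: np.ndarray) -> float:
        if dims.size == 0:
            return -np.inf
        return cfs_merit(X, y, dims)

    result = genetic_search(fitness, n_dims=X.shape[1], params=params)
    result.method = "CFS"
    result.params = {"ga": params.__dict__ | {"fitness": "cfs-merit"}}
    return result


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def top_k(scores: DimensionScores, sizes: Sequence[int]) -> list[SelectedSubset]:
    """Highest-scoring dimensions at each requested size (nested subsets).

    Ties are broken toward the lower dimension index so rankings are
    deterministic.
    """
    s = scores.scores
    order = np.lexsort((np.arange(len(s)), -s))
    subsets = []
    for size in sizes:
        if not 1 <= size <= len(s):
            raise ValueError(f"size {size} out of range [1, {len(s)}]")
        dims = order[:size]
        subsets.append(
            SelectedSubset(
                dims=dims,
                method=scores.method,
                params=dict(scores.params, size=int(size)),
                scores=s[dims],
            )
        )
    return subsets
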