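import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promstruct import (
    cfs_merit,
    cfs_select,
    chi2_scores,
    discretize_mdl,
    ig_scores,
    relieff_scores,
    top_k,
)
from promstruct.selection_filter import DimensionScores
from promstruct.selection_wrapper import GAParams


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def entropy(counts):
    n = sum(counts)
    return -sum(c / n * math.log2(c / n) for c in counts if c)


def mdl_best_cut_oracle(values, labels):
    """Exhaustive single-split MDL search over all candidate cut points."""
    order = np.argsort(values, kind="stable")
    v, lab = np.asarray(values)[order], np.asarray(labels)[order]
    n = len(v)
    classes = sorted(set(lab))

    def class_counts(subset):
        return [int((subset == c).sum()) for c in classes]

    best = None
    for i in range(n - 1):
        if v[i + 1] <= v[i]:
            continue
        left, right = lab[: i + 1], lab[i + 1 :]
        gain = entropy(class_counts(lab)) - (
            len(left) / n * entropy(class_counts(left))
            + len(right) / n * entropy(class_counts(right))
        )
        if best is None or gain > best[0]:
            best = (gain, (v[i] + v[i + 1]) / 2, left, right)
    if best is None:
        return None
    gain, cut, left, right = best
    k0 = sum(1 for c in class_counts(lab) if c)
    k1 = sum(1 for c in class_counts(left) if c)
    k2 = sum(1 for c in class_counts(right) if c)
    delta = math.log2(3**k0 - 2) - (
        k0 * entropy(class_counts(lab))
        - k1 * entropy(class_counts(left))
        - k2 * entropy(class_counts(right))
    )
    if gain <= (math.log2(n - 1) + delta) / n:
        return None
    return cut


def relieff_oracle(X, y, k):
    """Literal per-instance ReliefF update, all instances, Manhattan diff."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    rng_ = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_ > 0, rng_, 1.0)
    classes, labels = np.unique(y, return_inverse=True)
    priors = np.bincount(labels) / n
    W = np.zeros(d)
    for i in range(n):
        dists = [np.sum(np.abs((X[i] - X[j]) / scale)) for j in range(n)]
        for c in range(len(classes)):
            members = [j for j in range(n) if labels[j] == c and j != i]
            members.sort(key=lambda j: dists[j])
            nearest = members[:k]
            diff = np.mean(
                [np.abs((X[i] - X[j]) / scale) for j in nearest], axis=0
            )
            if c == labels[i]:
                W -= diff
            else:
                W += priors[c] / (1 - priors[labels[i]]) * diff
    W /= n
    W[rng_ == 0] = 0.0
    return W


# ---------------------------------------------------------------------------
# discretize_mdl
# ---------------------------------------------------------------------------

def test_label_aligned_dimension_gets_two_bins():
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    X = np.array([0.0, 0, 0, 0, 1, 1, 1, 1]).reshape(-1, 1)
    Xd, cuts = discretize_mdl(X, y)
    assert cuts[0] == [0.5]
    assert set(Xd[:, 0]) == {0, 1}
    np.testing.assert_array_equal(Xd[:, 0], y)


def test_constant_dimension_gets_one_bin():
    y = np.array([0, 1, 0, 1])
    X = np.ones((4, 1))
    Xd, cuts = discretize_mdl(X, y)
    assert cuts[0] == []
    assert np.all(Xd == 0)


def test_mdl_cut_matches_exhaustive_oracle(rng):
    y = rng.integers(0, 2, size=8)
    while len(set(y)) < 2:
        y = rng.integers(0, 2, size=8)
    for _ in range(20):
        col = rng.random(8)
        _, cuts = discretize_mdl(col.reshape(-1, 1), y)
        oracle = mdl_best_cut_oracle(col, y)
        if oracle is None:
            assert cuts[0] == []
        else:
            assert cuts[0][0] == pytest.approx(oracle) or oracle in cuts[0]


def test_mdl_first_cut_is_oracle_cut():
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
    col = np.arange(8, dtype=float)
    _, cuts = discretize_mdl(col.reshape(-1, 1), y)
    oracle = mdl_best_cut_oracle(col, y)
    if oracle is None:
        assert cuts[0] == []
    else:
        assert oracle in cuts[0]


# ---------------------------------------------------------------------------
# ig_scores
# ---------------------------------------------------------------------------

def make_binary_column(table):
    """Discretized column + labels realizing a 2x2 bin-by-class table."""
    col, y = [], []
    for b, row in enumerate(table):
        for c, count in enumerate(row):
            col += [b] * count
            y += [c] * count
    return np.array(col).reshape(-1, 1), np.array(y)


def test_ig_of_label_equals_one_bit():
    Xd, y = make_binary_column([[10, 0], [0, 10]])
    assert ig_scores(Xd, y).scores[0] == pytest.approx(1.0)


def test_ig_of_constant_is_zero():
    y = np.array([0, 1] * 5)
    Xd = np.zeros((10, 1), dtype=int)
    assert ig_scores(Xd, y).scores[0] == pytest.approx(0.0)


def test_ig_contingency_8_2():
    Xd, y = make_binary_column([[8, 2], [2, 8]])
    expected = 1.0 - entropy([8, 2])  # 1 - H(0.8) ~ 0.278 bits
    assert ig_scores(Xd, y).scores[0] == pytest.approx(expected)
    assert expected == pytest.approx(0.2781, abs=1e-4)


# ---------------------------------------------------------------------------
# chi2_scores
# ---------------------------------------------------------------------------

def test_chi2_perfect_association():
    Xd, y = make_binary_column([[10, 0], [0, 10]])
    assert chi2_scores(Xd, y).scores[0] == pytest.approx(20.0)


def test_chi2_8_2_table():
    Xd, y = make_binary_column([[8, 2], [2, 8]])
    assert chi2_scores(Xd, y).scores[0] == pytest.approx(7.2)


def test_chi2_independent_dimension_near_zero():
    Xd, y = make_binary_column([[5, 5], [5, 5]])
    assert chi2_scores(Xd, y).scores[0] == pytest.approx(0.0)


def test_ig_chi_rank_identically_on_equal_margin_tables():
    """Both criteria are monotone in association for balanced 2x2 tables."""
    tables = [[[10 - a, a], [a, 10 - a]] for a in range(6)]
    cols, ys = zip(*[make_binary_column(t) for t in tables])
    Xd = np.hstack(cols)
    y = ys[0]
    ig = ig_scores(Xd, y).scores
    chi = chi2_scores(Xd, y).scores
    np.testing.assert_array_equal(np.argsort(-ig), np.argsort(-chi))


# ---------------------------------------------------------------------------
# relieff_scores
# ---------------------------------------------------------------------------

def test_relieff_constant_dimension_is_zero(rng):
    X = np.column_stack([np.ones(20), rng.random(20)])
    y = np.array([0, 1] * 10)
    scores = relieff_scores(X, y, k_neighbors=3).scores
    assert scores[0] == 0.0


def test_relieff_four_instance_hand_example():
    X = np.array([[0.0, 0.0], [0.1, 1.0], [1.0, 0.0], [0.9, 1.0]])
    y = np.array([0, 0, 1, 1])
    scores = relieff_scores(X, y, k_neighbors=1).scores
    np.testing.assert_allclose(scores, [0.8, -1.0])


@pytest.mark.parametrize("n,k", [(12, 1), (20, 3), (17, 5)])
def test_relieff_matches_bruteforce_oracle(rng, n, k):
    X = rng.random((n, 4))
    y = np.array([0, 1] * (n // 2) + [0] * (n % 2))
    np.testing.assert_allclose(
        relieff_scores(X, y, k_neighbors=k).scores,
        relieff_oracle(X, y, k),
        atol=1e-12,
    )


def test_relieff_separating_beats_noise(rng):
    n = 100
    y = np.repeat([0, 1], n // 2)
    separating = y + 0.05 * rng.standard_normal(n)
    noise = rng.random(n)
    X = np.column_stack([separating, noise])
    scores = relieff_scores(X, y, k_neighbors=10, seed=0).scores
    assert scores[0] > scores[1]


def test_relieff_bounds(rng):
    X = rng.random((40, 6))
    y = np.array([0, 1] * 20)
    scores = relieff_scores(X, y).scores
    assert np.all(scores >= -1.0) and np.all(scores <= 1.0)


def test_relieff_small_class_is_error(rng):
    X = rng.random((5, 2))
    y = np.array([0, 0, 0, 0, 1])
    with pytest.raises(ValueError, match="k_neighbors"):
        relieff_scores(X, y, k_neighbors=2)


# ---------------------------------------------------------------------------
# cfs_merit / cfs_select
# ---------------------------------------------------------------------------

def orthogonal_design(r_cf=0.5):
    """Two dims with |r| = r_cf to the class and ~0 to each other."""
    n = 8
    y = np.repeat([1.0, 0.0], n // 2)
    u = (y - y.mean()) / np.linalg.norm(y - y.mean())
    rng = np.random.default_rng(3)
    basis = []
    for _ in range(2):
        v = rng.standard_normal(n)
        v -= v.mean()
        v -= u * (u @ v)
        for b in basis:
            v -= b * (b @ v)
        basis.append(v / np.linalg.norm(v))
    a = r_cf * u + math.sqrt(1 - r_cf**2) * basis[0]
    c1 = -(r_cf**2) / math.sqrt(1 - r_cf**2)
    c2 = math.sqrt(1 - r_cf**2 - c1**2)
    b = r_cf * u + c1 * basis[0] + c2 * basis[1]
    return np.column_stack([a, b]), y


def test_cfs_singleton_is_abs_correlation(rng):
    X = rng.random((30, 3))
    y = rng.integers(0, 2, size=30).astype(float)
    r = abs(np.corrcoef(X[:, 1], y)[0, 1])
    assert cfs_merit(X, y, [1]) == pytest.approx(r)


def test_cfs_two_uncorrelated_dims():
    X, y = orthogonal_design(r_cf=0.5)
    assert abs(np.corrcoef(X[:, 0], X[:, 1])[0, 1]) < 1e-9
    assert cfs_merit(X, y, [0, 1]) == pytest.approx(2 * 0.5 / math.sqrt(2))


def test_cfs_duplicated_dimension_collapses_to_r(rng):
    x = rng.random(40)
    y = (x + 0.3 * rng.random(40) > 0.6).astype(float)
    X = np.column_stack([x, x])
    r = abs(np.corrcoef(x, y)[0, 1])
    assert cfs_merit(X, y, [0, 1]) == pytest.approx(r)


def test_cfs_zero_variance_dim_treated_as_zero(rng):
    X = np.column_stack([np.ones(20), rng.random(20)])
    y = np.array([0, 1] * 10).astype(float)
    assert cfs_merit(X, y, [0]) == 0.0


@given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
@settings(max_examples=20, deadline=None)
def test_cfs_merit_affine_invariant(a, b):
    rng = np.random.default_rng(5)
    X = rng.random((30, 4))
    y = rng.integers(0, 2, size=30).astype(float)
    base = cfs_merit(X, y, [0, 2, 3])
    scaled = X.copy()
    scaled[:, 2] = a * scaled[:, 2] + b
    assert cfs_merit(scaled, y, [0, 2, 3]) == pytest.approx(base)


def exhaustive_cfs_best(X, y):
    best = (-np.inf, None)
    d = X.shape[1]
    for mask in range(1, 2**d):
        subset = [j for j in range(d) if mask >> j & 1]
        merit = cfs_merit(X, y, subset)
        if merit > best[0]:
            best = (merit, tuple(subset))
    return best


@pytest.fixture(scope="module")
def cfs_toy_problem():
    rng = np.random.default_rng(17)
    n = 60
    y = np.repeat([0.0, 1.0], n // 2)
    informative = np.column_stack(
        [y + 0.4 * rng.standard_normal(n), 1 - y + 0.5 * rng.standard_normal(n)]
    )
    noise = rng.random((n, 8))
    return np.hstack([informative, noise]), y


def test_cfs_select_matches_exhaustive(cfs_toy_problem):
    X, y = cfs_toy_problem
    best_merit, best_subset = exhaustive_cfs_best(X, y)
    result = cfs_select(X, y, GAParams(population=30, generations=40, seed=2))
    assert result.fitness == pytest.approx(best_merit)
    assert tuple(result.dims) == best_subset


def test_cfs_select_recovers_planted_dims(cfs_toy_problem):
    X, y = cfs_toy_problem
    result = cfs_select(X, y, GAParams(population=30, generations=40, seed=2))
    assert {0, 1} <= set(result.dims.tolist())


def test_cfs_select_is_deterministic(cfs_toy_problem):
    X, y = cfs_toy_problem
    a = cfs_select(X, y, GAParams(population=20, generations=15, seed=9))
    b = cfs_select(X, y, GAParams(population=20, generations=15, seed=9))
    np.testing.assert_array_equal(a.dims, b.dims)


# ---------------------------------------------------------------------------
# top_k
# ---------------------------------------------------------------------------

def test_top_k_sizes_and_nestedness(rng):
    scores = DimensionScores(method="IG", scores=rng.random(600))
    subsets = top_k(scores, [100, 200, 300, 400, 500])
    assert [s.size for s in subsets] == [100, 200, 300, 400, 500]
    for small, big in zip(subsets, subsets[1:]):
        assert set(small.dims) <= set(big.dims)


def test_top_k_full_size_returns_all(rng):
    scores = DimensionScores(method="IG", scores=rng.random(10))
    (subset,) = top_k(scores, [10])
    assert set(subset.dims) == set(range(10))


def test_top_k_ties_break_by_lower_index():
    scores = DimensionScores(method="IG", scores=np.array([0.5, 0.9, 0.5, 0.9]))
    (subset,) = top_k(scores, [3])
    np.testing.assert_array_equal(subset.dims, [1, 3, 0])


def test_top_k_bad_size_is_error(rng):
    scores = DimensionScores(method="IG", scores=rng.random(10))
    with pytest.raises(ValueError):
        top_k(scores, [0])
    with pytest.raises(ValueError):
        top_k(scores, [11])
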