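"""Genetic-algorithm subset search and classifier-wrapper selection."""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix
from .selection_filter import SelectedSubset

__all__ = ["GAParams", "genetic_search", "wrapper_select", "make_classifier"]


@dataclass
class GAParams:
    """Bitstring-GA parameters (one bit per candidate dimension)."""

    population: int = 20
    generations: int = 20
    crossover_prob: float = 0.6
    mutation_prob: float = 0.033
    elitism: int = 1
    tournament: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.elitism < self.population:
            raise ValueError("elitism must be in [0, population)")


def genetic_search(
    fitness: Callable[[np.ndarray], float],
    n_dims: int,
    params: GAParams | None = None,
) -> SelectedSubset:
    """Maximize *fitness* over dimension subsets with a bitstring GA.

    Tournament selection, single-point crossover, per-bit mutation and
    elitism; the best individual ever seen is returned together with the
    per-generation best-ever trace.  Fully deterministic under a fixed
    ``params.seed``.
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    params = params or GAParams()
    rng = np.random.default_rng(params.seed)

    pop = rng.random((params.population, n_dims)) < 0.5

    def evaluate(individuals: np.ndarray) -> np.ndarray:
        vals = np.empty(len(individuals))
        for i, bits in enumerate(individuals):
            try:
                vals[i] = fitness(np.flatnonzero(bits))
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(
                    f"fitness evaluation failed on subset of size {bits.sum()}"
                ) from exc
        return vals

    fit = evaluate(pop)
    best_idx = int(np.argmax(fit))
    best_bits = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    trace = [best_fit]

    for _ in range(params.generations):
        # tournament selection
        parents = np.empty_like(pop)
        for i in range(params.population):
            contenders = rng.integers(0, params.population, size=params.tournament)
            parents[i] = pop[contenders[np.argmax(fit[contenders])]]
        # single-point crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, params.population - 1, 2):
            if rng.random() < params.crossover_prob and n_dims > 1:
                point = int(rng.integers(1, n_dims))
                children[i, point:], children[i + 1, point:] = (
                    parents[i + 1, point:].copy(),
                    parents[i, point:].copy(),
                )
        # per-bit mutation
        flip = rng.random(children.shape) < params.mutation_prob
        children ^= flip
        # elitism: keep the best-ever individuals
        if params.elitism:
            elite_order = np.argsort(-fit, kind="stable")[: params.elitism]
            children[: params.elitism] = pop[elite_order]
            children[0] = best_bits
        pop = children
        fit = evaluate(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_bits = pop[gen_best].copy()
        trace.append(best_fit)

    return SelectedSubset(
        dims=np.flatnonzero(best_bits),
        method="GA",
        params={"ga": params.__dict__},
        seed=params.seed,
        fitness=best_fit,
        trace=trace,
    )


def make_classifier(kind: str, n_dims: int, seed: int | None = None):
    """The two reference classifiers: RBF-SVM (C=1, gamma=1/dims) and 5-NN."""
    kind = kind.lower()
    if kind == "svm":
        gamma = 1.0 / n_dims if n_dims else "scale"
        return SVC(C=1.0, kernel="rbf", gamma=gamma, random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier {kind!r}; use 'svm' or 'knn'")


def wrapper_select(
    fm: FeatureMatrix,
    classifier: str = "svm",
    params: GAParams | None = None,
    cv_folds: int = 5,
) -> SelectedSubset:
    """GA wrapper selection with inner cross-validated accuracy as fitness.

    The fitness of a candidate subset is the mean stratified *cv_folds*-fold
    CV accuracy of the target classifier restricted to those dimensions.
    Report final metrics on held-out data, not on this fitness, to avoid
    selection bias.
    """
    params = params or GAParams()
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    y = fm.y.astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=params.seed)

    def fitness(dims: np.ndarray) -> float:
        if dims.size == 0:
            return 0.0
        clf = make_classifier(classifier, n_dims=dims.size, seed=params.seed)
        return float(
            cross_val_score(clf, fm.X[:, dims], y, cv=cv, scoring="accuracy").mean()
        )

    result = genetic_search(fitness, n_dims=fm.n_dims, params=params)
    result.method = f"wrapper-{classifier.lower()}"
    result.params = {
        "ga": params.__dict__,
        "classifier": classifier.lower(),
        "cv_folds": cv_folds,
        "fitness": "cv-accuracy",
    }
    return result
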