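"""Feature selection: CMIM, JMIM, Boruta and genetic-algorithm subset search.

The information-theoretic filters (CMIM, JMIM) share a plug-in mutual
information estimator on equal-frequency bins. Boruta is the all-relevant
shadow-feature wrapper around random-forest importances with a binomial
decision test. The genetic algorithm searches feature-inclusion bit
vectors scored by cross-validated RMSE of a chosen learner.

All selectors are pure functions of (data, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import KFold

from qsarnest.features import FeatureMatrix


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a feature-selection run.

    ``selected`` is ordered (selection order for greedy filters, importance
    order for Boruta); ``scores`` holds the criterion value at selection or
    the importance per selected feature.
    """

    selected: tuple
    scores: dict
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")


@dataclass(frozen=True)
class SelectorSpec:
    """Declarative selector configuration consumed by the nested-CV driver."""

    method: str  # none | top_mi | cmim | jmim | boruta | ga
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mutual information on equal-frequency bins


def _bin_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Integer codes: native levels for low-cardinality features, else
    equal-frequency bins."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, x)
    codes = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def mutual_information(x, y, n_bins: int = 10) -> float:
    """Plug-in mutual information (nats) of equal-frequency-binned vectors.

    Binary/low-cardinality features keep their native levels. A constant
    vector has zero MI with anything.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return 0.0
    return float(mutual_info_score(_bin_codes(x, n_bins), _bin_codes(y, n_bins)))


def _pair_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a * (b.max() + 1) + b


def _greedy_mi_select(
    X: FeatureMatrix, y, k: int, n_bins: int, seed: int, criterion: str, initial=()
) -> SelectionResult:
    y = np.asarray(y, dtype=float)
    p = X.p
    k = min(k, p)
    method = criterion
    if k <= 0:
        return SelectionResult(selected=(), scores={}, method=method, params={"k": k, "n_bins": n_bins}, seed=seed)
    codes = [_bin_codes(X.values[:, j], n_bins) for j in range(p)]
    y_codes = _bin_codes(y, n_bins)
    marginal = np.array([float(mutual_info_score(c, y_codes)) for c in codes])
    mi_s_y: dict[int, float] = {}  # I(s; y) cache for conditional MI

    selected: list[int] = []
    scores: dict[str, float] = {}
    if initial:
        # warm start: force the given features into S in order
        for name in initial:
            j = X.feature_names.index(name)
            selected.append(j)
            scores[name] = marginal[j]
            mi_s_y[j] = marginal[j]
    else:
        # seed pick: argmax marginal MI, ties -> lower column index
        first = int(np.argmax(marginal))
        selected.append(first)
        scores[X.feature_names[first]] = marginal[first]
        mi_s_y[first] = marginal[first]

    # joint-MI cache keyed by (candidate, selected)
    joint: dict[tuple[int, int], float] = {}

    def joint_mi(f: int, s: int) -> float:
        key = (f, s)
        if key not in joint:
            joint[key] = float(mutual_info_score(_pair_codes(codes[f], codes[s]), y_codes))
        return joint[key]

    while len(selected) < k:
        best_j, best_score = -1, -np.inf
        for j in range(p):
            if j in selected:
                continue
            if criterion == "cmim":
                score = min(joint_mi(j, s) - mi_s_y[s] for s in selected)
            else:  # jmim
                score = min(joint_mi(j, s) for s in selected)
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        scores[X.feature_names[best_j]] = best_score
        mi_s_y[best_j] = marginal[best_j]
    return SelectionResult(
        selected=tuple(X.feature_names[j] for j in selected),
        scores=scores,
        method=method,
        params={"k": k, "n_bins": n_bins},
        seed=seed,
    )


def cmim_select(
    X: FeatureMatrix, y, k: int = 30, n_bins: int = 10, seed: int = 0, initial=()
) -> SelectionResult:
    """Conditional mutual information maximization.

    Greedily adds f* = argmax_f min_{s in S} I(f; y | s), seeded with the
    feature of maximum marginal MI (or the warm-start ``initial`` list);
    I(f;y|s) is computed as I((f,s); y) - I(s; y) on the joint binned
    table.
    """
    return _greedy_mi_select(X, y, k, n_bins, seed, "cmim", initial)


def jmim_select(
    X: FeatureMatrix, y, k: int = 30, n_bins: int = 10, seed: int = 0, initial=()
) -> SelectionResult:
    """Joint mutual information maximization: argmax_f min_{s in S} I((f,s); y)."""
    return _greedy_mi_select(X, y, k, n_bins, seed, "jmim", initial)


def top_mi_select(X: FeatureMatrix, y, k: int = 1, n_bins: int = 10, seed: int = 0) -> SelectionResult:
    """Top-k features by marginal mutual information (fallback selector)."""
    y = np.asarray(y, dtype=float)
    mi = np.array([mutual_information(X.values[:, j], y, n_bins) for j in range(X.p)])
    order = np.argsort(-mi, kind="stable")[: max(k, 0)]
    return SelectionResult(
        selected=tuple(X.feature_names[j] for j in order),
        scores={X.feature_names[j]: float(mi[j]) for j in order},
        method="top_mi",
        params={"k": k, "n_bins": n_bins},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Boruta


def boruta_select(
    X: FeatureMatrix,
    y,
    max_iter: int = 100,
    alpha: float = 0.05,
    rf_params: dict | None = None,
    seed: int = 0,
    include_tentative: bool = False,
) -> SelectionResult:
    """All-relevant selection against permuted shadow features.

    Each iteration appends column-permuted shadow copies of the full
    feature set (a stable null bar: with few shadows the max-shadow
    threshold collapses and lucky noise features sneak through), fits a
    random-forest regressor, and scores a hit for every undecided real
    feature whose importance exceeds the maximum shadow importance.
    Accumulated hit counts are tested against Binomial(trials, 1/2) with
    Bonferroni correction across the undecided features; significantly
    many hits confirm a feature, significantly few reject it. Stops when
    all features are decided or after ``max_iter`` iterations; undecided
    features remain tentative.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X.values).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in X or y")
    if X.n < 20:
        raise ValueError("Boruta needs at least 20 observations")
    rf_params = dict(rf_params or {})
    rf_params.setdefault("n_estimators", 100)
    rng = np.random.default_rng(seed)
    p = X.p
    status = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    imp_history: list[np.ndarray] = []

    for _ in range(max_iter):
        undecided = np.flatnonzero(status == 0)
        if undecided.size == 0:
            break
        live = np.flatnonzero(status >= 0)  # confirmed + undecided go into the forest
        shadows = X.values.copy()  # shadow pool spans all features
        for c in range(shadows.shape[1]):
            rng.shuffle(shadows[:, c])
        design = np.hstack([X.values[:, live], shadows])
        forest = RandomForestRegressor(
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1, **rf_params
        )
        forest.fit(design, y)
        imp = forest.feature_importances_
        real_imp = np.full(p, np.nan)
        real_imp[live] = imp[: live.size]
        imp_history.append(real_imp)
        shadow_max = imp[live.size :].max()
        for j in undecided:
            trials[j] += 1
            if real_imp[j] > shadow_max:
                hits[j] += 1
        m = undecided.size
        for j in undecided:
            if binomtest(int(hits[j]), int(trials[j]), 0.5, alternative="greater").pvalue < alpha / m:
                status[j] = 1
            elif binomtest(int(hits[j]), int(trials[j]), 0.5, alternative="less").pvalue < alpha / m:
                status[j] = -1

    mean_imp = np.nanmean(np.vstack(imp_history), axis=0) if imp_history else np.zeros(p)
    chosen = status == 1
    if include_tentative:
        chosen |= status == 0
    order = sorted(np.flatnonzero(chosen), key=lambda j: -mean_imp[j])
    return SelectionResult(
        selected=tuple(X.feature_names[j] for j in order),
        scores={X.feature_names[j]: float(mean_imp[j]) for j in order},
        method="boruta",
        params={
            "max_iter": max_iter,
            "alpha": alpha,
            "rf_params": rf_params,
            "include_tentative": include_tentative,
            "n_confirmed": int((status == 1).sum()),
            "n_rejected": int((status == -1).sum()),
            "n_tentative": int((status == 0).sum()),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genetic-algorithm wrapper


def _cv_rmse(X: np.ndarray, y: np.ndarray, learner_spec, folds: int, seed: int) -> float:
    from qsarnest import learners as ln

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in kf.split(X):
        model = ln.fit(learner_spec, X[tr], y[tr])
        pred = ln.predict(model, X[te])
        errs.append(float(np.sqrt(np.mean((y[te] - pred) ** 2))))
    return float(np.mean(errs))


def ga_select(
    X: FeatureMatrix,
    y,
    learner_spec,
    pop_size: int = 50,
    generations: int = 30,
    p_crossover: float = 0.9,
    p_mutation: float | None = None,
    fitness_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Genetic-algorithm subset search.

    Chromosomes are feature-inclusion bit vectors; fitness is the mean
    cross-validated RMSE of ``learner_spec`` on the encoded subset (lower
    is better). Tournament selection of size 3, uniform crossover,
    per-bit flip mutation (default rate 1/p) and elitism of one. An empty
    chromosome is repaired by activating one random bit. Fully seeded.
    """
    y = np.asarray(y, dtype=float)
    p = X.p
    if p_mutation is None:
        p_mutation = 1.0 / p
    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            cols = np.flatnonzero(chrom)
            cache[key] = _cv_rmse(
                X.values[:, cols], y, learner_spec, fitness_folds, seed=int(rng.integers(2**31 - 1))
            )
        return cache[key]

    def repair(chrom: np.ndarray) -> np.ndarray:
        if not chrom.any():
            chrom[rng.integers(p)] = 1
        return chrom

    pop = [repair(rng.integers(0, 2, size=p).astype(np.int8)) for _ in range(pop_size)]
    fits = np.array([fitness(c) for c in pop])
    history = [float(fits.min())]

    for _ in range(generations):
        elite = pop[int(fits.argmin())].copy()
        new_pop = [elite]
        while len(new_pop) < pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, pop_size, size=3)
                parents.append(pop[int(contenders[np.argmin(fits[contenders])])])
            if rng.random() < p_crossover:
                mask = rng.integers(0, 2, size=p).astype(bool)
                child = np.where(mask, parents[0], parents[1]).astype(np.int8)
            else:
                child = parents[0].copy()
            flip = rng.random(p) < p_mutation
            child = child ^ flip.astype(np.int8)
            new_pop.append(repair(child))
        pop = new_pop
        fits = np.array([fitness(c) for c in pop])
        history.append(min(history[-1], float(fits.min())))

    best = pop[int(fits.argmin())]
    best_rmse = float(fits.min())
    names = tuple(X.feature_names[j] for j in np.flatnonzero(best))
    return SelectionResult(
        selected=names,
        scores={nm: best_rmse for nm in names},
        method="ga",
        params={
            "pop_size": pop_size,
            "generations": generations,
            "p_crossover": p_crossover,
            "p_mutation": p_mutation,
            "fitness_folds": fitness_folds,
            "best_rmse": best_rmse,
            "fitness_history": history,
        },
        seed=seed,
    )


def run_selector(spec: SelectorSpec, X: FeatureMatrix, y, seed: int) -> SelectionResult:
    """Dispatch a SelectorSpec to its implementation (seed overrides spec)."""
    params = dict(spec.params)
    if spec.method == "none":
        return SelectionResult(
            selected=tuple(X.feature_names), scores={}, method="none", params={}, seed=seed
        )
    if spec.method == "top_mi":
        return top_mi_select(X, y, seed=seed, **params)
    if spec.method == "cmim":
        return cmim_select(X, y, seed=seed, **params)
    if spec.method == "jmim":
        return jmim_select(X, y, seed=seed, **params)
    if spec.method == "boruta":
        return boruta_select(X, y, seed=seed, **params)
    if spec.method == "ga":
        return ga_select(X, y, seed=seed, **params)
    raise ValueError(f"unknown selector {spec.method!r}")
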