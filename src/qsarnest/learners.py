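"""Regression-learner registry with seeded random-search tuning.

Every learner is addressed by name through :data:`REGISTRY`; tree-based
learners declare ``needs_scaling = False`` and receive features as-is,
while scale-sensitive learners are wrapped with an internal standardizer
fitted on the training rows. Hyperparameter tuning is seeded random
search scored by cross-validated RMSE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from qsarnest.features import AlignmentError, FeatureMatrix


class LearnerUnavailableError(RuntimeError):
    """The named learner requires an optional backend that is not installed."""


def _triangular_weights(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max(axis=1, keepdims=True) + 1e-12
    return 1.0 - dist / (dmax * (1 + 1e-9))


def _gaussian_weights(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max(axis=1, keepdims=True) + 1e-12
    return np.exp(-((dist / dmax) ** 2))


_KKNN_KERNELS = {
    "rectangular": "uniform",
    "triangular": _triangular_weights,
    "gaussian": _gaussian_weights,
    "inverse": "distance",
}


def _make_linear(params, seed):
    return LinearRegression()


def _make_svm_rbf(params, seed):
    return SVR(kernel="rbf", C=params.get("C", 1.0), gamma=params.get("gamma", "scale"),
               epsilon=params.get("epsilon", 0.1))


def _make_random_forest(params, seed):
    p = dict(params)
    mtry = p.pop("mtry_fraction", None)
    if mtry is not None:
        p["max_features"] = mtry
    p.setdefault("n_estimators", 500)
    return RandomForestRegressor(random_state=seed, n_jobs=1, **p)


def _make_xgboost(params, seed):
    from xgboost import XGBRegressor

    p = dict(params)
    p.setdefault("max_depth", 4)
    p.setdefault("learning_rate", 0.1)
    p.setdefault("n_estimators", 200)
    return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **p)


def _make_gbm(params, seed):
    p = dict(params)
    p.setdefault("n_estimators", 200)
    return GradientBoostingRegressor(random_state=seed, **p)


def _make_kknn(params, seed):
    p = dict(params)
    kernel = p.pop("kernel", "triangular")
    weights = _KKNN_KERNELS.get(kernel)
    if weights is None:
        raise ValueError(f"unknown kknn kernel {kernel!r}")
    return KNeighborsRegressor(
        n_neighbors=p.get("k", 7), weights=weights, p=p.get("distance_power", 2)
    )


def _make_bart(params, seed):
    raise LearnerUnavailableError(
        "the 'bart' learner needs an optional Bayesian additive regression "
        "trees backend (e.g. pymc-bart); install one or choose another learner"
    )


def _make_cubist_like(params, seed):
    raise LearnerUnavailableError(
        "the 'cubist_like' rule/instance-based learner is an optional "
        "extension and has no backend installed"
    )


@dataclass(frozen=True)
class _RegistryEntry:
    factory: object
    needs_scaling: bool
    default_grid: dict


# Default random-search grids: conventional ranges.
REGISTRY: dict[str, _RegistryEntry] = {
    "linear": _RegistryEntry(_make_linear, True, {}),
    "svm_rbf": _RegistryEntry(
        _make_svm_rbf,
        True,
        {"C": ("loguniform", 2**-2, 2**6), "gamma": ("loguniform", 2**-8, 2**2)},
    ),
    "random_forest": _RegistryEntry(
        _make_random_forest, False, {"mtry_fraction": ("uniform", 0.1, 0.9)}
    ),
    "xgboost": _RegistryEntry(
        _make_xgboost,
        False,
        {
            "max_depth": ("int", 2, 8),
            "learning_rate": ("loguniform", 0.01, 0.3),
            "n_estimators": ("int", 100, 600),
        },
    ),
    "gbm": _RegistryEntry(
        _make_gbm, False, {"max_depth": ("int", 2, 6), "learning_rate": ("loguniform", 0.01, 0.3)}
    ),
    "kknn": _RegistryEntry(
        _make_kknn,
        True,
        {
            "k": ("int", 3, 25),
            "distance_power": ("int", 1, 2),
            "kernel": ["rectangular", "triangular", "gaussian", "inverse"],
        },
    ),
    "bart": _RegistryEntry(_make_bart, False, {"n_trees": ("int", 50, 200)}),
    "cubist_like": _RegistryEntry(_make_cubist_like, False, {}),
}


@dataclass(frozen=True)
class LearnerSpec:
    """Named learner plus its tuning grid and seed.

    ``grid`` entries are either explicit candidate lists or range tuples
    ``("uniform", lo, hi)``, ``("loguniform", lo, hi)``, ``("int", lo, hi)``.
    ``params`` pins hyperparameters outside of tuning.
    """

    name: str
    grid: dict | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in REGISTRY:
            raise KeyError(f"unknown learner {self.name!r}; registered: {sorted(REGISTRY)}")

    @property
    def needs_scaling(self) -> bool:
        return REGISTRY[self.name].needs_scaling

    @property
    def effective_grid(self) -> dict:
        return REGISTRY[self.name].default_grid if self.grid is None else self.grid


@dataclass
class FittedModel:
    """A fitted learner plus its training fingerprint (n, p, feature names)."""

    spec: LearnerSpec
    chosen_params: dict
    estimator: object
    feature_names: tuple | None
    n: int
    p: int


def _as_values(X) -> tuple[np.ndarray, tuple | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, tuple(X.feature_names)
    return np.asarray(X, dtype=float), None


def fit(spec: LearnerSpec, X, y, params: dict | None = None) -> FittedModel:
    """Fit a learner; scale-sensitive learners get an internal standardizer."""
    values, names = _as_values(X)
    y = np.asarray(y, dtype=float)
    if values.shape[0] < 5:
        raise ValueError("need at least 5 training observations")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in X")
    merged = {**spec.params, **(params or {})}
    entry = REGISTRY[spec.name]
    est = entry.factory(merged, spec.seed)
    if entry.needs_scaling:
        est = Pipeline([("scale", StandardScaler()), ("model", est)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(values, y)
    return FittedModel(
        spec=spec,
        chosen_params=merged,
        estimator=est,
        feature_names=names,
        n=values.shape[0],
        p=values.shape[1],
    )


def predict(model: FittedModel, X) -> np.ndarray:
    """Predict pIC50 for rows of X; feature names (when known) must align."""
    values, names = _as_values(X)
    if model.feature_names is not None and names is not None and names != model.feature_names:
        raise AlignmentError("feature columns do not match the training feature names")
    if values.shape[1] != model.p:
        raise AlignmentError(f"expected {model.p} features, got {values.shape[1]}")
    return np.asarray(model.estimator.predict(values), dtype=float)


def _sample_param(rng: np.random.Generator, spec):
    if isinstance(spec, (list, tuple)) and spec and spec[0] in ("uniform", "loguniform", "int"):
        kind, lo, hi = spec
        if kind == "uniform":
            return float(rng.uniform(lo, hi))
        if kind == "loguniform":
            return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        return int(rng.integers(lo, hi + 1))
    seq = list(spec)
    return seq[int(rng.integers(len(seq)))]


def tune(spec: LearnerSpec, X, y, folds: int = 10, budget: int = 25, seed: int = 0) -> dict:
    """Seeded random search over the grid, minimizing mean CV RMSE.

    Ties keep the first candidate encountered under the seeded order; an
    empty grid returns the defaults (empty dict).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    grid = spec.effective_grid
    if not grid:
        return {}
    values, _ = _as_values(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    candidates = [{k: _sample_param(rng, g) for k, g in grid.items()} for _ in range(budget)]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(values))
    best_params, best_rmse = {}, np.inf
    for cand in candidates:
        errs = []
        for tr, te in splits:
            model = fit(spec, values[tr], y[tr], params=cand)
            pred = predict(model, values[te])
            errs.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
        mean_rmse = float(np.mean(errs))
        if mean_rmse < best_rmse - 1e-12:
            best_params, best_rmse = cand, mean_rmse
    return best_params
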