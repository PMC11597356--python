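"""Model validation: metrics, nested cross-validation, y-randomization,
and model interpretation.

The central design point is leakage control: inside each outer fold the
preprocessing filters, the feature selector and the hyperparameter search
see only the outer-training rows, and every compound is predicted exactly
once, by a model that never saw it. Metrics are computed on the pooled
out-of-fold prediction vector ("true q2" convention), with the reference
mean for R2 taken over the pooled observed values.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from qsarnest import learners as ln
from qsarnest.features import FeatureMatrix, drop_correlated, drop_low_variance
from qsarnest.feature_selection import SelectorSpec, run_selector, top_mi_select


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (reporting convention for tables)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Metrics


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSE/SST on pooled predictions.

    SST uses the mean of the observed values over the same pooled set; the
    value may be negative for predictions worse than the mean.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("need equal-length vectors of at least 3 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values are constant; R2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def ccc(y, yhat, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    2*s_xy / (s_x^2 + s_y^2 + (mean difference)^2), population (1/n)
    moments by default (original formulation); ``sample_moments`` switches
    to n-1 denominators.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("need equal-length vectors of at least 3 observations")
    ddof = 1 if sample_moments else 0
    vy = y.var(ddof=ddof)
    vyh = yhat.var(ddof=ddof)
    if vy == 0 and vyh == 0:
        raise ValueError("both vectors constant; CCC undefined")
    n = y.size
    denom = n - ddof
    s_xy = float(np.sum((y - y.mean()) * (yhat - yhat.mean()))) / denom
    return 2 * s_xy / (vy + vyh + (y.mean() - yhat.mean()) ** 2)


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("need equal-length vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass(frozen=True)
class MetricSet:
    """R2 (true q2), Lin's CCC and RMSE of one prediction vector."""

    r2: float
    ccc: float
    rmse: float

    @classmethod
    def from_predictions(cls, y, yhat) -> "MetricSet":
        return cls(r2=r_squared(y, yhat), ccc=ccc(y, yhat), rmse=rmse(y, yhat))


def rp_squared(r2_true: float, rr2_mean: float) -> float:
    """y-randomization validity statistic Rp2 = R * sqrt(R2 - Rr2).

    ``r2_true`` is the genuine model's R2, ``rr2_mean`` the mean R2 of the
    response-permuted reruns. Undefined (NaN) when R2 < Rr2 or R2 < 0.
    """
    if r2_true < rr2_mean or r2_true < 0:
        return math.nan
    return math.sqrt(r2_true) * math.sqrt(r2_true - rr2_mean)


def replicate_mean_sd(values, ndigits: int = 3) -> tuple[float, float]:
    """Replicate aggregation: mean and sample (n-1) sd, half-up rounded."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates for a sample sd")
    return round_half_up(float(arr.mean()), ndigits), round_half_up(float(arr.std(ddof=1)), ndigits)


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass
class FoldDetail:
    fold: int
    test_indices: np.ndarray
    selected_features: tuple
    chosen_params: dict


@dataclass
class NestedCVResult:
    """Out-of-fold predictions and pooled metrics of one nested-CV run."""

    seed: int
    oof_predictions: np.ndarray  # one prediction per compound, outer-loop order preserved
    fold_details: list[FoldDetail]
    metrics: MetricSet
    y: np.ndarray


def _preprocess_fold(X: FeatureMatrix, train_idx, preprocess: bool, correlation_filter: bool):
    """Fit the drop filters on the outer-training rows only; return kept names."""
    if not preprocess:
        return list(X.feature_names)
    train_view = X.subset_rows(train_idx)
    filtered = drop_low_variance(train_view)
    if correlation_filter and filtered.p >= 2:
        filtered = drop_correlated(filtered)
    return list(filtered.feature_names)


def nested_cv(
    X: FeatureMatrix,
    y,
    selector_spec: SelectorSpec,
    learner_spec: ln.LearnerSpec,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    preprocess: bool = True,
    correlation_filter: bool = True,
    tune_budget: int = 10,
) -> NestedCVResult:
    """Nested cross-validation with per-fold selection and tuning.

    The outer loop partitions compounds into ``outer_folds`` test sets
    (seeded shuffle, contiguous blocks). Per fold, the variance/correlation
    filters, the feature selector and the random-search tuning (scored by
    ``inner_folds``-fold RMSE) run on the outer-training rows only; the
    tuned model predicts the outer-test rows. Metrics are computed on the
    pooled out-of-fold vector. A selector returning zero features falls
    back to the top marginal-MI feature.
    """
    y = np.asarray(y, dtype=float)
    n = X.n
    if n < outer_folds * 2:
        raise ValueError("need at least 2 observations per outer fold")
    oof = np.full(n, np.nan)
    details: list[FoldDetail] = []
    kf = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    for fold_idx, (tr, te) in enumerate(kf.split(X.values)):
        fold_seed = int(np.random.default_rng([seed, fold_idx]).integers(2**31 - 1))
        kept = _preprocess_fold(X, tr, preprocess, correlation_filter)
        X_kept = X.select_features(kept)
        sel = run_selector(selector_spec, X_kept.subset_rows(tr), y[tr], seed=fold_seed)
        chosen = list(sel.selected)
        if not chosen:
            fallback = top_mi_select(X_kept.subset_rows(tr), y[tr], k=1, seed=fold_seed)
            chosen = list(fallback.selected)
            if not chosen:
                raise RuntimeError(f"fold {fold_idx}: no usable feature")
        X_sel = X_kept.select_features(chosen)
        spec = ln.LearnerSpec(
            name=learner_spec.name,
            grid=learner_spec.grid,
            params=learner_spec.params,
            seed=fold_seed,
        )
        params = ln.tune(
            spec, X_sel.values[tr], y[tr], folds=inner_folds, budget=tune_budget, seed=fold_seed
        )
        model = ln.fit(spec, X_sel.values[tr], y[tr], params=params)
        oof[te] = ln.predict(model, X_sel.values[te])
        details.append(
            FoldDetail(fold=fold_idx, test_indices=te, selected_features=tuple(chosen), chosen_params=params)
        )
    assert not np.isnan(oof).any(), "every compound must receive exactly one oof prediction"
    return NestedCVResult(
        seed=seed,
        oof_predictions=oof,
        fold_details=details,
        metrics=MetricSet.from_predictions(y, oof),
        y=y.copy(),
    )


@dataclass
class ReplicateSummary:
    """Per-seed metric sets of replicate nested-CV runs plus mean/sd."""

    seeds: list[int]
    metric_sets: list[MetricSet]
    results: list[NestedCVResult] = field(default_factory=list)

    @property
    def mean_sd(self) -> dict:
        out = {}
        for name in ("r2", "ccc", "rmse"):
            vals = [getattr(m, name) for m in self.metric_sets]
            out[name] = replicate_mean_sd(vals)
        return out


def replicate_nested_cv(X, y, selector_spec, learner_spec, seeds, **kwargs) -> ReplicateSummary:
    """Repeat nested CV once per seed (default convention: 5 seeds)."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least 2 replicate seeds")
    results = [
        nested_cv(X, y, selector_spec, learner_spec, seed=s, **kwargs) for s in seeds
    ]
    return ReplicateSummary(
        seeds=seeds, metric_sets=[r.metrics for r in results], results=results
    )


@dataclass
class RandomizationResult:
    """y-randomization outcome: permuted-run metrics, Rr2 mean and Rp2."""

    n_perm: int
    metric_sets: list[MetricSet]
    rr2_mean: float
    rp2: float  # NaN flags the undefined case (genuine R2 below Rr2 mean)
    genuine: MetricSet


def y_randomize(
    X: FeatureMatrix,
    y,
    selector_spec: SelectorSpec,
    learner_spec: ln.LearnerSpec,
    genuine: MetricSet,
    n_perm: int = 20,
    seed: int = 0,
    **cv_kwargs,
) -> RandomizationResult:
    """Permute the response and rerun the whole pipeline per permutation.

    Each permutation repeats everything from scratch — filters, feature
    selection, tuning, nested CV — on the shuffled response; ``genuine``
    is the metric set of the un-permuted run.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    sets: list[MetricSet] = []
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        res = nested_cv(
            X, y_perm, selector_spec, learner_spec, seed=int(rng.integers(2**31 - 1)), **cv_kwargs
        )
        sets.append(res.metrics)
    rr2 = float(np.mean([m.r2 for m in sets]))
    return RandomizationResult(
        n_perm=n_perm,
        metric_sets=sets,
        rr2_mean=rr2,
        rp2=rp_squared(genuine.r2, rr2),
        genuine=genuine,
    )


# ---------------------------------------------------------------------------
# Model interpretation


def permutation_importance(
    model: ln.FittedModel, X, y, n_repeats: int = 10, seed: int = 0
) -> dict:
    """Per-feature mean RMSE increase when the feature column is permuted."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    names = (
        list(X.feature_names)
        if isinstance(X, FeatureMatrix)
        else [f"x{j}" for j in range(values.shape[1])]
    )
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    baseline = rmse(y, model.estimator.predict(values))
    importances = {}
    for j, name in enumerate(names):
        deltas = []
        for _ in range(n_repeats):
            perm = values.copy()
            rng.shuffle(perm[:, j])
            deltas.append(rmse(y, model.estimator.predict(perm)) - baseline)
        importances[name] = float(np.mean(deltas))
    return importances


def partial_dependence(model: ln.FittedModel, X, feature, grid_size: int = 20):
    """Quantile-grid partial dependence of the model on one feature.

    Returns (grid values, mean prediction with the feature set to each
    grid value). Features with few distinct values get their native
    levels (a binary feature yields a 2-point grid; a constant one a
    single point).
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if isinstance(X, FeatureMatrix):
        j = X.feature_names.index(feature) if isinstance(feature, str) else int(feature)
    else:
        j = int(feature)
    col = values[:, j]
    uniq = np.unique(col)
    if uniq.size <= grid_size:
        grid = uniq
    else:
        grid = np.unique(np.quantile(col, np.linspace(0, 1, grid_size)))
    means = []
    for g in grid:
        mod = values.copy()
        mod[:, j] = g
        means.append(float(np.mean(model.estimator.predict(mod))))
    return grid, np.array(means)
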