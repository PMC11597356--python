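"""Stacked ensembles over base models' out-of-fold predictions.

Meta-features are the base models' outer-loop (out-of-fold) predictions,
which keeps stacking leakage-safe: every meta-feature value comes from a
model that never saw that compound. The representative replicate for each
base model is the seed whose CCC is closest to the replicate mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qsarnest import learners as ln
from qsarnest.features import AlignmentError, FeatureMatrix
from qsarnest.feature_selection import SelectorSpec
from qsarnest.validation import (
    MetricSet,
    NestedCVResult,
    ReplicateSummary,
    nested_cv,
)


@dataclass(frozen=True)
class EnsembleSpec:
    """Base-model out-of-fold predictions plus a meta-learner.

    ``meta_learner`` is a LearnerSpec, or the string ``"mean"`` for the
    unweighted average of base predictions.
    """

    base_results: tuple  # of (model id, NestedCVResult)
    meta_learner: object
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base_results) < 2:
            raise ValueError("an ensemble needs at least 2 base models")


def select_representative_seed(summary: ReplicateSummary) -> int:
    """Index of the replicate whose CCC is closest to the replicate mean CCC.

    Ties resolve to the lower replicate index.
    """
    cccs = np.array([m.ccc for m in summary.metric_sets])
    mean = cccs.mean()
    return int(np.argmin(np.abs(cccs - mean)))


def build_meta_matrix(base_results) -> FeatureMatrix:
    """One column per base model, holding its out-of-fold predictions."""
    base_results = list(base_results)
    if len(base_results) < 2:
        raise ValueError("an ensemble needs at least 2 base models")
    names, cols = [], []
    n = None
    for model_id, result in base_results:
        oof = np.asarray(result.oof_predictions, dtype=float)
        if n is None:
            n = oof.size
        elif oof.size != n:
            raise AlignmentError(
                f"base model {model_id!r} has {oof.size} predictions, expected {n}"
            )
        names.append(str(model_id))
        cols.append(oof)
    return FeatureMatrix(
        values=np.column_stack(cols), feature_names=names, feature_kind="continuous"
    )


def evaluate_ensemble(
    spec: EnsembleSpec,
    y,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int | None = None,
    tune_budget: int = 10,
) -> NestedCVResult:
    """Nested CV of the meta-learner on the meta matrix (no selection stage).

    The ``"mean"`` meta-learner has nothing to fit: its out-of-fold
    prediction is simply the row mean of the base predictions.
    """
    meta = build_meta_matrix(spec.base_results)
    y = np.asarray(y, dtype=float)
    if seed is None:
        seed = spec.seed
    if spec.meta_learner == "mean":
        oof = meta.values.mean(axis=1)
        return NestedCVResult(
            seed=seed,
            oof_predictions=oof,
            fold_details=[],
            metrics=MetricSet.from_predictions(y, oof),
            y=y.copy(),
        )
    return nested_cv(
        meta,
        y,
        SelectorSpec(method="none"),
        spec.meta_learner,
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        seed=seed,
        preprocess=False,
        tune_budget=tune_budget,
    )


def screening_predictor(base_models: list[ln.FittedModel], meta_model):
    """Deployment-time ensemble: base models refit on the full training set,
    meta-learner applied to their stacked predictions.

    Returns a callable mapping a feature matrix to ensemble pIC50s;
    ``meta_model`` is a FittedModel over base-prediction columns or the
    string ``"mean"``.
    """

    def predict_fn(X) -> np.ndarray:
        preds = np.column_stack([ln.predict(m, X) for m in base_models])
        if meta_model == "mean":
            return preds.mean(axis=1)
        return np.asarray(meta_model.estimator.predict(preds), dtype=float)

    return predict_fn
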