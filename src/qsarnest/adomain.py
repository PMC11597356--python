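"""Applicability-domain estimation.

Two AD flavours, matched to feature kind: for binary fingerprints, a
query compound is inside the domain when its maximum Tanimoto similarity
to any training compound exceeds a cutoff (default 20%); for continuous
descriptors, an isolation forest scores the query and compounds with an
anomaly score below the canonical 0.5 boundary count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import IsolationForest

from qsarnest.features import FeatureMatrix


@dataclass
class ADModel:
    """Fitted applicability domain: similarity-based or isolation-forest."""

    kind: str  # similarity | isolation_forest
    threshold: float
    train_fps: np.ndarray | None = None
    forest: IsolationForest | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("similarity", "isolation_forest"):
            raise ValueError(f"unknown AD kind {self.kind!r}")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ADVerdict:
    """Inside/outside call with the underlying score.

    For the similarity AD the score is the maximum Tanimoto similarity to
    the training set (inside iff score > threshold, strict); for the
    isolation forest it is the anomaly score in [0, 1] (inside iff
    score < threshold).
    """

    inside: bool
    score: float


def fit_similarity_ad(
    train_fps: FeatureMatrix, threshold: float = 0.20, statistic: str = "max"
) -> ADModel:
    """Similarity AD: store training fingerprints and the similarity cutoff.

    ``statistic`` chooses how per-training-compound similarities collapse
    to one score: ``"max"`` (default, strictest common reading) or
    ``"mean"``.
    """
    if train_fps.feature_kind != "binary":
        raise ValueError("similarity AD needs binary fingerprints")
    if train_fps.n < 1:
        raise ValueError("need at least one training compound")
    if statistic not in ("max", "mean"):
        raise ValueError(f"unknown similarity statistic {statistic!r}")
    return ADModel(
        kind="similarity",
        threshold=threshold,
        train_fps=train_fps.values.astype(bool),
        params={"statistic": statistic},
    )


def assess_similarity(model: ADModel, fp) -> ADVerdict:
    """Score = max (or mean) Tanimoto to the training set; inside iff score > threshold."""
    if model.kind != "similarity":
        raise ValueError("not a similarity AD model")
    fp = np.asarray(fp, dtype=bool)
    train = model.train_fps
    if fp.ndim != 1 or fp.size != train.shape[1]:
        raise ValueError(f"fingerprint length {fp.size} != training length {train.shape[1]}")
    inter = (train & fp).sum(axis=1).astype(float)
    union = train.sum(axis=1) + fp.sum() - inter
    sims = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    score = float(sims.max() if model.params.get("statistic", "max") == "max" else sims.mean())
    return ADVerdict(inside=score > model.threshold, score=score)


def fit_isoforest_ad(
    train_desc: FeatureMatrix,
    n_trees: int = 100,
    ntry: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
) -> ADModel:
    """Isolation-forest AD over continuous descriptors.

    ``ntry`` is the number of candidate features drawn per tree for
    splitting. Anomaly scores follow the canonical 2^(-E[h]/c(n))
    normalization in [0, 1]; scores above 0.5 mark anomalies, so a query
    is inside the domain when its score is below ``threshold``.
    """
    if train_desc.n < 20:
        raise ValueError("need at least 20 training compounds")
    if not np.isfinite(train_desc.values).all():
        raise ValueError("non-finite values in training descriptors")
    forest = IsolationForest(
        n_estimators=n_trees,
        max_features=min(ntry, train_desc.p),
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train_desc.values)
    return ADModel(
        kind="isolation_forest",
        threshold=threshold,
        forest=forest,
        params={"n_trees": n_trees, "ntry": ntry, "seed": seed},
    )


def assess_isoforest(model: ADModel, x) -> ADVerdict:
    """Anomaly score of one descriptor vector; inside iff score < threshold."""
    if model.kind != "isolation_forest":
        raise ValueError("not an isolation-forest AD model")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in query descriptors")
    # sklearn's score_samples returns the negated 2^(-E[h]/c(n)) score
    score = float(-model.forest.score_samples(x)[0])
    return ADVerdict(inside=score < model.threshold, score=score)


def assess(model: ADModel, x) -> ADVerdict:
    """Dispatch to the AD flavour of the fitted model."""
    if model.kind == "similarity":
        return assess_similarity(model, x)
    return assess_isoforest(model, x)


def ad_coverage(verdicts) -> tuple[np.ndarray, dict]:
    """Per-compound inside-count and its marginal distribution.

    ``verdicts`` is an (n_compounds, n_models) boolean table; returns the
    per-compound count of models for which the compound is inside, and a
    dict mapping count k (0..n_models) to the number of compounds with
    that count.
    """
    table = np.asarray(verdicts, dtype=bool)
    if table.ndim != 2:
        raise ValueError("verdicts must be a rectangular compound x model table")
    counts = table.sum(axis=1)
    n_models = table.shape[1]
    distribution = {k: int((counts == k).sum()) for k in range(n_models + 1)}
    return counts, distribution
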