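"""Chemical-space diversity summaries over binary fingerprints."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from qsarnest.features import FeatureMatrix


@dataclass(frozen=True)
class SimilaritySummary:
    """Distribution summary of all unique pairwise Tanimoto similarities."""

    mean: float
    q1: float
    q3: float
    n_pairs: int


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a AND b| / (|a| + |b| - |a AND b|) of two bit vectors.

    Defined as 0 (with a warning) when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    c = int(np.sum(a & b))
    denom = int(a.sum()) + int(b.sum()) - c
    if denom == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0", stacklevel=2)
        return 0.0
    return c / denom


def pairwise_similarities(fm: FeatureMatrix) -> np.ndarray:
    """Flat vector of Tanimoto similarities for all n(n-1)/2 unique pairs."""
    if fm.feature_kind != "binary":
        raise ValueError("pairwise similarity is defined for binary fingerprints")
    X = fm.values.astype(bool)
    inter = (X.astype(int) @ X.astype(int).T).astype(float)
    bits = X.sum(axis=1)
    union = bits[:, None] + bits[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    iu = np.triu_indices(fm.n, k=1)
    return sim[iu]


def pairwise_similarity_summary(fm: FeatureMatrix) -> SimilaritySummary:
    """Mean and quartiles of the all-pairs Tanimoto similarity distribution.

    Quartiles use linear interpolation.
    """
    if fm.n < 2:
        raise ValueError("need at least 2 compounds")
    sims = pairwise_similarities(fm)
    q1, q3 = np.percentile(sims, [25, 75])
    return SimilaritySummary(mean=float(sims.mean()), q1=float(q1), q3=float(q3), n_pairs=sims.size)
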