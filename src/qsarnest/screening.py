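"""AD-gated consensus virtual screening.

Each library compound is predicted by every model, but only predictions
from models whose applicability domain contains the compound are pooled
into the consensus (mean, median, relative standard deviation). Compounds
outside every AD stay in the output, flagged, with no aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from qsarnest import learners as ln
from qsarnest.adomain import ADModel, ad_coverage, assess
from qsarnest.curation import CompoundRecord, SmilesParseError
from qsarnest.features import FeatureMatrix, maccs_fingerprints
from qsarnest.validation import round_half_up


@dataclass(frozen=True)
class ConsensusPrediction:
    """Per-compound consensus over the within-AD model predictions.

    ``rsd_pct`` (100 * sd / mean, sample sd) is None when fewer than two
    models are inside; mean/median are None when no model is inside.
    """

    compound_id: str
    n_models: int
    n_inside: int
    mean_pic50: float | None
    median_pic50: float | None
    rsd_pct: float | None
    ensemble_pic50: float | None = None

    def __post_init__(self) -> None:
        if self.n_inside > self.n_models:
            raise ValueError("n_inside cannot exceed n_models")


def consensus(
    predictions,
    verdicts,
    compound_id: str = "",
    ensemble_pic50: float | None = None,
    sample_sd: bool = True,
) -> ConsensusPrediction:
    """Aggregate per-model predictions over the models whose AD contains the compound."""
    preds = np.asarray(list(predictions), dtype=float)
    inside = np.asarray(list(verdicts), dtype=bool)
    if preds.shape != inside.shape or preds.size < 1:
        raise ValueError("predictions and verdicts must be equal-length and non-empty")
    trusted = preds[inside]
    n_inside = int(inside.sum())
    mean = median = rsd = None
    if n_inside >= 1:
        mean = float(trusted.mean())
        median = float(np.median(trusted))
    if n_inside >= 2:
        sd = float(trusted.std(ddof=1 if sample_sd else 0))
        rsd = 100.0 * sd / mean if mean != 0 else math.inf
    return ConsensusPrediction(
        compound_id=compound_id,
        n_models=preds.size,
        n_inside=n_inside,
        mean_pic50=mean,
        median_pic50=median,
        rsd_pct=rsd,
        ensemble_pic50=ensemble_pic50,
    )


def hit_rate(n_hits: int, n_total: int) -> float:
    """Percentage of hits, half-up rounded to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_hits / n_total, 2)


def _default_featurizer(smiles_list) -> FeatureMatrix:
    return maccs_fingerprints(smiles_list)


def screen_library(
    library: list[CompoundRecord] | list[str],
    models: list[tuple[ln.FittedModel, ADModel]],
    featurizers=None,
    ensemble=None,
    threshold_pic50: float = 8.0,
):
    """Screen a compound library with AD-gated consensus predictions.

    ``library`` is a list of curated records or raw SMILES strings;
    ``featurizers`` is one callable (smiles list -> FeatureMatrix) shared
    by all models, or a list parallel to ``models`` (default: MACCS
    fingerprints). ``ensemble`` is an optional callable mapping the
    per-model prediction matrix to one value per compound; its prediction
    is reported un-gated in its own column. Compounds whose features
    cannot be computed are excluded and logged, not fatal.

    Returns ``(rows, summary)``: one ConsensusPrediction per screened
    compound, plus a summary with hit counts at the pIC50 threshold (and
    its equivalent IC50 in nM), the AD-coverage distribution and the RSD
    distribution summary.
    """
    if not models:
        raise ValueError("need at least one (model, AD) pair")
    smiles = [r.smiles if isinstance(r, CompoundRecord) else str(r) for r in library]
    ids = [r.id if isinstance(r, CompoundRecord) else f"cmpd_{i}" for i, r in enumerate(library)]
    if featurizers is None:
        featurizers = _default_featurizer
    if callable(featurizers):
        featurizers = [featurizers] * len(models)
    if len(featurizers) != len(models):
        raise ValueError("featurizers must match models")

    # pre-screen SMILES one by one so a bad compound is excluded, not fatal
    excluded: list[dict] = []
    usable = []
    for i, smi in enumerate(smiles):
        try:
            for fz in dict.fromkeys(featurizers):
                fz([smi])
        except (SmilesParseError, ValueError) as exc:
            excluded.append({"id": ids[i], "reason": str(exc)})
            continue
        usable.append(i)

    use_smiles = [smiles[i] for i in usable]
    use_ids = [ids[i] for i in usable]
    n = len(usable)
    n_models = len(models)
    preds = np.zeros((n, n_models))
    inside = np.zeros((n, n_models), dtype=bool)
    feature_cache: dict[int, FeatureMatrix] = {}
    for j, ((model, ad), fz) in enumerate(zip(models, featurizers)):
        key = id(fz)
        if key not in feature_cache:
            feature_cache[key] = fz(use_smiles)
        fm = feature_cache[key]
        # model may have been trained on a feature subset
        if model.feature_names is not None and list(model.feature_names) != fm.feature_names:
            fm_j = fm.select_features(list(model.feature_names))
        else:
            fm_j = fm
        preds[:, j] = ln.predict(model, fm_j)
        # the AD may have been fit on the full feature set or the model's subset
        ad_width = ad.train_fps.shape[1] if ad.kind == "similarity" else ad.forest.n_features_in_
        ad_fm = fm if fm.p == ad_width else fm_j
        for i in range(n):
            inside[i, j] = assess(ad, ad_fm.values[i]).inside

    ens_pred = ensemble(preds) if ensemble is not None else [None] * n
    rows = [
        consensus(
            preds[i],
            inside[i],
            compound_id=use_ids[i],
            ensemble_pic50=None if ens_pred[i] is None else float(ens_pred[i]),
        )
        for i in range(n)
    ]

    counts, coverage = ad_coverage(inside)
    rsds = np.array([r.rsd_pct for r in rows if r.rsd_pct is not None], dtype=float)
    summary = {
        "n_screened": n,
        "n_excluded": len(excluded),
        "excluded": excluded,
        "threshold_pic50": threshold_pic50,
        "threshold_ic50_nM": 10 ** (9 - threshold_pic50),
        "n_mean_ge_threshold": int(
            sum(1 for r in rows if r.mean_pic50 is not None and r.mean_pic50 >= threshold_pic50)
        ),
        "n_median_ge_threshold": int(
            sum(1 for r in rows if r.median_pic50 is not None and r.median_pic50 >= threshold_pic50)
        ),
        "ad_coverage": coverage,
        "rsd_summary": None
        if rsds.size == 0
        else {
            "mean": float(rsds.mean()),
            "median": float(np.median(rsds)),
            "min": float(rsds.min()),
            "max": float(rsds.max()),
            "q3": float(np.percentile(rsds, 75)),
        },
    }
    if ensemble is not None:
        summary["n_ensemble_ge_threshold"] = int(
            sum(1 for r in rows if r.ensemble_pic50 is not None and r.ensemble_pic50 >= threshold_pic50)
        )
    return rows, summary
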