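"""Feature matrices: fingerprints, descriptor tables and preprocessing filters.

The featurization surface is deliberately descriptor-agnostic: MACCS
structural keys are computed in-package (RDKit), while continuous
descriptor tables come from any external provider via CSV. The
preprocessing filters mirror standard QSAR practice — drop constant and
quasi-constant columns, then greedily remove one member of every highly
correlated pair — and record a drop reason per removed feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from qsarnest.curation import SmilesParseError


class AlignmentError(ValueError):
    """Rows or columns do not line up with the expected compound/feature set."""


@dataclass
class FeatureMatrix:
    """n x p numeric matrix with feature metadata.

    ``feature_kind`` is ``"binary"`` (fingerprint bits, values in {0,1})
    or ``"continuous"``. ``dropped`` maps removed feature names to the
    reason they were removed; ``block_labels`` optionally groups features
    into named descriptor blocks.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_kind: str
    ids: list[str] | None = None
    block_labels: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.feature_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.feature_kind == "binary" and self.values.size:
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary matrix may contain only 0/1 values")
        if self.ids is not None and len(self.ids) != self.values.shape[0]:
            raise ValueError("ids must match the number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names, index=self.ids)

    def select_features(self, names: list[str], reason: str | None = None) -> "FeatureMatrix":
        """Column subset preserving the given order; optionally logs drops."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        missing = [nm for nm in names if nm not in index]
        if missing:
            raise AlignmentError(f"features not in matrix: {missing}")
        cols = [index[nm] for nm in names]
        dropped = dict(self.dropped)
        if reason is not None:
            for nm in self.feature_names:
                if nm not in set(names):
                    dropped[nm] = reason
        return FeatureMatrix(
            values=self.values[:, cols],
            feature_names=list(names),
            feature_kind=self.feature_kind,
            ids=self.ids,
            block_labels={nm: self.block_labels[nm] for nm in names if nm in self.block_labels},
            dropped=dropped,
        )

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            feature_kind=self.feature_kind,
            ids=[self.ids[int(i)] for i in idx] if self.ids is not None else None,
            block_labels=dict(self.block_labels),
            dropped=dict(self.dropped),
        )


N_MACCS = 166


def maccs_fingerprints(smiles_list, ids: list[str] | None = None) -> FeatureMatrix:
    """166-bit MACCS structural-key fingerprints, one row per compound.

    Column ``maccs_i`` holds the presence (1) or absence (0) of MACCS key
    ``i`` (keys 1..166). Deterministic for a given input.
    """
    smiles_list = list(smiles_list)
    bad = []
    rows = np.zeros((len(smiles_list), N_MACCS), dtype=float)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad.append(ids[i] if ids is not None else smi)
            continue
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        rows[i, :] = np.array(fp)[1:]
    if bad:
        raise SmilesParseError(f"unparsable SMILES for: {bad}")
    names = [f"maccs_{k}" for k in range(1, N_MACCS + 1)]
    return FeatureMatrix(values=rows, feature_names=names, feature_kind="binary", ids=ids)


def load_descriptor_table(path, dataset_ids, id_col: str = "id", block_map=None) -> FeatureMatrix:
    """Load a precomputed continuous descriptor CSV aligned to the dataset.

    Every dataset id must be present in the table (extra rows are ignored);
    non-numeric cells become missing, and any feature with a missing value
    is dropped with reason recorded. ``block_map`` is an optional path to a
    2-column CSV (feature, block) attaching block labels.
    """
    table = pd.read_csv(path, dtype={id_col: str})
    if id_col not in table.columns:
        raise KeyError(f"column {id_col!r} not found in {path}")
    table = table.set_index(id_col)
    dataset_ids = [str(i) for i in dataset_ids]
    missing = [i for i in dataset_ids if i not in table.index]
    if missing:
        raise AlignmentError(f"descriptor table lacks ids: {missing}")
    table = table.loc[dataset_ids]
    numeric = table.apply(pd.to_numeric, errors="coerce")
    dropped = {c: "missing values" for c in numeric.columns[numeric.isna().any()]}
    kept = [c for c in numeric.columns if c not in dropped]
    blocks: dict[str, str] = {}
    if block_map is not None:
        bm = pd.read_csv(block_map)
        feature_col, block_col = bm.columns[:2]
        blocks = dict(zip(bm[feature_col].astype(str), bm[block_col].astype(str)))
        blocks = {c: blocks[c] for c in kept if c in blocks}
    return FeatureMatrix(
        values=numeric[kept].to_numpy(dtype=float),
        feature_names=kept,
        feature_kind="continuous",
        ids=dataset_ids,
        block_labels=blocks,
        dropped=dropped,
    )


def drop_low_variance(fm: FeatureMatrix, freq_ratio: float = 19.0, unique_pct: float = 10.0) -> FeatureMatrix:
    """Remove constant and quasi-constant features.

    A feature is constant if it has a single distinct value, and
    quasi-constant if the most-common/second-most-common frequency ratio
    exceeds ``freq_ratio`` AND its distinct-value count is below
    ``unique_pct`` percent of n (near-zero-variance convention).
    """
    keep: list[str] = []
    dropped = dict(fm.dropped)
    n = fm.n
    for j, name in enumerate(fm.feature_names):
        col = fm.values[:, j]
        _, counts = np.unique(col, return_counts=True)
        if len(counts) == 1:
            dropped[name] = "constant"
            continue
        counts = np.sort(counts)[::-1]
        ratio = counts[0] / counts[1]
        pct_unique = 100.0 * len(counts) / n
        if ratio > freq_ratio and pct_unique < unique_pct:
            dropped[name] = f"quasi-constant (freq ratio {ratio:.1f}, {pct_unique:.1f}% unique)"
            continue
        keep.append(name)
    out = fm.select_features(keep)
    out.dropped = dropped
    return out


def drop_correlated(fm: FeatureMatrix, cutoff: float = 0.90) -> FeatureMatrix:
    """Greedy removal of highly correlated features.

    While any absolute pairwise Pearson correlation exceeds ``cutoff``,
    the member of the worst (largest |r|) pair with the larger mean
    absolute correlation to all remaining features is removed;
    ties break toward removing the lexicographically later name. The
    result contains no pair with |r| > cutoff.
    """
    if fm.p < 2:
        return fm
    names = list(fm.feature_names)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(fm.values, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    active = list(range(len(names)))
    dropped = dict(fm.dropped)
    while len(active) > 1:
        sub = corr[np.ix_(active, active)]
        worst = sub.max()
        if worst <= cutoff:
            break
        # worst pair; deterministic scan order keeps ties reproducible
        i_loc, j_loc = np.unravel_index(int(sub.argmax()), sub.shape)
        a, b = active[i_loc], active[j_loc]
        mean_a = sub[i_loc].sum() / (len(active) - 1)
        mean_b = sub[j_loc].sum() / (len(active) - 1)
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = a if names[a] > names[b] else b
        partner = b if victim == a else a
        dropped[names[victim]] = f"correlated (|r|={worst:.3f} with {names[partner]})"
        active.remove(victim)
    out = fm.select_features([names[i] for i in active])
    out.dropped = dropped
    return out


@dataclass(frozen=True)
class Scaler:
    """Per-feature standardizer with statistics learned on training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple
    fit_indices: tuple  # rows the statistics were learned on (leakage audit)


def fit_scaler(fm: FeatureMatrix, train_idx) -> Scaler:
    """Learn per-feature mean/sd on the given training rows."""
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise ValueError("train indices must be non-empty")
    sub = fm.values[train_idx]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero training sd for feature(s): {[fm.feature_names[j] for j in zero]}")
    return Scaler(
        mean=mean, sd=sd, feature_names=tuple(fm.feature_names), fit_indices=tuple(int(i) for i in train_idx)
    )


def apply_scaler(scaler: Scaler, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted standardizer: (x - train mean) / train sd, no clipping."""
    if tuple(fm.feature_names) != scaler.feature_names:
        raise AlignmentError("feature names do not match the fitted scaler")
    return FeatureMatrix(
        values=(fm.values - scaler.mean) / scaler.sd,
        feature_names=list(fm.feature_names),
        feature_kind="continuous",
        ids=fm.ids,
        block_labels=dict(fm.block_labels),
        dropped=dict(fm.dropped),
    )
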