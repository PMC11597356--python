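"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator plants the pathologies each pipeline stage must handle:
block-correlated fingerprint bits, constant / quasi-constant / redundant
descriptor columns, a sparse linear (optionally interacting) response with
known active features and a recorded generative R*2, and a small raw
activity table exercising the curation rules (duplicates, acid/salt pair,
unparsable SMILES, non-positive and missing IC50).

Everything is deterministic given the seed; every fixture ships a
manifest of its ground truth.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from qsarnest.features import FeatureMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic feature matrix + response.

    ``block_corr`` is the within-block exchangeable correlation of the
    latent gaussians; ``n_constant`` / ``n_quasi`` / ``n_redundant``
    append pathological columns on top of the ``p`` base features.
    ``noise_sd`` defaults to the value giving a generative signal fraction
    R*2 = 0.75 under unit-variance features.
    """

    n: int = 300
    p: int = 50
    k_informative: int = 5
    beta: tuple = ()
    noise_sd: float | None = None
    r_star2: float | None = 0.75
    feature_kind: str = "continuous"
    n_constant: int = 0
    n_quasi: int = 0
    n_redundant: int = 0
    block_corr: float = 0.3
    block_size: int = 10
    interaction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.p:
            raise ValueError("k_informative cannot exceed p")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must lie in [0, 1)")
        if self.beta and len(self.beta) != self.k_informative:
            raise ValueError("beta must have k_informative entries")

    @property
    def effect_sizes(self) -> np.ndarray:
        return np.asarray(self.beta if self.beta else [1.0] * self.k_informative)


def gen_features(spec: SyntheticSpec) -> FeatureMatrix:
    """Block-correlated feature matrix with planted pathological columns.

    Continuous features are standard gaussians sharing a block factor
    (exchangeable correlation ``block_corr`` within blocks of
    ``block_size``); binary features threshold the same latents at
    quantiles drawn so marginal bit frequencies fall in [0.05, 0.6].
    Appended columns: ``const_*`` (constant), ``quasi_*`` (single rare
    off-value), ``redund_*`` (noisy copies of base features, |r| > 0.9).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p
    rho = spec.block_corr
    n_blocks = math.ceil(p / spec.block_size)
    block_factor = rng.standard_normal((n, n_blocks))
    latent = np.empty((n, p))
    block_of = np.empty(p, dtype=int)
    for j in range(p):
        b = j // spec.block_size
        block_of[j] = b
        latent[:, j] = math.sqrt(rho) * block_factor[:, b] + math.sqrt(1 - rho) * rng.standard_normal(n)

    names = [f"x{j}" for j in range(p)]
    blocks = {f"x{j}": f"block{block_of[j]}" for j in range(p)}
    if spec.feature_kind == "binary":
        freqs = rng.uniform(0.05, 0.6, size=p)
        values = (latent < norm.ppf(freqs)).astype(float)
    else:
        values = latent

    cols = [values]
    for c in range(spec.n_constant):
        cols.append(np.full((n, 1), float(c)))
        names.append(f"const_{c}")
    for q in range(spec.n_quasi):
        col = np.zeros((n, 1))
        col[rng.integers(n), 0] = 1.0  # single rare off-value
        cols.append(col)
        names.append(f"quasi_{q}")
    for r in range(spec.n_redundant):
        parent = r % p
        if spec.feature_kind == "binary":
            copy = values[:, parent].copy()
            flip = rng.random(n) < 0.02  # rare flips keep |r| > 0.9
            copy[flip] = 1 - copy[flip]
            cols.append(copy.reshape(-1, 1))
        else:
            cols.append((values[:, parent] + 0.2 * rng.standard_normal(n)).reshape(-1, 1))
        names.append(f"redund_{r}")
        blocks[f"redund_{r}"] = blocks[f"x{parent}"]

    return FeatureMatrix(
        values=np.hstack(cols),
        feature_names=names,
        feature_kind=spec.feature_kind,
        block_labels=blocks,
    )


def _noise_sd_for(spec: SyntheticSpec, signal: np.ndarray) -> float:
    if spec.noise_sd is not None:
        return spec.noise_sd
    r2 = spec.r_star2 if spec.r_star2 is not None else 0.75
    var_sig = float(signal.var())
    return math.sqrt(var_sig * (1 - r2) / r2)


def gen_response(X: FeatureMatrix, spec: SyntheticSpec):
    """Sparse response over a known active set, mapped to the pIC50 scale.

    y = sum_j beta_j x_j (+ optional product interaction of the first two
    active features) + gaussian noise, then affinely mapped to mean 6 and
    sd 1.5 (a realistic pIC50 span). Returns ``(y, truth, r_star2)`` where
    ``truth`` is the list of active feature names and ``r_star2`` the
    generative signal fraction Var(signal)/(Var(signal)+noise_sd^2)
    computed from the realized sample.
    """
    rng = np.random.default_rng([spec.seed, 1])
    active = list(range(spec.k_informative))
    beta = spec.effect_sizes
    signal = X.values[:, active] @ beta
    if spec.interaction and spec.k_informative >= 2:
        signal = signal + X.values[:, active[0]] * X.values[:, active[1]]
    noise_sd = _noise_sd_for(spec, signal)
    y_raw = signal + rng.normal(0, noise_sd, size=X.n)
    var_sig = float(signal.var())
    r_star2 = var_sig / (var_sig + noise_sd**2) if (var_sig + noise_sd**2) > 0 else 0.0
    # affine map preserves the signal/noise split
    sd = y_raw.std()
    y = 6.0 + 1.5 * (y_raw - y_raw.mean()) / (sd if sd > 0 else 1.0)
    truth = [X.feature_names[j] for j in active]
    return y, truth, r_star2


def gen_regression_problem(spec: SyntheticSpec):
    """Convenience: features + response in one call."""
    X = gen_features(spec)
    y, truth, r_star2 = gen_response(X, spec)
    return X, y, truth, r_star2


@dataclass
class CurationFixture:
    """Raw activity CSV (text) plus the manifest of expected outcomes."""

    csv_text: str
    manifest: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.csv_text)


def gen_curation_fixture(seed: int = 0) -> CurationFixture:
    """~30-row raw activity table exercising every curation rule.

    Contains a duplicate trio ({1, 10, 100} nM, median 10), a duplicate
    pair ({10, 1000} nM, midpoint 505), an acid/salt pair sharing one
    structure key, one unparsable SMILES, one non-positive IC50 and one
    blank IC50. The manifest records expected row/record counts.
    """
    rng = np.random.default_rng(seed)
    # simple distinct parent structures (alkanols/acids/amides of varying length)
    backbones = [
        "CCO", "CCCO", "CCCCO", "CCCCCO", "CC(C)O", "CC(C)CO",
        "CC(=O)N", "CCC(=O)N", "CCCC(=O)N", "CC(C)C(=O)N",
        "c1ccccc1O", "c1ccccc1N", "Cc1ccccc1", "CCc1ccccc1",
        "c1ccncc1", "Cc1ccncc1", "C1CCCCC1", "C1CCCC1",
        "CCOC", "CCOCC",
    ]
    rows = ["id,smiles,ic50_nM"]
    i = 0
    for smi in backbones:
        ic50 = float(np.round(10 ** rng.uniform(0, 5), 3))
        rows.append(f"c{i:03d},{smi},{ic50}")
        i += 1
    # duplicate trio -> median 10 nM
    for val in (1, 10, 100):
        rows.append(f"c{i:03d},OCCN,{val}")
        i += 1
    # duplicate pair (even count) -> midpoint 505 nM
    for val in (10, 1000):
        rows.append(f"c{i:03d},NCCN,{val}")
        i += 1
    # acid/salt pair -> one structure key (acid form)
    rows.append(f"c{i:03d},CC(=O)O,50")
    i += 1
    rows.append(f"c{i:03d},CC(=O)[O-].[Na+],200")
    i += 1
    # dropped rows: unparsable SMILES, non-positive IC50, blank IC50
    rows.append(f"c{i:03d},not_a_smiles,25")
    i += 1
    rows.append(f"c{i:03d},CCCl,0")
    i += 1
    rows.append(f"c{i:03d},CCBr,")
    i += 1
    n_rows = i
    manifest = {
        "n_rows": n_rows,
        "n_dropped": 3,
        "n_records_after_read": n_rows - 3,
        # trio collapses 3->1, pair 2->1, acid/salt 2->1
        "n_records_after_dedup": n_rows - 3 - 2 - 1 - 1,
        "duplicate_trio": {"smiles": "NCCO", "median_ic50_nM": 10.0},
        "duplicate_pair": {"smiles": "NCCN", "median_ic50_nM": 505.0},
        "acid_salt_key": "CC(=O)O",
    }
    return CurationFixture(csv_text="\n".join(rows) + "\n", manifest=manifest)
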