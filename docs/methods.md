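# Methods

`qsarnest` is a QSAR regression pipeline for pIC50 modeling of enzyme
inhibitors (its motivating target is human HMG-CoA reductase, the
rate-limiting enzyme of cholesterol biosynthesis, but nothing in the
pipeline is target-specific). This note records the models and procedures
implemented, the parameters that matter, and the design choices made
where the design was genuinely open.

## Data model and curation

A compound is (id, SMILES, IC50 in nM); activity is modeled as
pIC50 = −log10(IC50 in mol/L) = 9 − log10(IC50 in nM), so pIC50 ≥ 8 is
equivalent to IC50 ≤ 10 nM.

Structure standardization is deliberately minimal and deterministic:
parse → keep the largest covalent fragment (most heavy atoms; ties broken
by the longer canonical SMILES, then lexicographically) → neutralize
protonation-only charges (RDKit Uncharger) → canonical SMILES. This is
enough to make an acid and its salt collapse onto one structure key,
which is the behavior duplicate merging depends on. Tautomer
canonicalization is available behind a flag but off by default, because
tautomer rule sets differ between toolkits and silently change structure
keys.

Duplicates (same structure key) merge onto the **median** IC50 — the
midpoint of the two central values for an even count — and pIC50 is
recomputed from the merged IC50, not averaged over the duplicates'
pIC50s. Train/test splitting takes floor(n·ratio) training compounds
(ratio 0.75: 227 compounds split 170/57) by a seeded permutation, without
activity stratification.

Drug-likeness failure counting uses five checks (MW ≤ 500, ALogP ≤ 5,
HBD ≤ 5, HBA ≤ 10, rotatable bonds ≤ 10) so that a 0–5 failure histogram
is representable; the canonical four-rule variant is available by passing
`fifth_check=None`. The fifth criterion is configurable because
rule-of-five implementations disagree on it.

## Features and preprocessing

Binary features are the 166 MACCS structural keys (RDKit; the unused
bit 0 of the 167-bit vector is dropped). Continuous descriptors come from
any external provider via CSV — the pipeline is descriptor-agnostic by
design, with optional block labels (e.g. "Burden eigenvalues") attached
from a 2-column map.

Preprocessing order is fixed: constant/quasi-constant filter →
correlation filter → (per-fold) standardization. Quasi-constant means
most-common/second-most-common frequency ratio > 19 **and** distinct
values < 10% of n (common near-zero-variance defaults). The correlation
filter greedily removes, from the worst remaining pair with |r| > 0.90,
the member with the larger mean absolute correlation to everything else
(ties remove the lexicographically later name), and guarantees no
remaining pair above the cutoff. Scaling statistics are learned on
training rows only and recorded (`Scaler.fit_indices`) so leakage is
auditable; tree-based learners bypass scaling entirely.

## Feature selection

- **CMIM / JMIM** share a plug-in mutual-information estimator on
  equal-frequency bins (default 10; low-cardinality features keep their
  native levels). CMIM greedily adds argmax_f min_{s∈S} I(f; y | s), with
  I(f;y|s) = I((f,s); y) − I(s; y) on the joint binned table; JMIM uses
  min_{s∈S} I((f,s); y). Both seed with the max-marginal-MI feature;
  a warm-start list can force features into S, which is also how the
  XOR-interaction property (a parent of an XOR response is invisible
  marginally but dominant once the other parent is selected) is testable
  at all.
- **Boruta** compares random-forest importances against column-permuted
  "shadow" features. One deliberate choice: the shadow pool always spans
  the full feature set, not just the undecided features. With a shrinking
  pool the max-shadow bar collapses (a pool of 1–2 shadows is trivially
  beaten) and lucky noise features get confirmed; a full pool keeps the
  null bar stable across iterations. Decisions use one-sided binomial
  tests at level alpha (0.05) with Bonferroni correction across the
  undecided features; undecided features at `max_iter` (default 100)
  remain tentative and are excluded unless `include_tentative` is set.
- **GA subset search**: inclusion bit-vector chromosomes, fitness = mean
  cross-validated RMSE of a chosen learner on the encoded subset,
  tournament selection (size 3), uniform crossover (p = 0.9), per-bit
  mutation (1/p), elitism of one. Population 50 × 30 generations by
  default; all operators seeded, empty chromosomes repaired by setting
  one random bit. Elitism makes the best fitness non-increasing, which is
  property-tested.

## Learners

A registry maps names to seeded scikit-learn / XGBoost estimators
(svm_rbf, random_forest, xgboost, gbm, kknn with rectangular /
triangular / gaussian / inverse distance kernels, linear). Scale-sensitive
learners are wrapped with an internal standardizer, making predictions
invariant to affine feature rescaling. Tuning is seeded random search
(default budget 25 draws) over conventional ranges (SVM C ∈ 2^−2..2^6,
gamma ∈ 2^−8..2^2 log-uniform; kknn k ∈ 3..25; XGBoost depth 2–8, eta
0.01–0.3, 100–600 rounds), scored by k-fold RMSE; ties keep the first
candidate in seeded order. A BART (Bayesian additive regression trees)
entry exists in the registry but raises a documented error unless an
optional backend is installed; the rule/instance-based `cubist_like`
entry is likewise a reserved optional extension.

## Validation

Metrics on the pooled out-of-fold vector: R² = 1 − SSE/SST with the
reference mean taken over the pooled observed values ("true q²"), Lin's
concordance correlation coefficient with population (1/n) moments
(sample-moment variant by flag), and RMSE in pIC50 units. Reported
replicate aggregates are mean and sample (n−1) sd, rounded half-up to 3
decimals — ordinary round-half-even would not reproduce printed tables.

Nested CV: seeded shuffled contiguous outer folds (default 10); per fold,
variance/correlation filters, feature selection and random-search tuning
(inner k-fold RMSE, default 10 folds) run on the outer-training rows
only; a selector returning nothing falls back to the top marginal-MI
feature. Every compound is predicted exactly once. Replicates rerun the
whole procedure under different seeds (convention: 5) and the
representative replicate for stacking is the one whose CCC is closest to
the replicate mean (ties → lower index).

y-randomization permutes the response (default 20 times) and reruns the
pipeline from scratch per permutation. The validity statistic is
Rp² = √R² · √(R² − Rr²) with Rr² the mean permuted R²; it is flagged
undefined (NaN) when R² < Rr². This form reproduces the published triplet
(0.803, 0.773, 0.781) from inputs (0.701, −0.220), (0.719, −0.113),
(0.754, −0.056) within input-rounding tolerance.

Interpretation is generic: permutation importance (mean RMSE increase
over seeded column permutations) and quantile-grid partial dependence
(native levels for low-cardinality features, so a binary feature yields a
two-point grid).

## Stacking, applicability domain, screening

Meta-features are the base models' out-of-fold predictions — leakage-safe
stacking — and the ensemble is itself evaluated by nested CV of the
meta-learner (no selection stage); `"mean"` is accepted as a fit-free
meta-learner. At screening time, base models refit on the full training
set feed the meta-learner.

Applicability domains: for fingerprints, a query is inside iff its
**maximum** Tanimoto similarity to the training set strictly exceeds 0.20
(a mean-based variant is selectable, since "similarity to the training
set" is not pinned to one statistic); for descriptors, an isolation
forest (scikit-learn backend, 100 trees, 10 candidate split features)
with the canonical 2^(−E[h]/c(n)) anomaly score and the standard 0.5
anomaly boundary — inside iff score < 0.5.

Screening aggregates, per library compound, only the predictions of
models whose AD contains it: mean, median and relative standard
deviation (100·sd/mean, sample sd; undefined below two inside-AD models).
Compounds outside every AD stay in the output with n_inside = 0 and no
aggregate; unfeaturizable compounds are excluded and logged, not fatal.
The summary reports hit counts at a pIC50 threshold (default 8 ⇔ 10 nM),
the AD-coverage distribution over 0..M models, and the RSD distribution.
Hit rates are half-up rounded to 2 decimals.

## Synthetic data

The generator emulates the statistical structure of a curated QSAR
dataset, not its chemistry: block-exchangeable latent gaussians (default
within-block correlation 0.3, blocks of 10) thresholded to bits with
marginal frequencies in [0.05, 0.6] for the fingerprint case; planted
constant, quasi-constant (single rare off-value) and redundant (|r| > 0.9
noisy copies) columns; and a sparse linear response over a recorded
active set, affinely mapped to mean 6 / sd 1.5 (a realistic pIC50 span),
with noise either given directly or derived from a target generative
signal fraction R*² = Var(signal)/(Var(signal)+σ²) (default 0.75). A
small hand-written curation fixture (~30 rows) carries duplicate groups,
an acid/salt pair and malformed rows, with a manifest of expected counts.

Because the generator's response is (sparse) linear-plus-noise over
exchangeable gaussian features, passing tests demonstrate leakage-free
estimation and selector correctness under known ground truth — they do
not demonstrate accuracy on real activity cliffs, assay noise
heterogeneity, or scaffold-clustered chemical space, none of which the
generator emulates.

## Problem sizes used in the shipped checks

The end-to-end statistical checks run at n = 300, p = 50, 5 informative
features, generative R*² = 0.75, outer 5 × inner 3 folds, 5 seeds (and 5
permutations for the randomization null). Inside these runs Boruta uses
50 iterations and 50-tree forests — the signal there is strong enough
that decisions are made within the first ~15 iterations, and the
remainder of the default budget only churns on permanently tentative
features. Planted-truth recovery checks use independent features
(block correlation 0): under block correlation, non-planted blockmates
genuinely carry signal, so "false confirmation" would be ill-defined for
an all-relevant selector.

## Known limitations

- No BART backend ships with the package; the three published BART-based
  models can only be mirrored with the other registered learners.
- The descriptor-provider interface expects precomputed tables; no
  in-package 2D descriptor engine beyond MACCS keys.
- The similarity AD statistic ("max" vs "mean") and the fifth
  drug-likeness criterion are configurable because the conventions they
  mirror are not uniquely determined; defaults are the strictest common
  readings.
- Greedy MI filters inherit plug-in estimation bias at small n; the
  binning default (10 equal-frequency bins) is a desk-scale compromise.
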