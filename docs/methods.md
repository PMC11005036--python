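# Methods

`qsarkit` is a QSAR/QSPR pipeline for ligand-based activity prediction:
given only a SMILES string, it predicts receptor binding affinity
(pKi, the negative decadic logarithm of the inhibition constant Ki) for
serotonergic targets, or a binary ADME property such as blood–brain
barrier (BBB) penetration, together with an applicability-domain
verdict for every prediction.  This note records the models and
procedures, the choices made where the design was genuinely open, and
what the synthetic fixtures do and do not establish.

## Data curation

Bioactivity tables are assumed to come from two databases: a reference
source ("ZINC") and a secondary one ("ChEMBL").  Curation runs in a
fixed order:

1. **Structure validation.**  A record whose SMILES does not parse is
   dropped and audit-logged.  Parseable structures are canonicalized.
   Nothing else is done to structures — no salt stripping,
   neutralization or tautomer normalization — so what the model sees is
   exactly what the databases report.
2. **Within-source deduplication.**  Identical (SMILES, pKi) records
   collapse to one.  A molecule measured several times with different
   pKi in one source is merged to the **median** value: the median is
   order-independent and robust to a single aberrant entry, and the
   merge is audit-logged.  For binary endpoints, agreeing labels
   collapse and conflicting labels drop the molecule.
3. **Cross-database reconciliation.**  For molecules present in both
   sources, |ΔpKi| ≤ 0.1 keeps a single record carrying the reference
   (ZINC) value; |ΔpKi| > 0.1 is treated as evidence of assay
   incompatibility and the molecule is removed.  The boundary case
   0.1 itself is kept.  Inter-laboratory reproducibility of Ki
   measurements is rarely better than ~0.1–0.5 log units, so a 0.1
   cutoff retains only cross-database agreements tighter than typical
   experimental error.
4. **Split.**  An unstratified uniform random 80:20 train/test split
   with |train| = ⌊0.8·N + 0.5⌋; the seed is a required, recorded
   parameter.  Single-label endpoints (BBB) skip step 3.

Every input record ends up in the audit log as kept, merged or dropped;
conservation of records is asserted in tests.

## Molecular representation

Molecules are represented by RDKit's 2D descriptor set (~210
descriptors: atom/bond/ring counts, topological and connectivity
indices, Crippen logP/MR, TPSA, Estate and VSA bins, fragment counts).
Only graph-derived (2D) descriptors are used: conformer-dependent 3D
descriptors introduce optimization variability that 2D descriptors
avoid, and the representation stays a pure function of the canonical
SMILES.  A descriptor that raises or returns a non-finite value is
flagged as *failed*, never silently zeroed.

**Feature filtering** is fit on training data only:

* columns that are constant on the training set, or failed on more than
  50% of training molecules, are dropped first;
* then pairs with |Pearson r| > 0.95 (configurable) are pruned greedily
  in alphabetical name order, dropping the later-named member, so the
  outcome is deterministic.  The filter report records, for every
  pruned column, the kept partner that now represents it.

The frozen report — kept columns plus their training medians for
imputing failed cells — is applied unchanged to test sets and
prediction batches, which is what keeps test-set information out of
every modelling choice.  The exact number of surviving descriptors
depends on the descriptor-set version and the training molecules; it is
recorded in the model bundle, not asserted against any fixed value.

## Models

Both tasks use gradient-boosted decision-tree ensembles found by a
bounded random search, emulating an AutoML workflow at a configurable
budget (default 32 candidates; scalable upward):

* each candidate is an XGBoost or LightGBM learner with hyperparameters
  drawn from log-uniform/uniform ranges (learning rate 0.025–0.28,
  80–300 trees, depth 3–8 or 15–63 leaves, row/column subsampling,
  L2 regularization);
* every candidate is scored by its pooled out-of-fold predictions under
  a shared 10-fold cross-validation assignment — RMSE for regression,
  log loss for classification;
* a Caruana-style forward-selection ensemble (selection with
  replacement, max 10 picks) is grown on the out-of-fold predictions;
  the single best candidate is the degenerate one-member ensemble;
* the selected members are refitted on the full training set and
  combined with the selection weights.

Classification ensembles combine **raw margins** (log-odds), not
probabilities: the weighted-mean margin passes through a single
sigmoid.  This makes the ensemble additive in its members, so the exact
TreeSHAP attributions of the members combine linearly into exact
attributions for the ensemble (local accuracy holds by construction).
The decision threshold is fixed at probability 0.5.

All stochastic components — fold shuffling, hyperparameter sampling,
learner seeds — derive from one master seed recorded in the bundle, and
learners run single-threaded in deterministic mode, so training is
bit-reproducible for a given seed.

Cross-validation metrics are reported **pooled**: one RMSE/R² (or one
confusion matrix) over all out-of-fold predictions, giving a single
number per endpoint; per-fold values are retained alongside for
dispersion.  External-test metrics come from the refitted final model.

## Evaluation metrics

RMSE, R² = 1 − SS_res/SS_tot, accuracy, precision, recall, F1 and the
Matthews correlation coefficient are implemented from their defining
formulas and cross-checked in the tests against explicit-loop
recomputation (1,000 random inputs, 1e-12 relative) and against
scikit-learn.  Zero-denominator conventions: precision/recall/F1 and
MCC return 0.0 with a `degenerate` flag when their denominator
vanishes.  R² raises when all observed values coincide (SS_tot = 0).

## Applicability domain

The domain of a trained model is defined by its ten most influential
descriptors, ranked by **mean absolute Shapley attribution** over the
training set.  Attributions come from the exact TreeSHAP algorithm
built into XGBoost and LightGBM, combined by ensemble weight; ties in
the ranking break alphabetically.  For each of the ten descriptors the
training-set minimum and maximum are stored (inclusive bounds: the
extrema are observed values).  A query molecule is **in domain** when
at least 7 of the 10 values fall inside their training range; missing
or non-computable values count as out of range (conservative).  Min–max
normalization of the ranges is available for reporting and plotting;
membership is tested on the raw bounds, which is mathematically
identical.  By construction every training molecule scores 10/10.

If an estimator type without a TreeSHAP backend is ever plugged in,
`shapley_rank` refuses with an error naming the documented fallback
(`permutation_rank`, mean increase in squared error under column
permutation) rather than silently switching.

## Prediction modes

Single-molecule and batch modes share one engine: descriptors are
computed once per molecule and reused across endpoints, so batch and
single predictions agree to the last digit.  Batch CSVs must carry a
column named exactly `smiles` (lowercase; a case-mismatch produces an
error suggesting the rename).  Output preserves input row order and
pass-through columns, formats pKi and probabilities to 3 decimals,
writes AD verdicts as the literal strings `True`/`False`, and flags
unparseable rows with `INVALID_SMILES` instead of dropping them.

Model bundles (estimator, descriptor vocabulary, filter report with
imputation medians, AD reference, CV metrics, config) are persisted as
versioned joblib archives; the format version is checked on load, and a
reloaded bundle reproduces predictions bit-identically.

## Synthetic fixtures

Real curated bioactivity tables are large fixed-date database extracts
and are not shipped; every stage is instead exercised on generated
data with known ground truth:

* **Molecules** come from a deterministic enumeration of ~4,100
  substituted aryl-alkyl amines/alcohols (5 aromatic cores × 14 ring
  substituents × 6 chain lengths × 2 branchings × 5 head groups),
  guaranteeing validity and canonical uniqueness without a rejection
  loop.  A seed selects a random subset.
* **Regression labels** are a linear function of three *real computed
  descriptors* (standardized MolLogP, TPSA, NumRotatableBonds with
  coefficients 1.0, −0.7, 0.5) passed through a bounded tanh link —
  pKi = 7 + 3.2·tanh(score/2) — giving mean 7 and spread ≈1.4 log
  units inside the [3, 12] envelope typical of receptor-affinity
  tables, plus Gaussian noise (default σ = 0.3, a plausible scale for
  inter-assay variability).  The generative coefficients are returned
  for recovery tests.
* **Classification labels** are Bernoulli draws from a logistic model
  on the same score, thresholded at the quantile matching the requested
  class balance (default 0.5).
* **Dual-source sets** give every molecule a reference record and a
  secondary record shifted by 0.05 (within the reconciliation
  tolerance) or, for a seeded 20% of pairs, by 0.2 (beyond it), so
  curation outcomes are known exactly by construction.

Because the signal is planted in computed descriptors, the correlation
filter may prune a planted descriptor in favour of a highly correlated
kept partner (on this family NumRotatableBonds is absorbed by Kappa2 at
|r| ≈ 0.96); recovery checks therefore follow the filter report's
surrogate mapping.  What the fixture *does* establish: the pipeline
recovers planted signal down to the noise floor, ranks the signal
carriers at the top of the Shapley ordering, and finds nothing in
label-shuffled nulls.  What it does *not* establish: performance on
real SAR landscapes, which have activity cliffs, assay heterogeneity
and chemotype clustering that a smooth three-descriptor function cannot
emulate; published-table metrics are only reproducible from the
original curated datasets.

## Problem sizes and runtime choices

Default study conditions: n = 2,000 molecules (1,600 train / 400
test), σ = 0.3, 10-fold CV, 32-candidate search — about six minutes of
single-core compute for the full regression pipeline.  The
label-shuffled null retrains with a budget of 8: a null check needs *a*
model of the same family, not the full search.  The classification
fixture uses n = 1,000 and budget 16.  Unit tests run on 120-molecule
subsets with 4–5 folds and budgets of 2–4, which keeps the whole suite
fast while the acceptance-grade run exercises the full conditions.

## Known limitations

* Descriptor vocabulary is the RDKit 2D set; models trained with other
  descriptor sets (or versions) are not interchangeable — the bundle
  records its descriptor-set tag and refuses mismatched inputs.
* The min–max AD is a box criterion: it ignores correlations between
  descriptors and can declare in-domain a molecule far from the
  training manifold inside the box.  Distance- or leverage-based AD is
  deliberately out of scope.
* The search space contains tree ensembles only; endpoints whose
  response is better served by other model families are not covered.
* Cross-parser canonical SMILES differ; canonical forms are stable only
  within the RDKit backend used here.
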