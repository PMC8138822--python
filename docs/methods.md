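# Methods

Statistical and numerical methodology behind `fibroscreen`, with the
reasoning for every default. Defaults are chosen for screening-scale
problems (hundreds to low thousands of compounds, up to a few hundred
features) on a single CPU; all are overridable.

## 1. Featurization

### 1.1 Structural: MACCS fingerprints

A compound's structure is encoded as the 166 MACCS substructure keys.
RDKit's generator returns 167 bits with bit 0 permanently unused; the
featurizer drops bit 0 and exposes bits named `maccs_1` … `maccs_166`,
so the feature dimensionality is exactly 166 for every valid molecule.
Similarity between fingerprints is Tanimoto,
`|A ∩ B| / |A ∪ B|` over set bits, defined as 0 when both fingerprints
are empty (the only case where the ratio is 0/0).

### 1.2 Biological: quantile rank transform and Spearman

Expression profiles from different platforms are not on a common scale.
Each profile is therefore rank-transformed per sample:
`value → (average rank − 1)/(n − 1)`, with ties sharing the mean of
their ranks (midranks). The minimum maps to 0, the maximum to 1, and
the transform is invariant under any strictly increasing distortion of
the input — which is exactly the class of distortions that scanner
scaling and log-transform differences introduce. A constant profile is
degenerate (all 0.5) and triggers a warning rather than an error.

Profile similarity is Spearman correlation computed as Pearson on
midranks over the intersection of gene identifiers (at least 3 shared
genes required; fewer raises `InsufficientOverlapError`, zero rank
variance raises `UndefinedCorrelationError`). Gene identifiers can be
remapped (probe → entrez → symbol) with a composable `GeneIdMap`;
many-to-one mappings aggregate by mean (median/max available).

## 2. Sample quality control

Each label class is screened separately with a one-class SVM (RBF
kernel). The parameter ν upper-bounds the fraction of training samples
that can fall outside the learned boundary, so ν is a direct, auditable
cap on how much of each class QC may discard; the default ν = 0.3
matches the expectation that curated positive sets contain a
substantial minority of atypical members. Fitting is per class because
a single boundary over both classes would conflate class structure with
sample quality.

### 2.1 Kernel bandwidth

The default bandwidth is a *wide* variant of the median heuristic:
`gamma = 1 / (10 × median squared pairwise distance)`, computed on a
seeded subsample of at most 200 rows. The common `1/(d·Var)` rule
("scale") produces a kernel narrow enough that a gross outlier many
cloud-radii from the data becomes its own self-supported boundary
island: its dual coefficient saturates, its decision value is exactly
0, and it is *not* flagged. The wide kernel keeps such points in
low-density territory where their decision value is clearly negative.
Because the median pairwise distance scales with the data, the kept set
is invariant to uniform positive rescaling of the features — the same
property that motivates the `1/(d·Var)` rule. `"scale"` and explicit
floats remain available. The solver tolerance is tightened to 1e-8 so
boundary decisions are stable across platforms.

### 2.2 Finite-sample behavior of the ν bound

ν bounds the fraction of *margin errors*; samples numerically on the
boundary (decision ≈ −0) can push the flagged fraction slightly above
ν, particularly with small classes or duplicate rows (binary
fingerprints). Empirically on continuous Gaussian classes of 100+
samples the excess stays within 0.02–0.05; the test suite asserts the
bound with that slack. Classes smaller than 10 samples are refused
(`QCError`) rather than filtered unreliably.

## 3. Modeling

### 3.1 Split

Default split is 70/30, stratified, with the training size computed as
`round(0.7 · n)` so the configured fraction is met exactly. When
per-sample compound groups are supplied (several expression profiles of
the same compound), a grouped split keeps all profiles of one compound
on the same side, preventing leakage of compound identity across the
split; the splitter retries a few seeds to find a grouped split whose
class balance is acceptable and raises `StratificationError` otherwise.

### 3.2 Candidate algorithms

Five classifiers are compared: L1 logistic regression, L2 logistic
regression, decision tree, random forest, gradient boosting. All
candidates are evaluated on the *same* stratified 5-fold partition of
the training set so their CV scores are paired. Selection is by mean
CV AUC, ties broken by mean precision, then by fixed algorithm order —
a deterministic rule with no data-dependent randomness.

Fixed hyperparameters (screening-scale choices):

| algorithm | settings |
|---|---|
| logistic (L1/L2) | C = 1.0, liblinear, max_iter = 1000 |
| decision tree | max_depth = 5 |
| random forest | 50 trees, min_samples_leaf = 5 |
| gradient boosting | 50 rounds, learning rate 0.2, depth 2, subsample 0.5, max_features √p |

The ensemble sizes are deliberately lean: iterative feature elimination
(below) refits 5 CV folds at every subset size — about 830 fits for a
166-feature corpus — and these settings keep a full structural-corpus
pipeline run (QC → split → selection → IFE → final fit) in the tens of
seconds to low minutes on one CPU while leaving holdout AUC on planted-
signal corpora in the 0.95+ range. Larger ensembles are a one-line
override (`CandidateSpec("random_forest", {"n_estimators": 500})`).

### 3.3 AUC

AUC is computed as the Mann–Whitney rank statistic: the probability
that a random positive outranks a random negative, with ties counting
one half. The implementation is closed-form on midranks; the test
suite verifies it against exhaustive pair enumeration to 1e-12.

### 3.4 Iterative feature elimination (IFE)

Starting from all features, one feature is removed per step — the one
with the smallest model importance (|coefficient| for linear models,
impurity-based importance for trees/ensembles). Features whose
importance is exactly zero are dropped as a batch; removing them cannot
change the fitted model, so the skipped sizes inherit the current
score.

The AUC-versus-subset-size curve is estimated with *nested* fold-wise
elimination: each stratified fold runs its own greedy elimination using
only that fold's training half and scores every subset size on its
held-out half; the curve is the fold average. This matters: if the drop
decisions could see the held-out samples (e.g. by averaging importances
over fits on all folds and scoring on those same folds), the surviving
features would be chance-correlated with the evaluation data, and on
label-independent inputs the curve drifts far above 0.5 — the classic
feature-selection leak. With nested elimination the curve stays near
0.5 on null data, inflated only by the small max-over-sizes selection
effect.

The optimal size is the smallest attaining the maximum of the averaged
curve (parsimony among equivalent sizes). The reported elimination
order and the final feature subset come from one further elimination
pass on the full training set, so the deployed model uses all training
information — the same refit-after-nested-selection design as
scikit-learn's RFECV.

### 3.5 Final model and scores

The selected algorithm is refit on the training split restricted to the
optimal subset. The repositioning score of a candidate is the
classifier's positive-class probability; candidates with score ≥ 0.5
are labeled `anti_fibrosis`. Models serialize to a directory
(estimator via joblib, feature list, JSON metadata including a
configuration hash) and round-trip bit-identically.

## 4. Mechanism networks

For a query structure, the most similar knowledge-base compounds are
found by Tanimoto over MACCS keys (default threshold 0.5, top 10) or by
Spearman over rank profiles (default 0.6). The network is a typed
multigraph: query → similar compounds (similarity edges carrying the
score), compounds → targets/diseases and targets → diseases (each edge
backed by an explicit evidence link with source and reference). Raising
the similarity threshold can only remove compounds and therefore
monotonically shrinks the network. Exports: node-link JSON with
deterministic ordering, GraphML, and a flat TSV edge list; JSON and
GraphML re-import losslessly.

## 5. Synthetic data

The generators are pure functions of a frozen config (including the
seed) and return their ground truth alongside the data, so recovery is
testable.

*Structural*: binary 166-bit rows; informative bits fire with
probability `base_rate + effect_size` in positives versus `base_rate`
in negatives (defaults 0.75 vs 0.25, a single-bit marginal AUC ≈ 0.75 —
strong but not trivial signal); a small fraction (2%) of rows is
redrawn with bit rate 0.95, emulating corrupted or mis-registered
entries far outside the fingerprint density.

*Biological*: Gaussian profiles grouped 2–6 per synthetic compound
(mimicking perturbation compendia); planted genes shifted by the effect
size in noise-SD units in positive-compound profiles; batches apply an
additive shift plus a positive exponential scaling — a monotone
distortion that the rank transform provably removes, which the tests
assert; outlier profiles receive an 8-SD displacement.

A toy knowledge base accompanies each corpus: its compounds are exactly
the corpus positives plus decoys (with valid SMILES drawn from a
bundled 130-molecule fixture library), so labeling the corpus against
the KB reproduces the generator's labels, and mechanism queries resolve
end to end.

Default corpus sizes (500/500 structural, 200/200 × 300-gene
biological) are the package's screening-scale choice: large enough that
CV AUC estimates are stable and planted-feature recovery is
reproducible across seeds, small enough that full-pipeline property
tests run in minutes on one CPU.

## 6. Determinism

Every stochastic step takes an explicit seed: corpus generation, QC
subsampling, splitting, fold construction, and each estimator. CLI
commands resolve their configuration (flags > config file > defaults),
write the resolved snapshot next to their outputs, and replaying from
the snapshot reproduces outputs byte for byte.

## 7. Limitations

- The classifiers are screening tools; a high repositioning score is a
  hypothesis generator, not evidence of efficacy, and the 0.5 label
  threshold is a convention, not a calibrated decision boundary.
- Scores are not calibrated probabilities (no isotonic/Platt step);
  compare scores within one model, not across models.
- MACCS keys are coarse; structurally novel scaffolds can score poorly
  despite relevant biology (the biological model is the complement).
- The ν bound of QC is a cap on removal, not a guarantee that what is
  removed is truly artifactual; on very small or heavily duplicated
  classes the flagged fraction can exceed ν by a small finite-sample
  margin.
- IFE's importance ranking is model-relative; correlated informative
  features can shadow one another, so the optimal subset is one
  near-optimal subset, not the unique causal set.
- Grouped splitting removes within-compound leakage, but knowledge-base
  curation bias (which compounds got studied) is inherited by any model
  trained on it.
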