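# fibroscreen

Machine-learning toolkit for anti-fibrosis drug repositioning.

Fibrotic diseases — idiopathic pulmonary fibrosis, liver cirrhosis,
kidney and cardiac fibrosis — share core biology (TGF-β signalling,
myofibroblast activation, extracellular-matrix deposition) but have very
few approved drugs. Repositioning existing compounds toward
anti-fibrosis indications is attractive because known drugs have known
safety profiles. `fibroscreen` implements a knowledge-base-driven
screening pipeline for that problem:

1. **Knowledge base** — a curated, referentially validated collection of
   known anti-fibrosis compounds, fibrosis-related targets and diseases,
   and typed evidence links among them. The compounds define the
   positive class for supervised learning.
2. **Featurization** — two complementary views of a compound:
   *structural* (166-bit MACCS substructure fingerprints computed from
   SMILES with RDKit, compared by Tanimoto similarity) and *biological*
   (compound-induced gene-expression profiles, made platform-comparable
   by a per-sample quantile rank transform and compared by Spearman
   correlation over shared genes).
3. **Sample QC** — before training, each label class is screened for
   outlying samples with a one-class SVM (ν = 0.3 by default); ν
   upper-bounds the fraction of a class that can be removed.
4. **Modeling** — stratified 70/30 train/test split, five candidate
   algorithms (L1/L2 logistic regression, decision tree, random forest,
   gradient boosting) compared by stratified 5-fold cross-validated AUC
   on shared folds, then iterative feature elimination (IFE): features
   are dropped one at a time by model importance, the CV AUC is recorded
   at every subset size, and the smallest subset achieving the maximum
   CV AUC is kept for the final fit. The fitted classifier's positive
   probability is the **repositioning score** in [0, 1]; compounds
   scoring ≥ 0.5 are labeled `anti_fibrosis`.
5. **Mechanism** — for a query compound, a typed network linking it to
   its most similar knowledge-base compounds and onward to their known
   targets and diseases, with every non-similarity edge traced to an
   evidence link. Exportable as JSON, GraphML or TSV.
6. **Synthetic data** — seeded generators for structural and biological
   corpora with planted ground truth (informative features, outliers,
   batch structure), so the whole pipeline is testable offline.

The structural and biological classifiers are called **SPPM** and
**BPPM** (Structural / Biological Profile Prediction Model).

## Worked example

Train an SPPM on a synthetic structural corpus with planted signal and
score candidates (all seeded, so this reproduces exactly):

```python
from fibroscreen import RepositioningModel, SynthConfig, generate_structural_corpus

corpus = generate_structural_corpus(SynthConfig(n_pos=150, n_neg=150, seed=0))
results = RepositioningModel.from_corpus(corpus, seed=0).fit()
print(results.summary())
```

Output:

```text
SPPM (structural) — algorithm: random_forest
QC removed fractions: 0: 0.333, 1: 0.253
train/test sizes: 148/64

5-fold cross-validation (training set):
        algorithm  mean_auc  std_auc  mean_precision  mean_recall
      logistic_l1     0.958    0.029           0.882        0.909
      logistic_l2     0.921    0.042           0.832        0.872
    decision_tree     0.866    0.057           0.903        0.846
    random_forest     0.964    0.017           0.902        0.922
gradient_boosting     0.931    0.040           0.862        0.910

iterative feature elimination: optimal subset size 124 (max CV AUC 0.985)

holdout: AUC 0.970, precision 0.889, recall 0.941
```

Score candidates:

```python
scored = results.predict(corpus.matrix.values.iloc[:5])
print(scored.to_string(index=False))
```

```text
compound_id    score         label
    cmp0000 0.531063 anti_fibrosis
    cmp0001 0.532934 anti_fibrosis
    cmp0002 0.683871 anti_fibrosis
    cmp0003 0.768766 anti_fibrosis
    cmp0004 0.755856 anti_fibrosis
```

## Command line

The same pipeline is available as the `fibroscreen` CLI:

```bash
# generate a seeded synthetic corpus (features, labels, SMILES, toy KB)
fibroscreen simulate --modality structural --seed 0 \
    --n-pos 150 --n-neg 150 --out demo/corpus
# -> wrote corpus with 300 samples to demo/corpus

# QC, training (QC -> split -> CV selection -> IFE -> final fit), scoring
fibroscreen qc --features demo/corpus/features.csv \
    --labels demo/corpus/labels.csv --nu 0.3 --out demo/qc
fibroscreen train --features demo/corpus/features.csv \
    --labels demo/corpus/labels.csv --seed 0 --out demo/run
fibroscreen predict --model demo/run/model \
    --in demo/corpus/features.csv --out demo/scores.csv

# chemistry utilities
fibroscreen similarity --a "CC(=O)Oc1ccccc1C(=O)O" --b "OC(=O)c1ccccc1"
# -> 0.428571
fibroscreen mechanism --kb demo/corpus/kb \
    --query "CC(=O)Oc1ccccc1C(=O)O" --out demo/network.json
```

Every artifact-producing command writes a `resolved_config.yaml`
snapshot next to its outputs; re-running with
`--config resolved_config.yaml` replays the run byte for byte.

## Knowledge-base format

Four TSV tables: `compounds.tsv` (compound_id, name, smiles,
is_approved, sources), `targets.tsv` (target_id, symbol, entrez),
`diseases.tsv` (disease_id, name), `links.tsv` (subject_id, object_id,
link_type, source, reference) with link types `compound-target`,
`compound-disease` and `target-disease`. `fibroscreen build-kb`
validates referential integrity and duplicate links before writing a
canonical KB directory.

## Testing

```bash
python -m pytest -q tests/
```

The suite includes property-based checks (Hypothesis), brute-force
oracles for Tanimoto/Spearman/AUC, and an acceptance module
(`tests/test_acceptance.py`) covering the release criteria end to end.
`scripts/acceptance.py --seed 0 --out results/acceptance.json` reports
the flagged fraction of the default QC filter on a seeded Gaussian
sample.

See `docs/methods.md` for the full statistical methodology, parameter
choices and limitations.
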