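# targetrank

Genome-wide ranking of candidate therapeutic target genes for a cancer
type, from gene-level multi-omic features and the gene–gene interaction
network.

## The problem

Early-stage oncology drug discovery needs a ranked short-list of genes
worth pursuing as targets. Known targets (approved-drug targets with
curated interaction-type evidence, extended by cancer driver genes) are
few; every other protein-coding gene is unlabeled. `targetrank` frames
this as balanced binary classification: for a given cancer type it
contrasts the positive set *P* against ten pairwise disjoint "non-target"
sets *N₁…N₁₀*, each sampled without replacement from the non-positive
protein-coding genes with |Nᵢ| = |P|, and averages everything over the
ten replicates to reduce sampling variance.

Each gene *g* carries 35 features:

* three **primary** (cancer-type-specific) features — mutation rate
  (mean of binary somatic non-silent calls over tumor samples),
  expression (median over tumor samples), and essentiality (median
  CERES-like CRISPR sensitivity score over cell lines of the lineage);
* a 32-dimensional **network embedding** shared across cancer types:
  per source gene, random diffusion subgraphs of the interaction network
  are grown and their doubled-edge Euler tours emitted as sentences; a
  skip-gram model with negative sampling over this corpus places
  graph-proximal genes near each other in ℝ³².

The pipeline then runs, per negative set, on a stratified 70/30
train/test split:

1. **Univariate screen** — Mann–Whitney *U* per feature (positives vs
   pooled negatives, full data), Benjamini–Hochberg correction across the
   35 features.
2. **Feature selection** — random-forest information-gain importances
   compared against a null distribution from 100 label shuffles; the
   z-score *z = (real − μ₀)/σ₀* is averaged over the ten replicates and
   features with mean *z* ≥ 0.5 are retained.
3. **Model benchmarking** — random forest, logistic regression, SVM
   (cross-validated sigmoid probability calibration), gradient boosting,
   and a small neural network (two hidden layers, batch normalization,
   dropout 0.5), each tuned by stratified 5-fold CV on AUROC.
4. **Ensemble prediction** — the best method (highest 10-replicate mean
   test AUROC) is retrained on the full data of every replicate, and each
   non-positive gene receives the ensemble-mean target probability —
   using only the nine models that never trained on it if the gene sits
   in a negative set. Genes are ranked by mean probability (ties broken
   by symbol) and probabilities are additionally standardized to
   z-scores; a Spearman correlation against per-gene citation counts
   provides orthogonal validation.

Because the real inputs (tumor cohorts, CRISPR screens, curated
interaction and drug–gene databases) are external resources, the package
ships a first-class synthetic-scenario generator that emulates their
statistical shape — sparse Beta-distributed mutation rates, log-scale
expression, left-skewed essentiality, a scale-free community-structured
interaction graph — with a planted target set whose members differ from
background in configurable primary-feature effect sizes and in network
community membership. Three named scenarios (`null`, `signal`,
`community`) are used throughout the tests.

## Worked example

```sh
cat > config.yaml <<'YAML'
scenario:
  n_genes: 1000
  n_targets: 40
  mutation_effect: 3.0      # standardized shift of targets vs background
  expression_effect: 2.0
  essentiality_effect: 0.0  # planted as uninformative
  n_informative_modules: 3  # communities that concentrate targets
  cancer_label: demo
  seed: 42
regime: extended
grid_preset: fast
walks_per_node: 4
subgraph_size: 12
epochs: 3
n_shuffles: 30
seed: 42
YAML
targetrank run-all --config config.yaml --out demo_run
```

prints

```
best method: neural_net
mean test AUROC per method:
  random_forest: 0.993
  logistic_regression: 0.993
  svm: 0.996
  gbm: 0.949
  neural_net: 0.997
ranked genes: 960
citation Spearman rho=0.398 p=9.2e-38
```

All five classifiers separate the planted targets nearly perfectly (the
scenario shifts target mutation rates by 3 SD and expression by 2 SD);
feature selection kept `mutation`, `expression` and one embedding
dimension while correctly discarding the zero-effect essentiality
feature (`demo_run/selected_features.txt`). The ranking
(`demo_run/ranking.tsv`) covers the 960 genes with complete data that
are not positives:

```
gene    mean_probability        n_models  zscore  rank
G00704  0.991181379710538       9         4.943630039236588  1
G00583  0.987090562976338       10        4.921675284334574  2
G00435  0.9790549095554008      9         4.878549225946454  3
```

`n_models` is 9 exactly for genes that belong to one of the ten negative
sets (the model that saw them as training non-targets abstains) and 10
otherwise. The positive citation correlation reflects the generator's
literature bias toward genes with striking genomics.

Other subcommands (`simulate`, `embed`, `build`, `screen`, `select`,
`train`, `evaluate`, `predict`, `fixtures`) expose the individual stages;
`python -m targetrank.cli --help` lists them.

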