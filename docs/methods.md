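# Methods

This note documents the models, defaults and numerical choices behind
`targetrank`, and what the synthetic scenarios do and do not establish.

## Study design

The unit of analysis is one cancer type. The positive set is the union
of approved-drug target genes that carry explicit interaction-type
evidence (which excludes untargeted chemotherapies and off-target hits)
and cancer driver genes; duplicates collapse. Ten negative sets of the
same size are drawn without replacement from the non-positive
protein-coding genes with complete feature data, pairwise disjoint, so
that ten parallel balanced datasets share the same positives and never
reuse a negative. Treating randomly sampled genes as non-targets is an
approximation; true targets are assumed rare enough that contamination
of the negatives is negligible.

Each dataset is split 70/30 by stratified sampling (per class,
`round(0.7·n)` genes to train, round-half-even). Feature selection and
model tuning see only training rows; the test rows serve model
evaluation and best-method choice; the union of both is used for the
univariate screen and for retraining the final ensemble.

One master seed drives everything. Sub-seeds for negative sampling,
per-replicate splits, label shuffles and model fits are derived through
`numpy.random.SeedSequence(master, spawn_key=...)` children — a
collision-free variant of fixed seed offsets with the same
reproducibility contract: identical configuration gives byte-identical
outputs. The embedding stage, which is cancer-type independent and the
slowest step, is cached in the run directory under a content hash of the
edge list and its parameters.

## Network embedding

The interaction network is undirected, with self-loops and duplicate
edges dropped at load time. Per source node and repeat, a random
diffusion subgraph is grown: repeatedly pick a uniformly random
already-included node that still has neighbors outside the subgraph,
then a uniformly random such neighbor, until `subgraph_size` nodes are
included or the reachable neighborhood is exhausted. The resulting
random tree, with every edge doubled, admits an Euler circuit; its
depth-first traversal (emitting a node on entry and on every return) is
one sentence. Isolated nodes yield singleton sentences and end up with
zero vectors.

A skip-gram model with negative sampling is trained on the sentence
corpus: vectors of dimension d = 32, symmetric context window, negatives
drawn from the unigram distribution raised to 3/4, minibatch SGD with a
linearly decaying learning rate (initial 0.025), float32 parameters.
Minibatch accumulation approximates sequential updates only while index
collisions per batch are modest, so the effective batch is capped at
`max(64, 2·vocabulary)`; without the cap, training on very small graphs
can diverge. Training is single-threaded and deterministic per seed.

Defaults: `walks_per_node = 10`, `subgraph_size = 40`, `window = 5`,
`epochs = 5`, `negative = 5`. The bundled scenarios use
`walks_per_node = 4`, `subgraph_size = 12`, `epochs = 3`, which keeps a
full run on a ~2,000-gene graph under a minute while still separating
planted communities cleanly (nearest-centroid block accuracy 1.0 on a
two-block planted-partition toy graph). No interpretation of individual
embedding dimensions is attempted.

## Statistics

* **Univariate screen** — two-sided Mann–Whitney–Wilcoxon per feature,
  positives (counted once) against the ten negative sets pooled, on the
  full dataset. Exact enumeration for tie-free groups of at most 8,
  otherwise the tie-corrected normal approximation. The
  Benjamini–Hochberg family is the feature set of one cancer type (35
  features, or 3 in the primary regime).
* **Permutation-null feature selection** — a fixed random forest (100
  trees, entropy criterion, i.e. information-gain importances,
  unlimited depth) is fitted per training split; its importances are
  compared with those of forests refitted after uniformly permuting the
  labels (100 shuffles by default, each with a fresh derived seed). The
  importance forest is deliberately not tuned: the z statistic is a
  ratio against a null matched in every respect except the labels, so
  stability matters more than raw accuracy, and 100 trees keep the
  100-shuffle null affordable. A numerically zero null SD caps z at ±10
  (0 if the real importance equals the null mean) with a logged warning.
  Features with mean z ≥ 0.5 (inclusive) over the ten replicates are
  retained; an empty selection raises rather than silently passing all
  features through.

## Classifiers

Five families, each exposed behind a common probability interface and
tuned by stratified 5-fold cross-validation on mean AUROC (grids ordered
simplest-first; ties keep the earliest grid point; one-point grids skip
CV). Scale-sensitive models are preceded by standardization.

| method | default grid |
| --- | --- |
| random forest | trees {100, 300, 500} × depth {3, 5, ∞} × max-features {√p, p} |
| logistic regression | no tuning |
| SVM | linear C {0.1, 1, 10}; RBF C {0.1, 1, 10} × bandwidth scale-heuristic × {0.5, 1, 2} |
| GBM | learning rate {0.01, 0.1} × trees {100, 300} × depth {2, 3} |
| neural net | Adam learning rate {0.003, 0.01} |

The SVM obtains probabilities from an explicit cross-validated sigmoid
calibration layer. The neural network is a compact numpy implementation:
two hidden layers (64, 16), batch normalization before rectifier
activations, dropout probability 0.5 after each hidden layer, Adam on
the binary cross-entropy, early stopping on a stratified 10% validation
slice (patience 25 epochs, best weights restored), inputs standardized
internally, fully deterministic per seed. These architecture choices
are declared defaults for the small-tabular-data regime and are
config-overridable. The bundled scenarios use one-point "fast" grids;
the full grids remain the package default.

The best method is the argmax of the ten-replicate mean test AUROC; it
is retrained per replicate on train + test rows with the tuned
hyperparameters, giving the ten-model ensemble used genome-wide.

## Prediction and validation

Every gene with complete data except the positives is scored by the
ensemble mean; genes inside a negative set use only the other nine
models. Ranks are 1-based, descending in mean probability, ties broken
lexicographically by gene symbol for reproducible output files. The
ensemble-mean probabilities are standardized to z-scores (mean 0, SD 1
over the ranked genes); standardization is applied after averaging, not
per model. With balanced training data the fraction of genes above
probability 0.5 is large and is logged as a diagnostic only — the
product is the ranking, and no probability calibration is attempted.

Citation validation samples 1,000 ranked genes (all, with a warning, if
fewer exist) and reports the Spearman correlation between predicted
probability and citation count; genes missing from the citation table
count as 0, logged. Across multiple cancer types the p values are BH
corrected.

## Synthetic scenarios

The generator emulates the statistical shape of per-cancer aggregates,
not their biology:

* **Mutation** — per-gene Bernoulli rate drawn from Beta(1.5, 25)
  (mode ≈ 0.02, matching somatic mutation sparsity), shifted for targets
  by `mutation_effect` background SDs; rates clipped to [0, 1] with a
  warning (clipping, not resampling — a small documented bias at extreme
  effects); binary calls per sample; aggregated as the mean.
* **Expression** — gene-level mean from Normal(3, 1.5) on a log-like
  scale, within-gene sample SD 1, aggregated as the median.
* **Essentiality** — gene-level mean from a left-skewed normal
  (skew −5, location 0.1, scale 0.6), mimicking CERES semantics
  (negative = dependency); a positive effect shifts targets toward more
  negative scores; default effect 0, making the feature a planted
  negative control.
* **Network** — Chung–Lu wiring with bounded-Pareto degree propensities
  (heavy-tailed degrees) and block structure: 12 communities by default,
  cross-community edge weight `community_mixing = 0.08`, expected mean
  degree 8. When `n_informative_modules > 0`, 90% of targets are placed
  in that many designated communities, so the class signal travels
  through community membership rather than degree — by design the
  embedding, not a trivial connectivity feature, is what can carry it.
* **Citations** — log-normal counts whose log-intensity includes
  0.4 × the gene's standardized mutation and expression values
  (literature is biased toward genes with striking genomics) with a 3×
  multiplier for planted targets. Under a null scenario the features
  carry no class signal and citations are uninformative by construction.

Scenario marginals are stipulated, not fitted to any cohort: real
feature distributions, mutation signatures, co-expression structure and
cancer-type-specific biology are out of scope. Passing tests therefore
establish that the pipeline recovers signal of the planted kind at the
planted strength — not that it attains any particular accuracy on real
cohorts.

Named scenarios (sizes chosen within the range of real per-cancer
positive-set sizes, with the universe ≥ 22× the positive set so the ten
disjoint negative sets always fit with attrition headroom):

* `null` — 2,200 genes, 100 targets, all effects 0, targets wired
  randomly. Used for calibration: every classifier's mean test AUROC
  should sit at chance, and permutation z-scores should center on 0.
* `signal` — 2,000 genes, 80 targets, mutation +3 SD, expression +2 SD,
  essentiality 0, targets concentrated in 3 of 12 communities.
* `community` — as `signal` but with all primary effects 0: the class
  signal is purely network-borne, isolating the value of the embedding
  features over the primary-only regime.

## Problem sizes in the repeated-seed checks

The calibration and recovery checks that loop over 10 master seeds use
reduced per-iteration sizes — 20 label shuffles, 50-tree importance
forests, and a minimal walk budget (2 walks per node, subgraph 8, 1
epoch) — because the measured quantities (the null mean of z; retention
of features planted at ≥ 2 SD, whose z-scores are an order of magnitude
above threshold) are insensitive to these sizes. Single-run checks use
the scenario defaults above. All thresholds and tolerances are stated
independently of these sizes.

## Known limitations

* The negative-set assumption (random genes are non-targets) is
  optimistic; the synthetic generator plants the same assumption, so the
  tests cannot detect its violation.
* Balanced training on a rare-positive problem produces uncalibrated
  probabilities; only ranks are meaningful.
* The diffusion-walk + skip-gram embedding is stochastic; the strict
  determinism contract holds single-threaded with a fixed seed, and
  embedding quality at the reduced scenario walk budgets is sufficient
  for community recovery but not converged in any stronger sense.
* `assemble_feature_table` drops genes with any missing primary feature
  or without an embedding row before negative sampling, so negative
  sets are drawn from the complete-data pool; per-cancer attrition of
  positives is logged, mirroring the "genes with data" accounting of
  real cohorts.
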