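"""Synthetic multi-omic scenario generator.

Produces seeded gene universes, sample-level mutation / expression /
essentiality matrices, a sparse scale-free interaction network with
community structure, and a planted set of "target" genes that differ from
the background in configurable primary features and in network
neighborhood.  The generator emulates the statistical shape of per-cancer
aggregates built from tumor cohorts (binary somatic mutation calls,
log-scale expression) and CRISPR knock-out screens (CERES-like scores
centered near zero with a negative tail); it makes no attempt to model
cancer-type-specific biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats

__all__ = [
    "ScenarioConfig",
    "TargetSet",
    "SampleMatrix",
    "Scenario",
    "generate_universe",
    "generate_network",
    "generate_sample_matrices",
    "aggregate_samples",
    "generate_scenario",
    "write_scenario",
]

# Background distributions for the three primary features.  Mutation rates
# are Beta-distributed with mode ~0.02 (somatic mutation sparsity);
# expression is a log2-like location-scale normal; essentiality is a
# left-skewed normal centered near zero (negative = loss of proliferation
# on knock-out).
_MUT_A, _MUT_B = 1.5, 25.0
_EXPR_LOC, _EXPR_SCALE = 3.0, 1.5
_ESS_SKEW, _ESS_LOC, _ESS_SCALE = -5.0, 0.1, 0.6


def _beta_sd(a: float, b: float) -> float:
    return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0))))


def _skewnorm_sd(a: float, scale: float) -> float:
    delta = a / np.sqrt(1.0 + a * a)
    return float(scale * np.sqrt(1.0 - 2.0 * delta * delta / np.pi))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of a synthetic study.

    Effect sizes are standardized mean shifts (in units of the background
    SD of the gene-level latent value) of target genes relative to the
    background; an effect of 0 makes the feature uninformative.  A positive
    essentiality effect shifts targets toward *more negative* scores
    (stronger dependency).  ``n_informative_modules`` > 0 concentrates
    target genes in that many network communities so that class signal is
    carried by network neighborhood rather than by degree.
    """

    n_genes: int = 2000
    n_targets: int = 60
    n_heldout: int = 0
    n_samples_mutation: int = 100
    n_samples_expression: int = 100
    n_samples_essentiality: int = 40
    mutation_effect: float = 0.0
    expression_effect: float = 0.0
    essentiality_effect: float = 0.0
    n_informative_modules: int = 0
    n_communities: int = 12
    mean_degree: float = 8.0
    community_mixing: float = 0.08
    cancer_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError(f"n_genes must be >= 50, got {self.n_genes}")
        for name in ("n_targets", "n_samples_mutation",
                     "n_samples_expression", "n_samples_essentiality"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_heldout < self.n_targets:
            raise ValueError("n_heldout must lie in [0, n_targets)")
        if self.n_genes < 22 * self.n_targets:
            # ten disjoint negative sets plus the positives must fit with
            # headroom for missing-data attrition
            raise ValueError(
                f"n_genes={self.n_genes} too small for n_targets="
                f"{self.n_targets}; need at least {22 * self.n_targets}")
        if self.n_informative_modules > self.n_communities:
            raise ValueError("n_informative_modules exceeds n_communities")


@dataclass(frozen=True)
class TargetSet:
    cancer_label: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("target set must be non-empty")


@dataclass
class SampleMatrix:
    """Genes x samples matrix for one data type.

    Mutation entries are binary calls (1 = non-silent mutation observed in
    that sample); expression and essentiality are continuous.
    """

    data_type: str
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.data_type not in ("mutation", "expression", "essentiality"):
            raise ValueError(f"unknown data_type {self.data_type!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be 2-D with >= 1 sample column")
        if len(self.genes) != self.values.shape[0]:
            raise ValueError("gene list and value rows disagree")
        if self.data_type == "mutation" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("mutation entries must be in {0, 1}")


def generate_universe(n_genes: int, seed: int = 0) -> list[str]:
    """Ordered list of unique synthetic gene symbols.

    Symbols are index-based ("G00001", ...) so the same universe size
    yields the same symbols regardless of seed; the seed parameter is kept
    for interface symmetry with the other generators.
    """
    if n_genes < 50:
        raise ValueError(f"n_genes must be >= 50, got {n_genes}")
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _rng(config: ScenarioConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def _communities(config: ScenarioConfig, target_idx: np.ndarray) -> np.ndarray:
    """Community assignment; targets concentrated in informative modules."""
    rng = _rng(config, 11)
    comm = rng.integers(0, config.n_communities, size=config.n_genes)
    if config.n_informative_modules > 0:
        m = config.n_informative_modules
        # 90% of targets land in the designated modules
        informative = rng.random(target_idx.size) < 0.9
        comm[target_idx[informative]] = rng.integers(0, m, size=int(informative.sum()))
    return comm


def generate_network(universe: list[str], config: ScenarioConfig,
                     targets: TargetSet | None = None) -> nx.Graph:
    """Sparse scale-free graph with community structure over the universe.

    Chung-Lu style wiring: each gene receives a Pareto degree propensity
    and pairs connect with probability proportional to the product of
    propensities, down-weighted by ``community_mixing`` across communities
    and normalised so the expected mean degree matches the config.  Every
    gene is a node; isolated nodes are allowed.
    """
    if len(universe) != config.n_genes:
        raise ValueError("universe size does not match config.n_genes")
    n = config.n_genes
    gene_pos = {g: i for i, g in enumerate(universe)}
    target_idx = (np.array([gene_pos[g] for g in targets.genes], dtype=int)
                  if targets is not None else np.empty(0, dtype=int))

    g = nx.Graph()
    g.add_nodes_from(universe)
    if config.mean_degree <= 0:
        return g

    rng = _rng(config, 12)
    comm = _communities(config, target_idx)
    # bounded Pareto propensities -> heavy-tailed degree sequence
    w = (1.0 - rng.random(n)) ** (-1.0 / 1.5)
    w = np.minimum(w, np.sqrt(n))

    same = comm[:, None] == comm[None, :]
    mix = np.where(same, 1.0, config.community_mixing)
    ww = np.outer(w, w) * mix
    iu = np.triu_indices(n, k=1)
    total = ww[iu].sum()
    theta = (n * config.mean_degree / 2.0) / total
    p = np.clip(theta * ww[iu], 0.0, 1.0)
    hit = rng.random(p.size) < p
    genes_arr = np.asarray(universe, dtype=object)
    g.add_edges_from(zip(genes_arr[iu[0][hit]], genes_arr[iu[1][hit]]))
    return g


def generate_sample_matrices(universe: list[str], targets: TargetSet,
                             config: ScenarioConfig) -> dict[str, SampleMatrix]:
    """Sample-level matrices for the three primary data types.

    Gene-level latent values (per-gene Bernoulli mutation rate, mean
    expression, mean essentiality) are drawn from the background
    distributions and shifted for target genes by the configured effect
    sizes; per-sample values are then drawn around the latents.
    """
    if not set(targets.genes) <= set(universe):
        raise ValueError("targets must be a subset of the universe")
    n = len(universe)
    is_target = np.isin(np.asarray(universe, dtype=object), list(targets.genes))

    out: dict[str, SampleMatrix] = {}

    rng = _rng(config, 21)
    rate = rng.beta(_MUT_A, _MUT_B, size=n)
    rate[is_target] += config.mutation_effect * _beta_sd(_MUT_A, _MUT_B)
    if (rate < 0).any() or (rate > 1).any():
        warnings.warn("mutation rates clipped to [0, 1]", stacklevel=2)
        rate = np.clip(rate, 0.0, 1.0)
    calls = (rng.random((n, config.n_samples_mutation)) < rate[:, None]).astype(np.int8)
    out["mutation"] = SampleMatrix("mutation", list(universe), calls)

    rng = _rng(config, 22)
    mu = rng.normal(_EXPR_LOC, _EXPR_SCALE, size=n)
    mu[is_target] += config.expression_effect * _EXPR_SCALE
    vals = rng.normal(mu[:, None], 1.0, size=(n, config.n_samples_expression))
    out["expression"] = SampleMatrix("expression", list(universe), vals)

    rng = _rng(config, 23)
    mu = stats.skewnorm.rvs(_ESS_SKEW, loc=_ESS_LOC, scale=_ESS_SCALE,
                            size=n, random_state=rng)
    # positive effect = stronger dependency = more negative CERES-like score
    mu[is_target] -= config.essentiality_effect * _skewnorm_sd(_ESS_SKEW, _ESS_SCALE)
    vals = rng.normal(mu[:, None], 0.3, size=(n, config.n_samples_essentiality))
    out["essentiality"] = SampleMatrix("essentiality", list(universe), vals)
    return out


def aggregate_samples(matrix: SampleMatrix) -> pd.Series:
    """Collapse a sample matrix to the per-gene summary used for modeling.

    Mutation: mean of the binary calls (a rate in [0, 1]).  Expression and
    essentiality: median over samples.
    """
    if matrix.values.shape[1] < 1:
        raise ValueError("matrix has no sample columns")
    if matrix.data_type == "mutation":
        agg = matrix.values.mean(axis=1)
    else:
        agg = np.median(matrix.values, axis=1)
    return pd.Series(agg, index=matrix.genes, name=matrix.data_type)


@dataclass
class Scenario:
    """A complete synthetic study: inputs plus ground truth."""

    config: ScenarioConfig
    universe: list[str]
    targets: TargetSet                     # all planted targets
    positives: tuple[str, ...]             # planted minus held-out
    heldout: tuple[str, ...]
    network: nx.Graph
    matrices: dict[str, SampleMatrix]
    primary_features: pd.DataFrame         # gene x (mutation, expression, essentiality)
    citations: pd.Series = field(repr=False, default=None)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    universe = generate_universe(config.n_genes, config.seed)
    rng = _rng(config, 1)
    planted = tuple(sorted(rng.choice(universe, size=config.n_targets, replace=False)))
    targets = TargetSet(config.cancer_label, planted)
    if config.n_heldout:
        held_idx = rng.choice(config.n_targets, size=config.n_heldout, replace=False)
        heldout = tuple(planted[i] for i in sorted(held_idx))
    else:
        heldout = ()
    positives = tuple(g for g in planted if g not in set(heldout))

    network = generate_network(universe, config, targets)
    matrices = generate_sample_matrices(universe, targets, config)
    primary = pd.DataFrame({name: aggregate_samples(m) for name, m in matrices.items()})
    primary = primary[["mutation", "expression", "essentiality"]]
    primary.index.name = "gene"

    # synthetic literature coverage: log-normal counts whose intensity
    # tracks how target-like a gene's genomics look (literature is biased
    # toward genes with striking mutation/expression profiles), with an
    # extra boost for planted targets.  Under a null scenario the features
    # carry no class signal, so citations stay uninformative there.
    crng = _rng(config, 31)
    zmut = (primary["mutation"] - primary["mutation"].mean()) \
        / primary["mutation"].std()
    zexp = (primary["expression"] - primary["expression"].mean()) \
        / primary["expression"].std()
    log_mu = 1.0 + 0.4 * zmut.to_numpy() + 0.4 * zexp.to_numpy()
    counts = np.exp(log_mu + crng.normal(0.0, 1.2, size=config.n_genes))
    counts[np.isin(universe, planted)] *= 3.0
    citations = pd.Series(np.floor(counts).astype(int), index=universe, name="citations")
    citations.index.name = "gene"

    return Scenario(config, universe, targets, positives, heldout,
                    network, matrices, primary, citations)


def write_scenario(scenario: Scenario, outdir) -> dict[str, str]:
    """Write the file-based input bundle (all UTF-8, tab-delimited).

    Returns a name -> path mapping for: primary feature TSV, edge-list
    TSV, positive-gene list, held-out list (if any), citation TSV and a
    flat key-value config file.
    """
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = out / "primary_features.tsv"
    scenario.primary_features.to_csv(p, sep="\t")
    paths["primary_features"] = str(p)

    p = out / "edges.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        for u, v in sorted(scenario.network.edges()):
            fh.write(f"{u}\t{v}\n")
    paths["edges"] = str(p)

    p = out / "universe.txt"
    p.write_text("\n".join(scenario.universe) + "\n", encoding="utf-8")
    paths["universe"] = str(p)

    p = out / "positives.txt"
    p.write_text("\n".join(scenario.positives) + "\n", encoding="utf-8")
    paths["positives"] = str(p)

    if scenario.heldout:
        p = out / "heldout.txt"
        p.write_text("\n".join(scenario.heldout) + "\n", encoding="utf-8")
        paths["heldout"] = str(p)

    p = out / "citations.tsv"
    scenario.citations.to_frame().to_csv(p, sep="\t")
    paths["citations"] = str(p)

    p = out / "scenario_config.txt"
    with open(p, "w", encoding="utf-8") as fh:
        for k, v in asdict(scenario.config).items():
            fh.write(f"{k}\t{v}\n")
    paths["config"] = str(p)
    return paths
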