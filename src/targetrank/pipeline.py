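"""End-to-end pipeline driver.

Runs the full workflow in order — network embedding, dataset assembly,
univariate screening, permutation-null feature selection, training of the
five classifier families, test-set evaluation, full-data retraining and
genome-wide ranking — from either a synthetic scenario or file-based
inputs, writing every intermediate artifact plus a manifest into a run
directory.  Identical configuration (including the master seed)
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets as dsmod
from . import models as mdmod
from . import selection as selmod
from . import simulate as simmod
from . import stats as stmod
from .evaluate import (EvaluationReport, citation_validation,
                       evaluate as evaluate_models, predict_genomewide,
                       retrain_full)
from .embedding import embed_network, load_edge_list

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "make_fixtures", "FIXTURE_SCENARIOS", "fixture_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, with field defaults matching the
    study design: ten negative sets, 70/30 stratified split, 100 label
    shuffles, selection threshold z >= 0.5, 32 embedding dimensions and
    5-fold CV tuning."""

    # inputs: either a synthetic scenario ...
    scenario: simmod.ScenarioConfig | None = None
    # ... or file paths
    primary_features_path: str | None = None
    edges_path: str | None = None
    positives_path: str | None = None
    universe_path: str | None = None
    citations_path: str | None = None

    cancer_label: str = "synthetic"
    regime: str = "extended"               # "extended" | "primary"
    apply_feature_selection: bool = True
    k_negative_sets: int = 10
    train_frac: float = 0.7
    n_shuffles: int = 100
    z_threshold: float = 0.5
    embedding_dim: int = 32
    walks_per_node: int = 10
    subgraph_size: int = 40
    window: int = 5
    epochs: int = 5
    methods: tuple = mdmod.METHODS
    grid_preset: str = "full"              # "full" | "fast"
    cv_folds: int = 5
    n_citation_sample: int = 1000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("extended", "primary"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.grid_preset not in ("full", "fast"):
            raise ValueError(f"unknown grid_preset {self.grid_preset!r}")
        if self.scenario is None and self.primary_features_path is None:
            raise ValueError("either a scenario or input paths are required")


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: pd.DataFrame
    positives: tuple
    negatives: dsmod.NegativeSetCollection
    datasets: list
    univariate: pd.DataFrame
    selection: pd.DataFrame | None
    selected_features: list[str]
    evaluation: EvaluationReport
    best_method: str
    ensemble: list
    ranking: pd.DataFrame
    citation: tuple | None = None
    heldout: tuple = ()
    embedding: pd.DataFrame | None = None


def _grids(config: PipelineConfig) -> dict:
    maker = mdmod.default_grid if config.grid_preset == "full" else mdmod.fast_grid
    return {m: maker(m) for m in config.methods}


def _load_inputs(config: PipelineConfig):
    """Returns (universe, network_or_None, primary, positives, citations, heldout)."""
    if config.scenario is not None:
        sc = simmod.generate_scenario(config.scenario)
        return (sc.universe, sc.network, sc.primary_features,
                tuple(sc.positives), sc.citations, tuple(sc.heldout))
    primary = pd.read_csv(config.primary_features_path, sep="\t",
                          index_col="gene")
    positives = tuple(_read_list(config.positives_path))
    universe = _read_list(config.universe_path) if config.universe_path \
        else list(primary.index)
    network = None
    if config.edges_path:
        network = load_edge_list(config.edges_path, universe=universe)
    citations = None
    if config.citations_path:
        citations = pd.read_csv(config.citations_path, sep="\t",
                                index_col="gene")["citations"]
    return universe, network, primary, positives, citations, ()


def _read_list(path) -> list[str]:
    if path is None:
        raise ValueError("missing required input path")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input path does not exist: {p}")
    return [line.strip() for line in p.read_text(encoding="utf-8").splitlines()
            if line.strip()]


def _embedding_cache_key(network, config: PipelineConfig) -> str:
    h = hashlib.sha256()
    for u, v in sorted(network.edges()):
        h.update(f"{u}\t{v}\n".encode())
    h.update(json.dumps([config.embedding_dim, config.walks_per_node,
                         config.subgraph_size, config.window, config.epochs,
                         config.seed]).encode())
    return h.hexdigest()[:16]


def _get_embedding(network, config: PipelineConfig) -> pd.DataFrame:
    """Embedding with content-hash caching (the slow, cancer-independent stage)."""
    cache = None
    if config.outdir:
        key = _embedding_cache_key(network, config)
        cache = Path(config.outdir) / f"embedding_{key}.tsv"
        if cache.exists():
            logger.info("embedding cache hit: %s", cache)
            return pd.read_csv(cache, sep="\t", index_col="gene")
    emb = embed_network(network, d=config.embedding_dim,
                        walks_per_node=config.walks_per_node,
                        subgraph_size=config.subgraph_size,
                        window=config.window, epochs=config.epochs,
                        seed=config.seed)
    if cache is not None:
        emb.to_csv(cache, sep="\t")
    return emb


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    universe, network, primary, positives, citations, heldout = _load_inputs(config)

    embedding = None
    if config.regime == "extended":
        if network is None:
            raise ValueError("extended regime requires an interaction network")
        logger.info("stage embed: %d nodes, %d edges",
                    network.number_of_nodes(), network.number_of_edges())
        embedding = _get_embedding(network, config)

    logger.info("stage build: assembling feature table")
    features = dsmod.assemble_feature_table(primary, embedding, genes=universe)
    pos_with_data = tuple(g for g in sorted(set(positives)) if g in features.index)
    if not pos_with_data:
        raise RuntimeError("stage build failed: no positive gene has complete data")
    negatives = dsmod.sample_negative_sets(list(features.index), pos_with_data,
                                           k=config.k_negative_sets,
                                           seed=config.seed)
    datasets = dsmod.build_datasets(features, pos_with_data, negatives,
                                    train_frac=config.train_frac,
                                    seed=config.seed)

    logger.info("stage screen: univariate Mann-Whitney + BH")
    univariate = stmod.univariate_screen(features, pos_with_data, negatives,
                                         cancer_label=config.cancer_label)

    selection = None
    if config.regime == "primary":
        selected = list(dsmod.PRIMARY_FEATURES)
        train_sets = [mdmod.restrict_features(ds, selected) for ds in datasets]
    elif config.apply_feature_selection:
        logger.info("stage select: %d-shuffle permutation null x %d sets",
                    config.n_shuffles, negatives.k)
        reports = selmod.importance_for_datasets(datasets,
                                                 n_shuffles=config.n_shuffles,
                                                 seed=config.seed)
        selection = selmod.select_features(reports, config.z_threshold)
        selected = list(selection.index[selection["selected"]])
        train_sets = [mdmod.restrict_features(ds, selected) for ds in datasets]
    else:
        selected = list(features.columns)
        train_sets = datasets

    logger.info("stage train: %d methods x %d negative sets",
                len(config.methods), negatives.k)
    trained = mdmod.train_all(train_sets, methods=config.methods,
                              grids=_grids(config), cv_folds=config.cv_folds,
                              seed=config.seed)

    logger.info("stage evaluate")
    evaluation = evaluate_models(trained, train_sets, regime=config.regime)
    best = evaluation.best_method
    logger.info("best method: %s (mean test AUROC %.3f)", best,
                evaluation.means[best])

    logger.info("stage retrain + predict")
    ensemble = retrain_full(trained[best], train_sets)
    ranking = predict_genomewide(ensemble, features, pos_with_data, negatives)
    citation = None
    if citations is not None:
        citation = citation_validation(ranking, citations,
                                       n_sample=config.n_citation_sample,
                                       seed=config.seed)

    result = PipelineResult(config, features, pos_with_data, negatives,
                            datasets, univariate, selection, selected,
                            evaluation, best, ensemble, ranking, citation,
                            heldout, embedding)
    if outdir:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    result.features.to_csv(outdir / "feature_table.tsv", sep="\t")
    with open(outdir / "negative_sets.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tset_index\n")
        for i, s in enumerate(result.negatives.sets):
            for g in sorted(s):
                fh.write(f"{g}\t{i}\n")
    for ds in result.datasets:
        ds.frame.to_csv(outdir / f"dataset_neg{ds.negative_set_index}.tsv",
                        sep="\t", index=False)
    result.univariate.to_csv(outdir / "univariate.tsv", sep="\t")
    if result.selection is not None:
        result.selection.to_csv(outdir / "importance_selection.tsv", sep="\t")
    (outdir / "selected_features.txt").write_text(
        "\n".join(result.selected_features) + "\n", encoding="utf-8")
    ev = result.evaluation.table.copy()
    ev["mean"] = result.evaluation.means
    ev.to_csv(outdir / "evaluation.tsv", sep="\t")
    result.ranking.to_csv(outdir / "ranking.tsv", sep="\t")
    result.ranking.head(25).to_csv(outdir / "top_predictions.tsv", sep="\t")

    cfg = asdict(result.config)
    if result.config.scenario is not None:
        cfg["scenario"] = asdict(result.config.scenario)
    manifest = {
        "config": cfg,
        "best_method": result.best_method,
        "mean_test_auroc": {m: float(v)
                            for m, v in result.evaluation.means.items()},
        "n_positives_with_data": len(result.positives),
        "n_ranked_genes": int(len(result.ranking)),
        "selected_features": result.selected_features,
        "citation_validation": (None if result.citation is None
                                else {"rho": result.citation[0],
                                      "p": result.citation[1]}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                          encoding="utf-8")


# ---------------------------------------------------------------------------
# fixtures: miniature, fully seeded study scenarios

FIXTURE_SCENARIOS = ("null", "signal", "community")


def _fixture_scenario(name: str, seed: int, n_heldout: int = 0
                      ) -> simmod.ScenarioConfig:
    if name == "null":
        return simmod.ScenarioConfig(
            n_genes=2200, n_targets=100, n_heldout=n_heldout,
            mutation_effect=0.0, expression_effect=0.0,
            essentiality_effect=0.0, n_informative_modules=0,
            cancer_label="null", seed=seed)
    if name == "signal":
        return simmod.ScenarioConfig(
            n_genes=2000, n_targets=80, n_heldout=n_heldout,
            mutation_effect=3.0, expression_effect=2.0,
            essentiality_effect=0.0, n_informative_modules=3,
            cancer_label="signal", seed=seed)
    if name == "community":
        return simmod.ScenarioConfig(
            n_genes=2000, n_targets=80, n_heldout=n_heldout,
            mutation_effect=0.0, expression_effect=0.0,
            essentiality_effect=0.0, n_informative_modules=3,
            cancer_label="community", seed=seed)
    raise ValueError(f"unknown scenario {name!r}; valid names: "
                     f"{', '.join(FIXTURE_SCENARIOS)}")


def fixture_config(name: str, seed: int, n_heldout: int = 0,
                   **overrides) -> PipelineConfig:
    """Pipeline configuration for one of the bundled miniature scenarios.

    Fixture runs use reduced walk parameters and the one-point "fast"
    hyperparameter grids so a complete run stays small; scenario
    parameters themselves are fixed per scenario name.
    """
    defaults = dict(scenario=_fixture_scenario(name, seed, n_heldout),
                    cancer_label=name, seed=seed, grid_preset="fast",
                    walks_per_node=4, subgraph_size=12, epochs=3,
                    n_shuffles=30)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def make_fixtures(name: str, seed: int, outdir) -> dict[str, str]:
    """Write a complete miniature input bundle for a named scenario."""
    sc = simmod.generate_scenario(_fixture_scenario(name, seed))
    return simmod.write_scenario(sc, outdir)
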