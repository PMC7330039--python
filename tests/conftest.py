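import warnings

import numpy as np
import pytest

from targetrank.pipeline import fixture_config, run_pipeline
from targetrank.simulate import ScenarioConfig, generate_scenario

warnings.filterwarnings("ignore", category=FutureWarning)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def small_scenario():
    """Tiny planted-signal scenario for module-level unit tests."""
    cfg = ScenarioConfig(n_genes=300, n_targets=12, n_samples_mutation=40,
                         n_samples_expression=40, n_samples_essentiality=20,
                         mutation_effect=3.0, expression_effect=2.0,
                         n_informative_modules=3, cancer_label="unit", seed=11)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Small but complete pipeline run exercising all stages."""
    cfg = fixture_config("signal", FIXTURE_SEED,
                         outdir=str(tmp_path_factory.mktemp("small_run")))
    cfg.scenario = ScenarioConfig(
        n_genes=400, n_targets=16, n_samples_mutation=40,
        n_samples_expression=40, n_samples_essentiality=20,
        mutation_effect=3.0, expression_effect=2.0,
        n_informative_modules=2, cancer_label="small", seed=FIXTURE_SEED)
    cfg.walks_per_node, cfg.subgraph_size, cfg.epochs = 3, 10, 2
    cfg.n_shuffles = 10
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def signal_rundir(tmp_path_factory):
    # shared by the signal runs so the embedding cache is reused
    return str(tmp_path_factory.mktemp("signal_runs"))


@pytest.fixture(scope="session")
def signal_run(signal_rundir):
    """Full signal-fixture run (planted mutation/expression + community wiring)."""
    return run_pipeline(fixture_config("signal", FIXTURE_SEED,
                                       outdir=signal_rundir))


@pytest.fixture(scope="session")
def signal_heldout_run(signal_rundir, signal_run):
    """Signal fixture with 20 planted targets withheld from the positives."""
    return run_pipeline(fixture_config("signal", FIXTURE_SEED, n_heldout=20,
                                       outdir=signal_rundir))


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """Null-fixture run: no planted signal anywhere, selection stage off."""
    return run_pipeline(fixture_config(
        "null", FIXTURE_SEED, apply_feature_selection=False,
        outdir=str(tmp_path_factory.mktemp("null_run"))))


@pytest.fixture(scope="session")
def community_runs(tmp_path_factory):
    """Community fixture under both feature regimes."""
    outdir = str(tmp_path_factory.mktemp("community_runs"))
    ext = run_pipeline(fixture_config("community", FIXTURE_SEED, outdir=outdir))
    pri = run_pipeline(fixture_config("community", FIXTURE_SEED,
                                      regime="primary"))
    return ext, pri


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
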