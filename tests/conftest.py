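import logging

import numpy as np
import pytest

from fatesimplex.pipeline import PipelineConfig, run_all, stage_seed
from fatesimplex.simulate import SimParams, simulate_fate_landscape

logging.getLogger("fatesimplex").setLevel(logging.WARNING)

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run (simulate -> arrows), shared across tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(outdir=str(outdir), seed=PIPELINE_SEED)
    result = run_all(config)
    return result, outdir


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth matching the dataset `default_run` simulated internally."""
    params = SimParams(seed=stage_seed(PIPELINE_SEED, "simulate"))
    _, truth = simulate_fate_landscape(params)
    return truth


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy landscape for unit tests that need real structure."""
    params = SimParams(n_cells=150, n_genes=300, n_markers_per_fate=20, seed=42)
    return simulate_fate_landscape(params)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free landscape: layers are the exact NB means."""
    params = SimParams(n_cells=120, n_genes=200, n_markers_per_fate=15, noise="none", seed=5)
    return simulate_fate_landscape(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
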