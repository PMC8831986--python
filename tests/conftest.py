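import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_metrics helper

from cofitnet.pipeline import RunConfig, run_pipeline
from cofitnet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard benchmark condition: 300 genes, 40 lines, 10 modules."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One complete pipeline run on the default synthetic dataset, seed 1."""
    outdir = tmp_path_factory.mktemp("full_run")
    cfg = RunConfig(seed=1, outdir=str(outdir))
    report = run_pipeline(cfg)
    return report, outdir


@pytest.fixture(scope="session")
def small_config_sections():
    """A reduced end-to-end configuration for fast determinism checks."""
    return {
        "simulate": {"n_genes": 120, "n_modules": 5, "module_size_range": [6, 9]},
        "cv": {"repeats": 2, "backends": ["mars"]},
    }
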