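import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hybridepi import SimulationConfig, run_pipeline, simulate_all
from hybridepi.types import GeneModel

SMALL_SEED = 11
FULL_SEED = 1


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Desk-scale synthetic bundle (150 genes) for smoke and behaviour tests."""
    out = tmp_path_factory.mktemp("sim_small")
    config = SimulationConfig(seed=SMALL_SEED, n_genes=150)
    truth = simulate_all(config, out)
    return config, out, truth


@pytest.fixture(scope="session")
def small_result(small_bundle, tmp_path_factory):
    _, in_dir, _ = small_bundle
    out = tmp_path_factory.mktemp("pipe_small")
    return run_pipeline(in_dir, out), out


@pytest.fixture(scope="session")
def full_bundle(tmp_path_factory):
    """Study-scale bundle (2,000 genes) for parameter-recovery checks."""
    out = tmp_path_factory.mktemp("sim_full")
    config = SimulationConfig(seed=FULL_SEED, n_genes=2000)
    truth = simulate_all(config, out)
    return config, out, truth


@pytest.fixture(scope="session")
def full_result(full_bundle, tmp_path_factory):
    _, in_dir, _ = full_bundle
    out = tmp_path_factory.mktemp("pipe_full")
    return run_pipeline(in_dir, out), out


@pytest.fixture
def plus_gene():
    """A forward-strand two-exon gene: [10000, 20000), exons split by an intron."""
    return GeneModel(
        "gplus", "chr1", "+", 10_000, 20_000,
        exons=[(10_000, 14_000), (15_000, 20_000)],
        cds=[(10_150, 14_000), (15_000, 19_850)],
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        "gminus", "chr2", "-", 50_000, 56_000,
        exons=[(50_000, 52_000), (53_000, 56_000)],
        cds=[(50_150, 52_000), (53_000, 55_850)],
    )
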