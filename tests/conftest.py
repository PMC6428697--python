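import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from beaudit.guides import GuideSpec
from beaudit.simulate import (
    DEFAULT_GUIDE,
    SimulationConfig,
    plant_offtarget_homologs,
    simulate_genome,
)


@pytest.fixture(scope="session")
def guide() -> GuideSpec:
    return DEFAULT_GUIDE


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, noiseless trio scenario with every spike-in category."""
    return SimulationConfig(
        seed=101,
        genome_length=200_000,
        n_contigs=4,
        scaffold_fraction=0.25,
        n_inherited_snps=300,
        n_db_known_snps=60,
        n_denovo_snps=20,
        n_denovo_indels=10,
        n_offtarget_edits=3,
    )


@pytest.fixture(scope="session")
def small_genome(small_config, guide):
    genome = simulate_genome(small_config)
    genome, planted = plant_offtarget_homologs(
        genome, guide, 5, [1, 2, 2, 3, 3], seed=small_config.seed
    )
    return genome, planted
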