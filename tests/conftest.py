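import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mybkit.simulate import SyntheticGenomeConfig, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A modest genome with every planted structure present."""
    cfg = SyntheticGenomeConfig(
        chromosome_length=120_000,
        n_family_genes=40,
        n_background_genes=60,
        n_tandem_clusters=2,
        n_segmental_blocks=1,
        segmental_span=20_000,
        homoeolog_fraction=0.45,
        repeat_noise=0.05,
        seed=11,
    )
    bundle, truth = generate_genome(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def clean_genome():
    """Zero-noise genome: planted repeats are exact consensus copies."""
    cfg = SyntheticGenomeConfig(
        chromosome_length=100_000,
        n_family_genes=20,
        n_background_genes=20,
        n_tandem_clusters=1,
        n_segmental_blocks=0,
        homoeolog_fraction=0.3,
        repeat_noise=0.0,
        seed=7,
    )
    bundle, truth = generate_genome(cfg)
    return cfg, bundle, truth
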