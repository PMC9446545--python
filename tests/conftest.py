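import numpy as np
import pytest

from zcwcross import GenomeLayout, SimConfig
from zcwcross.pipeline import PIPELINE_PAIRS, run_pipeline
from zcwcross.simulate import simulate


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout(("chr1", "chr2"), (200_000, 150_000))


@pytest.fixture(scope="session")
def small_config(small_layout):
    """Down-scaled study: 2 x ~200 kb chromosomes, 50 sites."""
    return SimConfig(
        layout=small_layout,
        n_hotspot_sites=46,
        n_promoter_sites=4,
        min_site_gap=2_000,
        n_decoy_tss=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config, pairs=PIPELINE_PAIRS)


@pytest.fixture(scope="session")
def default_run():
    """The full default simulated study (seed 42), shared across tests."""
    return run_pipeline(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
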