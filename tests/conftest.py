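import numpy as np
import pytest

from meripdiff.motif import load_adrb2_fragments
from meripdiff.pipeline import PipelineConfig, run_pipeline
from meripdiff.simulate import SimulationConfig


@pytest.fixture(scope="session")
def adrb2():
    """The bundled (wild-type, site-mutant) Adrb2 3'UTR fragments."""
    return load_adrb2_fragments()


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study design (seed 7),
    shared by the pipeline and acceptance tests."""
    return run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=7)))


@pytest.fixture()
def small_config():
    """A fast small-scale simulation for unit tests."""
    return SimulationConfig(
        n_genes=40,
        n_targets=6,
        utr5_len_range=(50, 100),
        cds_len_range=(200, 400),
        utr3_len_range=(150, 300),
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
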