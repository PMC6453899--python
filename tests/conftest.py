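import numpy as np
import pytest

from tripcas.synthetic import (
    DEFAULT_GUIDES,
    SimulationConfig,
    generate_reporter_library,
    simulate_cas9_reads,
)


@pytest.fixture(scope="session")
def guides():
    return {g.name: g for g in DEFAULT_GUIDES}


@pytest.fixture(scope="session")
def small_library():
    cfg = SimulationConfig(seed=101, n_irs=6, coverage_mean=40, seq_error_rate=0.0)
    return cfg, generate_reporter_library(cfg)


@pytest.fixture(scope="session")
def clean_assay(small_library, guides):
    """Error-free reads plus truth table for one disruption assay."""
    cfg, lib = small_library
    reads, truth = simulate_cas9_reads(lib, guides["sgG3"], cfg)
    return lib, reads, truth


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0x7E57]))
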