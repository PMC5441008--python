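import numpy as np
import pytest

from ptxmap.simulate import SimScenario, simulate_family


@pytest.fixture(scope="session")
def one_chrom_scenario():
    """Single 100 cM chromosome, noise-free, testcross-only markers."""
    return SimScenario(
        n_chromosomes=1,
        chrom_lengths_bp=(50_000_000,),
        chrom_lengths_cM=(100.0,),
        n_markers=30,
        seg_mix={"testcross_P1": 1.0},
        error_rate=0.0,
        missing_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def one_chrom_family(one_chrom_scenario):
    return simulate_family(one_chrom_scenario, 200, "F", seed=11)


@pytest.fixture(scope="session")
def two_chrom_scenario():
    return SimScenario(
        n_chromosomes=2,
        chrom_lengths_bp=(40_000_000, 50_000_000),
        chrom_lengths_cM=(80.0, 100.0),
        n_markers=40,
        seg_mix={"testcross_P1": 1.0},
        error_rate=0.0,
        missing_rate=0.0,
        seed=19,
    )
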