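import numpy as np
import pytest

from bcrasm.params import PipelineParams
from bcrasm.simulator import (
    SimParams,
    make_toy_germline_db,
    simulate_reads,
    simulate_receptor,
)


@pytest.fixture(scope="session")
def toy_db():
    """Synthetic germline set (random sequences, IMGT-like names)."""
    return make_toy_germline_db()


@pytest.fixture
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def clean_cell(toy_db):
    """One simulated cell at zero noise: (truth, reads, sim params)."""
    rng = np.random.default_rng(7)
    sp = SimParams(seed=7, depth=100.0)
    truth = simulate_receptor(toy_db, sp, rng, "cellA")
    reads = simulate_reads(truth, sp, rng)
    return truth, reads, sp


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
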