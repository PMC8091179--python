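import numpy as np
import pytest

from satarch.annotation import ReferenceRepeat
from satarch.simulate import SimulationParams, make_monomer, simulate


@pytest.fixture(scope="session")
def monomer():
    seq, info = make_monomer(389, seed=1)
    return seq, info


@pytest.fixture(scope="session")
def small_sim():
    """Error-free simulation shared across tests (seed 42, 12 reads)."""
    params = SimulationParams(seed=42, n_reads=12, n_loci=2).error_free()
    loci, reads, truths, refdb, info = simulate(params)
    return {"params": params, "loci": loci, "reads": reads,
            "truths": truths, "refdb": refdb, "info": info}


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-error (5%) simulation shared across tests."""
    params = SimulationParams(seed=7, n_reads=12, n_loci=2)
    loci, reads, truths, refdb, info = simulate(params)
    return {"params": params, "loci": loci, "reads": reads,
            "truths": truths, "refdb": refdb, "info": info}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture()
def satellite_ref(monomer):
    seq, _ = monomer
    return ReferenceRepeat("CUS-TR24", "satellite", seq)
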