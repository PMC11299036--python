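import numpy as np
import pytest

from paleohybrid.formats import Alignment, Sequence
from paleohybrid.genetreesort import GroupScheme
from paleohybrid.simulate import SCENARIO_GROUPS, SimulationConfig, simulate_case_loci


@pytest.fixture(scope="session")
def toy_scheme():
    """Minimal group scheme used by hand-built tree examples."""
    return GroupScheme.from_dict(
        dict(outgroup=["O"], focal=["B1"], parent1=["A1", "A2"], parent2=["C1", "C2"])
    )


@pytest.fixture(scope="session")
def case_scheme():
    return GroupScheme.from_dict(SCENARIO_GROUPS)


@pytest.fixture(scope="session")
def case_loci():
    """Quota-mode case-study gene trees (no sequences), truth attached."""
    cfg = SimulationConfig(n_loci=150, sites_per_locus=10, seed=0, mode="classes")
    return simulate_case_loci(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_sequences(rng, n=10, min_len=1, max_len=120):
    """Random nucleotide records with unique ids."""
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        residues = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        out.append(Sequence(f"seq{i:03d}", residues))
    return out


def random_alignment(rng, n_seqs=5, length=60):
    seqs = [
        Sequence(f"t{i}", "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)]))
        for i in range(n_seqs)
    ]
    return Alignment(seqs)
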