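import pytest

from cyp2d6pop.genotypes import table1_matrix_counts
from cyp2d6pop.phasing import em_phase
from cyp2d6pop.star import load_definitions
from cyp2d6pop.synthetic import default_spec, simulate


@pytest.fixture(scope="session")
def table1_counts():
    """GenotypeCounts built from the bundled study count table."""
    return table1_matrix_counts()


@pytest.fixture(scope="session")
def star_defs():
    return load_definitions()


@pytest.fixture(scope="session")
def default_cohort():
    """The study-structured synthetic cohort at a fixed seed."""
    gm, truth = simulate(default_spec(seed=1))
    return gm, truth


@pytest.fixture(scope="session")
def phased_cohort(default_cohort):
    gm, _ = default_cohort
    return em_phase(gm, seed=1, n_restarts=3)
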