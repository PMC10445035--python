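import pytest
from hypothesis import settings

from ndgpmap.core import project_deterministic

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")
from ndgpmap.synthetic import SyntheticMapSpec, random_nd_map, toy_map_T1


@pytest.fixture
def t1():
    return toy_map_T1()


@pytest.fixture
def t1_projection(t1):
    return project_deterministic(t1)


def small_random_maps(n, *, K=2, L=3, n_phenotypes=3, max_support=3, seed0=100, **kw):
    """Seeded stream of small ND maps for oracle-style tests."""
    for s in range(seed0, seed0 + n):
        yield random_nd_map(
            SyntheticMapSpec(
                K=K, L=L, n_phenotypes=n_phenotypes, max_support=max_support, seed=s, **kw
            )
        )


@pytest.fixture(scope="session")
def rna8_map():
    """Exhaustive Boltzmann ND map over all 4**8 RNA sequences (session-wide)."""
    from ndgpmap.rna import build_rna_map

    return build_rna_map(8)


@pytest.fixture(scope="session")
def rna8_quantities(rna8_map):
    from ndgpmap.quantities import compute_quantity_table

    return compute_quantity_table(rna8_map, method="fast")
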