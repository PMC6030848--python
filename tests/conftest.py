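import pytest

from protmod import fixtures


@pytest.fixture(scope="session")
def rotlib():
    """Toy backbone-dependent rotamer library (all chi-bearing types)."""
    return fixtures.make_rotlib(seed=11)


@pytest.fixture(scope="session")
def helix12():
    return fixtures.make_helix(12)


@pytest.fixture(scope="session")
def dimer_with_truth():
    return fixtures.make_toy_dimer(12, 4, seed=1)
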