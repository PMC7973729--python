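import pytest

from pathalign import PenaltyScheme, build_catalog, load_fixture


@pytest.fixture(scope="session")
def catalog():
    """The 15-activity case-study catalog (expert groups and ranks)."""
    return load_fixture("catalog")


@pytest.fixture(scope="session")
def pen_min():
    """Smallest guideline-compliant penalty scheme."""
    return PenaltyScheme(m=1, s=2, g=2, ns=5)


@pytest.fixture(scope="session")
def pen_wide():
    """Wide-gap scheme used in the clustering case studies."""
    return PenaltyScheme(m=1, s=2, g=9, ns=19)


@pytest.fixture(scope="session")
def small_catalog():
    """Five activities in three groups, ranks 0..4, for exhaustive checks."""
    return build_catalog(
        groups={"A": 0, "B": 0, "C": 1, "D": 1, "E": 2},
        ranks={"A": 0, "B": 1, "C": 2, "D": 3, "E": 4},
    )


@pytest.fixture(scope="session")
def sample1():
    return load_fixture("sample1").pathways


@pytest.fixture(scope="session")
def sample2():
    return load_fixture("sample2").pathways
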