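import pytest

from cagefit.model import (
    FitnessScheme,
    GenotypeDist,
    Scenario,
    SexedPopulation,
    paper_seed_population,
)


@pytest.fixture
def cage_seed() -> SexedPopulation:
    """Founder mix of the real experiment: all-KO females, 50:50 WT:KO males."""
    return paper_seed_population()


@pytest.fixture
def neutral() -> FitnessScheme:
    return FitnessScheme(scenario=Scenario.HET_EQUALS_WT, f_ko=1.0)


def dist_from_weights(a: float, b: float, c: float) -> GenotypeDist:
    """Normalize three non-negative weights into a GenotypeDist."""
    total = a + b + c
    return GenotypeDist(a / total, b / total, c / total)
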