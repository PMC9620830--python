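import pytest
from hypothesis import HealthCheck, settings

from listagg import Dataset, GeneList, ListKind, SimulationConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_dataset() -> Dataset:
    """Two full ranked lists over {a, b, c} with a symmetric a/b swap."""
    return Dataset.from_lists(
        [
            GeneList("l1", "c1", ListKind.RANKED, ("a", "b", "c")),
            GeneList("l2", "c2", ListKind.RANKED, ("b", "a", "c")),
        ]
    )


@pytest.fixture
def mixed_dataset() -> Dataset:
    """A ranked and an unranked list over a 4-entity universe."""
    return Dataset.from_lists(
        [
            GeneList("r1", "c1", ListKind.RANKED, ("g1", "g2", "g3")),
            GeneList("u1", "c2", ListKind.UNRANKED, ("g2", "g4")),
        ]
    )


def small_config(**overrides) -> SimulationConfig:
    """A 500-entity configuration for fast replicated experiments."""
    defaults = dict(
        n_entities=500,
        n_signal=25,
        M=3.0,
        D=1.0,
        m_c=100.0,
        D_c=0.5,
        L=10,
        U=500,
        list_specs=tuple((f"s{i}", ListKind.RANKED) for i in range(4)),
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
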