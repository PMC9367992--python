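import pytest

from hoolinet import build_paper_fixture
from hoolinet.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic synthetic dataset with one planted rivalry and
    one planted alliance."""
    config = SimulationConfig(
        heads=("head_1", "head_2", "head_3"),
        n_opponents=6,
        matches_per_pair=12,
        planted_relations={
            ("head_1", "club_01"): 6.0,
            ("head_2", "club_02"): 0.1,
        },
        seed=2024,
    )
    records, truth = generate_dataset(config)
    return config, records, truth
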