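import numpy as np
import pytest

from tissueppi import (
    InteractionRecord,
    SyntheticParams,
    encode_paper_fixture,
    generate_dataset,
    paper_expression,
)
from tissueppi.synthetic import BRAIN_REGIONS, FIXTURE_TISSUES


@pytest.fixture(scope="session")
def fixture_networks():
    return encode_paper_fixture()


@pytest.fixture(scope="session")
def brain_networks(fixture_networks):
    return [fixture_networks[t] for t in BRAIN_REGIONS]


@pytest.fixture(scope="session")
def all_networks(fixture_networks):
    return [fixture_networks[t] for t in FIXTURE_TISSUES]


@pytest.fixture(scope="session")
def paper_nx():
    return paper_expression()


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("synthetic")
    return generate_dataset(out, SyntheticParams(), rng_seed=0)


def random_records(rng: np.random.Generator, n: int = 50,
                   seed_gene: str = "HUB1") -> list[InteractionRecord]:
    """Random interaction records around a hub, for property tests."""
    type_pool = ["MI:0407", "MI:0915", "MI:0914", "MI:0403"]
    records = []
    for i in range(n):
        n_types = int(rng.integers(0, 3))
        types = set(rng.choice(type_pool, size=n_types, replace=False))
        records.append(InteractionRecord(
            id_a=seed_gene,
            id_b=f"P{i:03d}",
            confidence=float(np.round(rng.random(), 3)),
            interaction_types=types,
        ))
    return records
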