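import numpy as np
import pytest

from metaminer.align import ScoringScheme
from metaminer.examples import example_knowledgebase


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def example_kb():
    return example_knowledgebase()


@pytest.fixture(scope="session")
def kb_by_id(example_kb):
    return {s.enzyme_id: s for s in example_kb}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_protein_seq(rng: np.random.Generator, length: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, 20, size=length))
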