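import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from glylec.fixtures import GrammarParams, random_glycan_corpus, synthetic_clec17a
from glylec.notation import parse_condensed


@pytest.fixture(scope="session")
def small_corpus():
    """200 seeded random glycans with ground-truth graphs."""
    return random_glycan_corpus(200, GrammarParams(seed=7))


@pytest.fixture(scope="session")
def lactose():
    return parse_condensed("Galb1-4Glcb")


@pytest.fixture(scope="session")
def lewis_x():
    return parse_condensed("Galb1-4(Fuca1-3)GlcNAcb-Sp0")


@pytest.fixture(scope="session")
def sialyllactose():
    return parse_condensed("Neu5Aca2-3Galb1-4Glcb")


@pytest.fixture(scope="session")
def benchmark_lectin():
    return synthetic_clec17a()
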