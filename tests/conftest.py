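import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from svgraph.graph_model import DELETION, INSERTION, SWAP, GraphParams, SVRecord, build_graph

BASES = np.array(list("ACGT"))


def random_sequence(rng, length):
    return "".join(rng.choice(BASES, length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def reference_seq():
    r = np.random.default_rng(7)
    return "".join(r.choice(BASES, 20_000))


@pytest.fixture(scope="session")
def reference(reference_seq):
    return {"chr1": reference_seq}


@pytest.fixture
def deletion_record():
    return SVRecord("chr1", 5000, 5300, DELETION, id="del1")


@pytest.fixture
def insertion_record(rng):
    return SVRecord("chr1", 8000, 8000, INSERTION, alt_seq=random_sequence(rng, 120), id="ins1")


@pytest.fixture
def swap_record(rng):
    return SVRecord("chr1", 12000, 12100, SWAP, alt_seq=random_sequence(rng, 120), id="swap1")


@pytest.fixture
def deletion_graph(deletion_record, reference):
    return build_graph(deletion_record, reference, GraphParams(read_length=150))


@pytest.fixture
def insertion_graph(insertion_record, reference):
    return build_graph(insertion_record, reference, GraphParams(read_length=150))


@pytest.fixture
def swap_graph(swap_record, reference):
    return build_graph(swap_record, reference, GraphParams(read_length=150))
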