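import numpy as np
import pytest
from hypothesis import settings

from circimc import AssociationDataset, OntologyGraph, SequenceRecord
from circimc.synthetic import SyntheticSpec, generate_all

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_dataset():
    """4 circRNAs x 3 diseases with a hand-built pattern."""
    pairs = [
        ("c1", "d1"), ("c1", "d2"),
        ("c2", "d1"),
        ("c3", "d3"),
        ("c4", "d2"), ("c4", "d3"),
    ]
    return AssociationDataset.from_pairs(pairs)


@pytest.fixture
def chain_ontology():
    """a is_a b is_a c."""
    return OntologyGraph({"a": {"b"}, "b": {"c"}, "c": set()})


@pytest.fixture
def diamond_ontology():
    """a with two parents b and c, both under root r."""
    return OntologyGraph({"a": {"b", "c"}, "b": {"r"}, "c": {"r"}, "r": set()})


@pytest.fixture
def sibling_ontology():
    """Two leaves a, b under a shared root r."""
    return OntologyGraph({"a": {"r"}, "b": {"r"}, "r": set()})


@pytest.fixture
def toy_records():
    return [
        SequenceRecord("c1", "ACGTACGT"),
        SequenceRecord("c2", "ACGTACGA"),
        SequenceRecord("c3", "TTTTGGGG"),
    ]


@pytest.fixture(scope="session")
def planted():
    """Coupled planted benchmark: 40x10, rank 2, density 0.1, signal 3."""
    return generate_all(SyntheticSpec(coupled=True, seed=7))


@pytest.fixture(scope="session")
def null_data():
    """Signal-free control under otherwise identical conditions."""
    return generate_all(SyntheticSpec(coupled=False, signal=0.0, seed=7))
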