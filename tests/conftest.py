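import numpy as np
import pytest

from nrlmf import AssociationMatrix, DiseaseOntology, EntityIndex, make_world


@pytest.fixture(scope="session")
def tiny_world():
    """30x20 planted world used throughout the unit tests."""
    return make_world(m=30, n=20, rank=3, density=0.05, seed=7)


@pytest.fixture()
def chain_ontology():
    """D -> p1 -> p2 with diseases (D, other)."""
    return DiseaseOntology.from_edges(
        [("D", "p1"), ("p1", "p2")], disease_ids=["D", "other"]
    )


@pytest.fixture()
def diamond_ontology():
    """D -> {a, b}, a -> r, b -> r."""
    return DiseaseOntology.from_edges(
        [("D", "a"), ("D", "b"), ("a", "r"), ("b", "r")], disease_ids=["D"]
    )


@pytest.fixture()
def four_disease_ontology():
    """Covered diseases {A, B, C, P}: A and B children of P, C isolated.

    The auxiliary non-disease term X makes C appear in the edge file without
    giving it an ancestor, so T(C) = {C} and T(P) = {P}.
    """
    return DiseaseOntology.from_edges(
        [("A", "P"), ("B", "P"), ("X", "C")],
        disease_ids=["A", "B", "C", "P"],
    )


@pytest.fixture()
def small_assoc():
    values = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return AssociationMatrix(values, EntityIndex(["r1", "r2"]), EntityIndex(["d1", "d2", "d3"]))
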