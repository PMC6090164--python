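"""Disease semantic similarity over MeSH-style DAGs.

Two contribution models are supported. Model 1 decays a term's
contribution geometrically with its distance from the disease of interest
(decay factor ``delta``, default 0.5): the disease itself contributes 1 and
every ancestor contributes the maximum of ``delta`` times the contribution
of its children inside the disease's DAG. Model 2 scores a term by its
information content, ``-ln(fraction of disease DAGs containing the term)``,
so rare, specific terms contribute more than broad ones. In both models the
similarity of two diseases is the summed contribution of the shared part of
their DAGs normalised by the total semantic values:

    SS(d_i, d_j) = sum_{t in T(d_i) & T(d_j)} (C_{d_i}(t) + C_{d_j}(t))
                   / (DV(d_i) + DV(d_j))

where T(D) is the disease plus all its ancestors and DV is the sum of all
contributions. Self-similarity is exactly 1 and scores lie in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import DiseaseOntology, EntityIndex, SimilarityMatrix

__all__ = [
    "SemanticProfile",
    "dag_of",
    "contributions_model1",
    "contributions_model2",
    "semantic_similarity",
    "semantic_similarity_matrices",
]


@dataclass
class SemanticProfile:
    """Per-disease DAG contributions and their sum (the semantic value)."""

    disease: str
    contributions: dict[str, float]
    semantic_value: float
    model: int


def dag_of(ontology: DiseaseOntology, disease: str) -> frozenset[str]:
    """T(D): the disease itself plus all its ancestral terms."""
    if disease not in ontology.covered:
        raise ValueError(f"disease {disease!r} has no DAG in the ontology")
    return frozenset({disease}) | ontology.ancestors(disease)


def contributions_model1(
    ontology: DiseaseOntology, disease: str, delta: float = 0.5
) -> SemanticProfile:
    """Decay-based contributions of every term of DAG(D) to disease D."""
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"decay factor must be in (0, 1], got {delta}")
    terms = dag_of(ontology, disease)
    sub = ontology.graph.subgraph(terms)  # edges child -> parent
    contrib: dict[str, float] = {}
    # children precede parents in topological order of child->parent edges
    for node in nx.topological_sort(sub):
        if node == disease:
            contrib[node] = 1.0
        else:
            contrib[node] = max(delta * contrib[c] for c in sub.predecessors(node))
    return SemanticProfile(
        disease=disease,
        contributions=contrib,
        semantic_value=float(sum(contrib.values())),
        model=1,
    )


def contributions_model2(
    ontology: DiseaseOntology, covered: frozenset[str] | None = None
) -> dict[str, SemanticProfile]:
    """Information-content contributions for every covered disease.

    A term's contribution, identical across all DAGs containing it, is
    ``-ln(n_DAGs_containing_term / n_covered_diseases)`` (natural log); a
    term present in every DAG contributes exactly 0. A disease whose total
    semantic value is 0 is flagged with a warning because it cannot enter
    the similarity ratio.
    """
    covered = ontology.covered if covered is None else covered
    if not covered:
        raise ValueError("no covered disease has a DAG")
    dags = {d: dag_of(ontology, d) for d in sorted(covered)}
    counts: dict[str, int] = {}
    for terms in dags.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n = len(covered)
    ic = {t: -math.log(c / n) for t, c in counts.items()}
    profiles: dict[str, SemanticProfile] = {}
    for d, terms in dags.items():
        contrib = {t: ic[t] for t in terms}
        dv = float(sum(contrib.values()))
        if dv == 0.0:
            warnings.warn(
                f"disease {d!r} has zero model-2 semantic value "
                "(every term of its DAG occurs in all DAGs)"
            )
        profiles[d] = SemanticProfile(disease=d, contributions=contrib, semantic_value=dv, model=2)
    return profiles


def semantic_similarity(p1: SemanticProfile, p2: SemanticProfile) -> float:
    """Shared-contribution similarity of two same-model profiles."""
    if p1.model != p2.model:
        raise ValueError("profiles come from different contribution models")
    denom = p1.semantic_value + p2.semantic_value
    if denom == 0.0:
        raise ValueError(
            f"degenerate similarity for ({p1.disease!r}, {p2.disease!r}): "
            "both semantic values are 0"
        )
    shared = set(p1.contributions) & set(p2.contributions)
    num = sum(p1.contributions[t] + p2.contributions[t] for t in shared)
    # numerator <= denominator mathematically; clamp float summation overshoot
    return float(min(1.0, num / denom))


def semantic_similarity_matrices(
    ontology: DiseaseOntology,
    disease_index: EntityIndex,
    delta: float = 0.5,
) -> tuple[SimilarityMatrix, SimilarityMatrix, np.ndarray]:
    """Pairwise model-1 and model-2 similarity over the covered diseases.

    Returns (SS1, SS2, covered_mask). Entries involving an uncovered
    disease are undefined; they are stored as 0 and flagged False in the
    mask so integration can fall back to the interaction-profile kernel.
    """
    n = len(disease_index)
    mask = np.array([d in ontology.covered for d in disease_index.ids], dtype=bool)
    ss1 = np.zeros((n, n))
    ss2 = np.zeros((n, n))
    if mask.any():
        covered_ids = [d for d in disease_index.ids if d in ontology.covered]
        prof1 = {d: contributions_model1(ontology, d, delta) for d in covered_ids}
        prof2 = contributions_model2(ontology, frozenset(covered_ids))
        pos = [disease_index.position[d] for d in covered_ids]
        for a, da in zip(pos, covered_ids):
            for b, db in zip(pos, covered_ids):
                if b < a:
                    continue
                s1 = semantic_similarity(prof1[da], prof1[db])
                ss1[a, b] = ss1[b, a] = s1
                if prof2[da].semantic_value + prof2[db].semantic_value > 0.0:
                    s2 = semantic_similarity(prof2[da], prof2[db])
                    ss2[a, b] = ss2[b, a] = s2
    return (
        SimilarityMatrix(ss1, disease_index, role="SS1"),
        SimilarityMatrix(ss2, disease_index, role="SS2"),
        mask,
    )
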