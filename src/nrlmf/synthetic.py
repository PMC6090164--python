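"""Synthetic association worlds with planted low-rank logistic structure.

The generator emulates the statistical assumptions of the factorization:
true factors drawn from zero-mean Gaussians, associations sampled from the
logistic of their inner product (with an intercept solved so the expected
density hits a target, default 3%, close to the density of curated
miRNA-disease catalogs), a functional-similarity matrix built as a radial
kernel over the true miRNA factors (so nearest-neighbor graphs carry real
neighborhood signal), and a random disease hierarchy in which only a
fraction of diseases participates, exercising the kernel fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from .data import AssociationMatrix, DiseaseOntology, EntityIndex, SimilarityMatrix

__all__ = ["SyntheticWorld", "make_world", "make_ontology", "shuffle_labels"]


@dataclass
class SyntheticWorld:
    """A complete, reproducible input set for the pipeline."""

    true_U: np.ndarray
    true_V: np.ndarray
    bias: float
    Y: AssociationMatrix
    MS: SimilarityMatrix
    functional_mask: np.ndarray
    ontology: DiseaseOntology
    seed: int
    params: dict

    @property
    def mirna_index(self) -> EntityIndex:
        return self.Y.mirna_index

    @property
    def disease_index(self) -> EntityIndex:
        return self.Y.disease_index


def _factor_kernel(F: np.ndarray) -> np.ndarray:
    """Radial kernel over factor rows, median-heuristic bandwidth, diag 1."""
    d2 = squareform(pdist(F, metric="sqeuclidean"))
    off = d2[~np.eye(len(F), dtype=bool)]
    med = np.median(off) if off.size else 1.0
    if med == 0.0:
        med = 1.0
    K = np.exp(-d2 / med)
    np.fill_diagonal(K, 1.0)
    return K


def _latent_groups(
    F: np.ndarray, branching: int, levels: int, rng: np.random.Generator
) -> np.ndarray:
    """Hierarchy-consistent group index per row of F.

    Recursively splits the rows into ``branching`` equal parts by their
    projection onto a fresh random direction; after ``levels`` rounds the
    group index's base-``branching`` digits spell the path through the
    splits, so rows sharing a long prefix are close in factor space.
    """
    groups = np.zeros(len(F), dtype=int)
    for _ in range(levels):
        direction = rng.standard_normal(F.shape[1])
        new = np.zeros_like(groups)
        for g in np.unique(groups):
            members = np.flatnonzero(groups == g)
            order = members[np.argsort(F[members] @ direction, kind="stable")]
            parts = np.array_split(order, branching)
            for b, part in enumerate(parts):
                new[part] = g * branching + b
        groups = new
    return groups


def make_ontology(
    disease_ids: list[str],
    depth: int = 4,
    branching: int = 3,
    coverage_fraction: float = 0.9,
    seed: int = 0,
    group_of: np.ndarray | None = None,
) -> DiseaseOntology:
    """Random rooted hierarchy with a fraction of diseases attached as leaves.

    Internal levels 0..depth-1 form a ``branching``-ary tree below a single
    root; each covered disease is attached as a child of a deepest internal
    node — a uniformly chosen one, or, when ``group_of`` assigns each
    disease a group number, the node ``group_of[d] % n_deepest`` (this lets
    the world generator place latently similar diseases on the same branch
    so semantic similarity carries neighborhood signal, while the hierarchy
    topology itself stays random). With depth 1 every covered disease's DAG
    is just {itself, root}. Uncovered diseases never appear in the
    hierarchy and fall back to the kernel similarity downstream.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    levels: list[list[str]] = [["term-root"]]
    edges: list[tuple[str, str]] = []
    counter = 0
    for lvl in range(1, depth):
        layer = []
        for parent in levels[lvl - 1]:
            for _ in range(branching):
                node = f"term-{counter:04d}"
                counter += 1
                edges.append((node, parent))
                layer.append(node)
        levels.append(layer)
    n_cov = int(round(coverage_fraction * len(disease_ids)))
    covered = sorted(rng.choice(len(disease_ids), size=n_cov, replace=False))
    deepest = levels[-1]
    for k in covered:
        if group_of is not None:
            parent = deepest[int(group_of[k]) % len(deepest)]
        else:
            parent = deepest[int(rng.integers(len(deepest)))]
        edges.append((disease_ids[k], parent))
    return DiseaseOntology.from_edges(edges, disease_ids)


def make_world(
    m: int = 100,
    n: int = 80,
    rank: int = 10,
    density: float = 0.03,
    bias: float | None = None,
    coverage_fraction: float = 0.9,
    ontology_depth: int = 4,
    ontology_branching: int = 3,
    seed: int = 0,
) -> SyntheticWorld:
    """Sample a planted logistic world.

    True factors are i.i.d. standard normal; associations are Bernoulli
    with probability sigma(u_i . v_j + bias). Unless given, the intercept
    is solved by root finding so the mean planted probability equals the
    target density. The realized density is then binomial around the
    target.
    """
    if not rank < min(m, n):
        raise ValueError("rank must be smaller than both m and n")
    rng = np.random.default_rng(seed)
    true_U = rng.standard_normal((m, rank))
    true_V = rng.standard_normal((n, rank))
    logits = true_U @ true_V.T
    if bias is None:
        if not (0.0 < density < 1.0):
            raise ValueError("target density must be in (0, 1)")
        bias = float(
            brentq(lambda b: expit(logits + b).mean() - density, -60.0, 60.0, xtol=1e-10)
        )
    probs = expit(logits + bias)
    Yv = (rng.random((m, n)) < probs).astype(float)
    mirna_ids = [f"mir-{i:04d}" for i in range(m)]
    disease_ids = [f"dis-{j:04d}" for j in range(n)]
    mi, di = EntityIndex(mirna_ids), EntityIndex(disease_ids)
    Y = AssociationMatrix(Yv, mi, di)
    MS = SimilarityMatrix(_factor_kernel(true_U), mi, role="MS")
    # branch assignment by recursive random-hyperplane partition of the
    # planted disease factors: diseases that separate only deep in the tree
    # are latently close, so the semantic similarity (like MS) encodes true
    # neighborhood structure at every scale while the topology stays random
    group_of = _latent_groups(true_V, ontology_branching, ontology_depth - 1, rng)
    ontology = make_ontology(
        disease_ids,
        depth=ontology_depth,
        branching=ontology_branching,
        coverage_fraction=coverage_fraction,
        seed=int(rng.integers(2**31)),
        group_of=group_of,
    )
    return SyntheticWorld(
        true_U=true_U,
        true_V=true_V,
        bias=bias,
        Y=Y,
        MS=MS,
        functional_mask=np.ones(m, dtype=bool),
        ontology=ontology,
        seed=seed,
        params=dict(
            m=m, n=n, rank=rank, density=density,
            coverage_fraction=coverage_fraction,
            ontology_depth=ontology_depth, ontology_branching=ontology_branching,
        ),
    )


def shuffle_labels(world: SyntheticWorld, seed: int = 0) -> SyntheticWorld:
    """Negative control: permute Y's cells uniformly, keeping the count.

    Similarities and the ontology are untouched, so any planted signal
    linking them to the associations is destroyed.
    """
    rng = np.random.default_rng(seed)
    flat = world.Y.values.ravel()
    shuffled = flat[rng.permutation(flat.size)].reshape(world.Y.shape)
    return SyntheticWorld(
        true_U=world.true_U,
        true_V=world.true_V,
        bias=world.bias,
        Y=AssociationMatrix(shuffled, world.mirna_index, world.disease_index),
        MS=world.MS,
        functional_mask=world.functional_mask,
        ontology=world.ontology,
        seed=world.seed,
        params=dict(world.params, shuffled_with=seed),
    )
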