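"""Domain containers and text-file I/O for the association-prediction pipeline.

Everything on disk is tab-separated UTF-8 text; ``#`` starts a comment line.
Identifiers are opaque, case-sensitive strings. Rows of the association
matrix are miRNAs, columns are diseases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EntityIndex",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseOntology",
    "SIMILARITY_ROLES",
    "load_association_edges",
    "write_edges",
    "load_matrix",
    "write_matrix",
    "load_ontology",
    "write_ontology",
    "write_predictions",
]

#: matrix roles that denote a square, symmetric similarity in [0, 1]
SIMILARITY_ROLES = frozenset({"MS", "SS1", "SS2", "GD", "GR", "SD", "SR"})

_SYM_TOL = 1e-8  # asymmetry accepted on load, then symmetrized


class EntityIndex:
    """Ordered, unique string identifiers with 0-based positions.

    Order is preserved exactly as first seen, so indices built from the
    same input are deterministic.
    """

    __slots__ = ("ids", "position")

    def __init__(self, ids: Iterable[str]):
        ids = tuple(str(i) for i in ids)
        if any(not i for i in ids):
            raise ValueError("empty identifier in index")
        position = {ident: k for k, ident in enumerate(ids)}
        if len(position) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate identifier {dup!r} in index")
        self.ids = ids
        self.position = position

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, ident: object) -> bool:
        return ident in self.position

    def __getitem__(self, k: int) -> str:
        return self.ids[k]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EntityIndex) and self.ids == other.ids

    def __repr__(self) -> str:  # pragma: no cover
        return f"EntityIndex(n={len(self)})"


@dataclass
class AssociationMatrix:
    """Binary m x n adjacency matrix Y: rows miRNAs, columns diseases."""

    values: np.ndarray
    mirna_index: EntityIndex
    disease_index: EntityIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_index), len(self.disease_index)):
            raise ValueError(
                f"shape {self.values.shape} does not match indices "
                f"({len(self.mirna_index)}, {len(self.disease_index)})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be exactly 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), self.mirna_index, self.disease_index)


@dataclass
class SimilarityMatrix:
    """Square, symmetric, labeled similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    index: EntityIndex
    role: str = "SD"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.index)
        if self.values.shape != (k, k):
            raise ValueError(f"similarity matrix must be {k}x{k}, got {self.values.shape}")
        if self.role not in SIMILARITY_ROLES:
            raise ValueError(f"unknown similarity role {self.role!r}")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > 1e-12:
            raise ValueError(f"similarity matrix asymmetric (max deviation {asym:.3g})")
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValueError("similarity values must lie in [0, 1]")


@dataclass
class DiseaseOntology:
    """Child->parent disease hierarchy; per-disease DAGs are derived from it.

    ``covered`` holds the diseases of the working index that appear anywhere
    in the hierarchy and therefore possess a semantic DAG. Remaining diseases
    fall back to the interaction-profile kernel downstream.
    """

    nodes: frozenset[str]
    parents: dict[str, frozenset[str]]
    covered: frozenset[str]
    graph: nx.DiGraph = field(repr=False, default_factory=nx.DiGraph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], disease_ids: Sequence[str] = ()
    ) -> "DiseaseOntology":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"ontology contains a cycle: {path}")
        nodes = frozenset(g.nodes)
        parents = {n: frozenset(g.successors(n)) for n in g.nodes}
        covered = frozenset(d for d in disease_ids if d in nodes)
        return cls(nodes=nodes, parents=parents, covered=covered, graph=g)

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive closure of parents (excluding the term itself)."""
        return frozenset(nx.descendants(self.graph, term))


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def load_association_edges(
    path: str | Path,
    mirna_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read ``mirna<TAB>disease`` pairs into a binary association matrix.

    Without explicit id lists the index order is the order of first
    appearance in the file. With id lists, those fix the order and entities
    with no edges are kept as all-zero rows/columns; a pair naming an id
    outside the lists is an error.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        tokens = line.split("\t")
        if len(tokens) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated tokens, got {len(tokens)}")
        pair = (tokens[0], tokens[1])
        if pair in seen:
            warnings.warn(f"duplicate association {pair[0]}\t{pair[1]}; keeping a single 1")
            continue
        seen.add(pair)
        pairs.append(pair)

    if mirna_ids is None:
        mirna_ids = list(dict.fromkeys(p[0] for p in pairs))
    if disease_ids is None:
        disease_ids = list(dict.fromkeys(p[1] for p in pairs))
    mi, di = EntityIndex(mirna_ids), EntityIndex(disease_ids)
    values = np.zeros((len(mi), len(di)))
    for r, d in pairs:
        if r not in mi:
            raise ValueError(f"miRNA id {r!r} not in the supplied id list")
        if d not in di:
            raise ValueError(f"disease id {d!r} not in the supplied id list")
        values[mi.position[r], di.position[d]] = 1.0
    return AssociationMatrix(values, mi, di)


def write_edges(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the 1-cells of an association matrix as an edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, r in enumerate(assoc.mirna_index.ids):
            for j, d in enumerate(assoc.disease_index.ids):
                if assoc.values[i, j] == 1.0:
                    fh.write(f"{r}\t{d}\n")


def load_matrix(path: str | Path, role: str) -> SimilarityMatrix | AssociationMatrix:
    """Read a labeled dense TSV matrix (row 1 = column ids, column 1 = row ids).

    Similarity roles are validated square and symmetric to 1e-8, then
    symmetrized as (S + S^T)/2; the ``"Y"`` role is validated binary.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    row_index = EntityIndex(df.index.astype(str))
    col_index = EntityIndex(df.columns.astype(str))
    if role == "Y":
        return AssociationMatrix(values, row_index, col_index)
    if role not in SIMILARITY_ROLES:
        raise ValueError(f"unknown matrix role {role!r}")
    if row_index != col_index:
        raise ValueError(f"similarity matrix in {path} is not square-labeled")
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > _SYM_TOL:
        raise ValueError(f"similarity matrix asymmetric beyond tolerance ({asym:.3g} > {_SYM_TOL})")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, row_index, role=role)


def write_matrix(
    matrix: SimilarityMatrix | AssociationMatrix, path: str | Path
) -> None:
    if isinstance(matrix, AssociationMatrix):
        rows, cols = matrix.mirna_index.ids, matrix.disease_index.ids
    else:
        rows = cols = matrix.index.ids
    # repr round-trips doubles exactly; pandas' default float format does not
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(cols) + "\n")
        for rid, row in zip(rows, matrix.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_ontology(path: str | Path, disease_index: EntityIndex) -> DiseaseOntology:
    """Read ``child<TAB>parent`` lines; verify acyclicity."""
    edges = []
    for lineno, line in _data_lines(path):
        tokens = line.split("\t")
        if len(tokens) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated tokens, got {len(tokens)}")
        edges.append((tokens[0], tokens[1]))
    return DiseaseOntology.from_edges(edges, disease_index.ids)


def write_ontology(ontology: DiseaseOntology, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(ontology.graph.edges):
            fh.write(f"{child}\t{parent}\n")


def write_predictions(
    path: str | Path,
    scores: np.ndarray,
    mirna_index: EntityIndex,
    disease_index: EntityIndex,
    exclude_known: bool = False,
    association: AssociationMatrix | None = None,
) -> None:
    """Write per-disease ranked predictions.

    Rows are ``mirna<TAB>disease<TAB>score<TAB>rank``, sorted within each
    disease by descending score, ties broken by ascending miRNA index.
    With ``exclude_known``, known pairs (y = 1) are removed before ranking,
    so only candidate miRNAs are ranked.
    """
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("NaN score in predictions")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite score in predictions")
    if exclude_known and association is None:
        raise ValueError("exclude_known requires the association matrix")
    with open(path, "w", encoding="utf-8") as fh:
        for j, d in enumerate(disease_index.ids):
            col = scores[:, j]
            rows = np.arange(len(mirna_index))
            if exclude_known:
                rows = rows[association.values[:, j] == 0.0]
            order = rows[np.argsort(-col[rows], kind="stable")]
            for rank, i in enumerate(order, 1):
                fh.write(f"{mirna_index[i]}\t{d}\t{float(col[i])!r}\t{rank}\n")
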