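"""Gaussian interaction profile (GIP) kernel similarity and integration.

The interaction profile of a miRNA is its row of the binary association
matrix Y; a disease's profile is its column. The kernel is

    K(a, b) = exp(-beta * ||IV(a) - IV(b)||^2)

with the bandwidth rescaled by the data so the mean squared profile norm
maps to the original bandwidth beta' (default 1):

    beta = beta' / (mean_k ||IV(k)||^2)

Integration combines the knowledge-based similarities with the kernel:
disease pairs in which both diseases carry a semantic DAG use the average
of the two semantic models, miRNA pairs in which both miRNAs appear in the
functional-similarity matrix use that value; all other pairs fall back to
the GIP kernel. Membership, not the stored value, decides the branch — a
recorded functional similarity of exactly 0 is still used as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import AssociationMatrix, SimilarityMatrix

__all__ = [
    "GipBandwidth",
    "gip_bandwidth",
    "gip_similarity",
    "integrate_disease_similarity",
    "integrate_mirna_similarity",
    "integrated_similarities",
]


@dataclass
class GipBandwidth:
    beta: float
    beta_prime: float
    mean_profile_norm_sq: float


def _profiles(Y: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "mirna":
        return Y.values
    if axis == "disease":
        return Y.values.T
    raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")


def gip_bandwidth(
    Y: AssociationMatrix,
    axis: str,
    beta_prime: float = 1.0,
    on_zero: str = "raise",
) -> GipBandwidth:
    """Data-scaled kernel bandwidth for one axis of the association matrix.

    An all-zero Y leaves the bandwidth undefined. ``on_zero="raise"``
    aborts with advice; ``on_zero="identity"`` returns beta = inf, which
    makes the kernel an identity matrix (only sensible in pathological
    cross-validation folds).
    """
    iv = _profiles(Y, axis)
    mean_sq = float((iv * iv).sum(axis=1).mean())
    if mean_sq == 0.0:
        if on_zero == "identity":
            return GipBandwidth(beta=np.inf, beta_prime=beta_prime, mean_profile_norm_sq=0.0)
        raise ValueError(
            "association matrix is all-zero: GIP bandwidth undefined "
            "(pass on_zero='identity' to fall back to an identity kernel)"
        )
    return GipBandwidth(
        beta=beta_prime / mean_sq, beta_prime=beta_prime, mean_profile_norm_sq=mean_sq
    )


def gip_similarity(
    Y: AssociationMatrix, axis: str, bandwidth: GipBandwidth | None = None
) -> SimilarityMatrix:
    """Gaussian kernel over interaction profiles; diagonal exactly 1."""
    if bandwidth is None:
        bandwidth = gip_bandwidth(Y, axis)
    iv = _profiles(Y, axis)
    role = "GR" if axis == "mirna" else "GD"
    index = Y.mirna_index if axis == "mirna" else Y.disease_index
    if np.isinf(bandwidth.beta):
        return SimilarityMatrix(np.eye(iv.shape[0]), index, role=role)
    if bandwidth.beta <= 0.0:
        raise ValueError("kernel bandwidth must be positive")
    d2 = squareform(pdist(iv, metric="sqeuclidean"))
    values = np.exp(-bandwidth.beta * d2)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, index, role=role)


def _check_same_index(*mats: SimilarityMatrix) -> None:
    first = mats[0].index
    for m in mats[1:]:
        if m.index != first:
            raise ValueError("similarity matrices do not share an entity index")


def integrate_disease_similarity(
    ss1: SimilarityMatrix,
    ss2: SimilarityMatrix,
    gd: SimilarityMatrix,
    covered_mask: np.ndarray,
) -> SimilarityMatrix:
    """SD: average of the two semantic models where defined, else the kernel."""
    _check_same_index(ss1, ss2, gd)
    both = np.outer(covered_mask, covered_mask)
    values = np.where(both, (ss1.values + ss2.values) / 2.0, gd.values)
    return SimilarityMatrix(values, gd.index, role="SD")


def integrate_mirna_similarity(
    ms: SimilarityMatrix,
    gr: SimilarityMatrix,
    functional_mask: np.ndarray,
) -> SimilarityMatrix:
    """SR: functional similarity where both miRNAs have one, else the kernel."""
    _check_same_index(ms, gr)
    both = np.outer(functional_mask, functional_mask)
    values = np.where(both, ms.values, gr.values)
    return SimilarityMatrix(values, gr.index, role="SR")


def integrated_similarities(
    Y: AssociationMatrix,
    ms: SimilarityMatrix,
    functional_mask: np.ndarray,
    ss1: SimilarityMatrix,
    ss2: SimilarityMatrix,
    covered_mask: np.ndarray,
    beta_prime: float = 1.0,
    on_zero: str = "raise",
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Build (SR, SD) for a given (training) association matrix.

    The kernel part depends on Y, so cross-validation calls this per round;
    the semantic matrices and functional similarity are Y-independent and
    are passed in precomputed.
    """
    gr = gip_similarity(Y, "mirna", gip_bandwidth(Y, "mirna", beta_prime, on_zero))
    gd = gip_similarity(Y, "disease", gip_bandwidth(Y, "disease", beta_prime, on_zero))
    sr = integrate_mirna_similarity(ms, gr, functional_mask)
    sd = integrate_disease_similarity(ss1, ss2, gd, covered_mask)
    return sr, sd
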