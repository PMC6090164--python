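"""Neighborhood-regularized logistic matrix factorization (NRLMF).

The model places every miRNA and disease in a shared r-dimensional latent
space (rows ``u_i`` of U, ``v_j`` of V) and scores a pair through the
logistic link ``p_ij = sigma(u_i . v_j)``. Fitting minimizes

    F(U, V) = sum_ij (1 + c*y_ij - y_ij) * ln(1 + exp(u_i . v_j))
              - c * y_ij * (u_i . v_j)
              + 1/2 tr[U^T (lambda_r I + alpha L_r) U]
              + 1/2 tr[V^T (lambda_d I + beta L_d) V]

i.e. a weighted logistic likelihood in which each observed association
counts ``c`` times (c >= 1 up-weights the trustworthy positives against the
mixed unlabeled zeros), Gaussian priors on the factors (lambda = 1/sigma^2),
and graph-Laplacian terms that pull the latent vectors of the K1 most
similar miRNAs/diseases together. L is built from the directed KNN
adjacency A of the integrated similarity:

    L = (diag(row sums A) + diag(col sums A)) - (A + A^T)

Training is alternating gradient descent with AdaGrad step sizes: the U
step uses the current P, V is updated with P recomputed after the U step.

Cold-start smoothing: entities with no training associations (the sets
M- and D-) have factors learned only from unlabeled zeros, so before
prediction their latent vectors are replaced by the similarity-weighted
average of their K2 nearest neighbors among entities that do have
associations (M+ / D+).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterator

import numpy as np
from scipy.special import expit

from .data import AssociationMatrix, SimilarityMatrix

__all__ = [
    "Hyperparameters",
    "DEFAULT_GRID",
    "NeighborGraphs",
    "LatentFactors",
    "knn_adjacency",
    "laplacian",
    "neighbor_graphs",
    "association_probability",
    "objective",
    "gradients",
    "smooth_latent",
    "NRLMF",
    "NRLMFResults",
]

_ADAGRAD_EPS = 1e-10  # inside the square root; avoids 0/0 at the first step


@dataclass(frozen=True)
class Hyperparameters:
    """Tunable knobs of the factorization.

    Defaults: latent dimension 50, lambda = 2^-2, alpha = beta = 2^-3,
    learning rate 2^-1, importance level c = 5 and both neighborhood sizes
    5, trained for 100 fixed iterations (no early stopping, which keeps
    cross-validation deterministic).
    """

    r: int = 50
    lambda_r: float = 0.25
    lambda_d: float = 0.25
    alpha: float = 0.125
    beta: float = 0.125
    c: float = 5.0
    K1: int = 5
    K2: int = 5
    gamma: float = 0.5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("r, K1 and K2 must be positive integers")
        if self.lambda_r <= 0 or self.lambda_d <= 0:
            raise ValueError("lambda_r and lambda_d must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.c < 1:
            raise ValueError("importance level c must be >= 1")
        if self.gamma <= 0:
            raise ValueError("learning rate gamma must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")

    def replace(self, **kw) -> "Hyperparameters":
        return replace(self, **kw)


#: factorial hyperparameter search domains for grid_search
DEFAULT_GRID: dict[str, list] = {
    "r": [50, 100],
    "lambda": [2.0**k for k in range(-5, 2)],
    "alpha": [2.0**k for k in range(-5, 3)],
    "beta": [2.0**k for k in range(-5, 1)],
    "gamma": [2.0**k for k in range(-3, 1)],
}


@dataclass
class LatentFactors:
    U: np.ndarray
    V: np.ndarray
    grad_accum_U: np.ndarray
    grad_accum_V: np.ndarray


@dataclass
class NeighborGraphs:
    A: np.ndarray
    B: np.ndarray
    L_r: np.ndarray
    L_d: np.ndarray


def knn_adjacency(S: SimilarityMatrix | np.ndarray, k: int) -> np.ndarray:
    """Directed K-nearest-neighbor adjacency of a similarity matrix.

    Row i keeps S(i, mu) for the k most similar entities mu != i and zeros
    elsewhere; ties break toward the lower index; with fewer than k
    candidates all are kept. The result is not symmetric in general.
    """
    if k <= 0:
        raise ValueError("neighborhood size must be positive")
    S = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = S.shape[0]
    A = np.zeros_like(S)
    for i in range(n):
        sims = S[i].copy()
        sims[i] = -np.inf  # never a neighbor of itself
        # stable sort on the negated values -> ties resolved by ascending index
        order = np.argsort(-sims, kind="stable")[: min(k, n - 1)]
        A[i, order] = S[i, order]
    return A


def laplacian(A: np.ndarray) -> np.ndarray:
    """Graph Laplacian of a directed non-negative adjacency.

    L = (diag(row sums) + diag(col sums)) - (A + A^T); symmetric, positive
    semidefinite, and annihilates the constant vector, so
    1/2 sum_{i,mu} a_{i mu} ||u_i - u_mu||^2 = 1/2 tr(U^T L U).
    """
    A = np.asarray(A, dtype=float)
    deg = np.diag(A.sum(axis=1) + A.sum(axis=0))
    return deg - (A + A.T)


def neighbor_graphs(sr: SimilarityMatrix, sd: SimilarityMatrix, k1: int) -> NeighborGraphs:
    A = knn_adjacency(sr, k1)
    B = knn_adjacency(sd, k1)
    return NeighborGraphs(A=A, B=B, L_r=laplacian(A), L_d=laplacian(B))


_P_MAX = float(np.nextafter(1.0, 0.0))
_P_MIN = float(np.nextafter(0.0, 1.0))


def association_probability(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Logistic link P = sigma(U V^T), overflow-stable, entries in (0, 1).

    Saturated inner products are clamped one ulp inside the open interval
    so downstream ranking never sees an exact 0 or 1.
    """
    return np.clip(expit(U @ V.T), _P_MIN, _P_MAX)


def objective(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    c: float,
    lambda_r: float,
    lambda_d: float,
    alpha: float,
    beta: float,
    L_r: np.ndarray,
    L_d: np.ndarray,
) -> float:
    """Regularized weighted logistic loss F (to be minimized)."""
    X = U @ V.T
    softplus = np.logaddexp(0.0, X)
    loss = ((1.0 + c * Y - Y) * softplus - c * Y * X).sum()
    reg_u = 0.5 * (lambda_r * (U * U).sum() + alpha * np.trace(U.T @ (L_r @ U)))
    reg_v = 0.5 * (lambda_d * (V * V).sum() + beta * np.trace(V.T @ (L_d @ V)))
    return float(loss + reg_u + reg_v)


def _grad_U(U, V, Y, P, c, lambda_r, alpha, L_r):
    W = P + (c - 1.0) * (Y * P) - c * Y
    return W @ V + lambda_r * U + alpha * (L_r @ U)


def _grad_V(U, V, Y, P, c, lambda_d, beta, L_d):
    W = P + (c - 1.0) * (Y * P) - c * Y
    return W.T @ U + lambda_d * V + beta * (L_d @ V)


def gradients(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    P: np.ndarray,
    c: float,
    lambda_r: float,
    lambda_d: float,
    alpha: float,
    beta: float,
    L_r: np.ndarray,
    L_d: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives of F with respect to U and V (both at the same P)."""
    return (
        _grad_U(U, V, Y, P, c, lambda_r, alpha, L_r),
        _grad_V(U, V, Y, P, c, lambda_d, beta, L_d),
    )


def _knn_weighted_rows(
    target: np.ndarray,
    S: np.ndarray,
    cold: np.ndarray,
    warm: np.ndarray,
    k: int,
) -> np.ndarray:
    """Replace rows ``cold`` of ``target`` by similarity-weighted averages of
    their k most similar rows among ``warm`` (ties toward lower index)."""
    out = target.copy()
    k = min(k, len(warm))
    for i in cold:
        sims = S[i, warm]
        order = np.argsort(-sims, kind="stable")[:k]
        nbrs = warm[order]
        w = S[i, nbrs]
        total = w.sum()
        if total > 0.0:
            out[i] = (w @ target[nbrs]) / total
        else:  # all neighbor similarities zero: fall back to the plain mean
            out[i] = target[nbrs].mean(axis=0)
    return out


def smooth_latent(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    SR: np.ndarray,
    SD: np.ndarray,
    k2: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cold-start smoothing of the latent factors.

    miRNAs (diseases) with no training association get the similarity-
    weighted average of the latent vectors of their k2 nearest miRNAs
    (diseases) that do have associations; warm entities keep their vectors.
    """
    m_pos = np.flatnonzero(Y.sum(axis=1) > 0)
    m_neg = np.flatnonzero(Y.sum(axis=1) == 0)
    d_pos = np.flatnonzero(Y.sum(axis=0) > 0)
    d_neg = np.flatnonzero(Y.sum(axis=0) == 0)
    if m_neg.size and not m_pos.size:
        raise ValueError("no miRNA with a training association to smooth from")
    if d_neg.size and not d_pos.size:
        raise ValueError("no disease with a training association to smooth from")
    U_s = _knn_weighted_rows(U, SR, m_neg, m_pos, k2) if m_neg.size else U.copy()
    V_s = _knn_weighted_rows(V, SD, d_neg, d_pos, k2) if d_neg.size else V.copy()
    return U_s, V_s


class NRLMF:
    """Neighborhood-regularized logistic matrix factorization model.

    Parameters
    ----------
    Y : AssociationMatrix
        Binary training associations (rows miRNAs, columns diseases).
    mirna_similarity, disease_similarity : SimilarityMatrix
        Integrated similarities SR and SD on the same indices as Y.
    hyper : Hyperparameters, optional
        Model and optimizer settings; see :class:`Hyperparameters`.

    Examples
    --------
    >>> model = NRLMF(Y, SR, SD)
    >>> res = model.fit(seed=0)
    >>> scores = res.predict()          # smoothed association probabilities
    >>> print(res.summary())
    """

    def __init__(
        self,
        Y: AssociationMatrix,
        mirna_similarity: SimilarityMatrix,
        disease_similarity: SimilarityMatrix,
        hyper: Hyperparameters | None = None,
    ):
        if mirna_similarity.index != Y.mirna_index:
            raise ValueError("miRNA similarity index does not match the association rows")
        if disease_similarity.index != Y.disease_index:
            raise ValueError("disease similarity index does not match the association columns")
        self.Y = Y
        self.SR = mirna_similarity
        self.SD = disease_similarity
        self.hyper = hyper or Hyperparameters()
        self.graphs = neighbor_graphs(self.SR, self.SD, self.hyper.K1)

    def initialize(self, seed: int | np.random.SeedSequence) -> tuple[np.ndarray, np.ndarray]:
        """Draw U, V i.i.d. zero-mean Gaussian with standard deviation 1/sqrt(r)."""
        rng = np.random.default_rng(seed)
        m, n = self.Y.shape
        r = self.hyper.r
        scale = 1.0 / np.sqrt(r)
        U = rng.standard_normal((m, r)) * scale
        V = rng.standard_normal((n, r)) * scale
        return U, V

    def fit(self, seed: int | np.random.SeedSequence | None = None) -> "NRLMFResults":
        """Run AdaGrad alternating descent for ``max_iter`` iterations."""
        h = self.hyper
        seed = h.seed if seed is None else seed
        Y = self.Y.values
        L_r, L_d = self.graphs.L_r, self.graphs.L_d
        U, V = self.initialize(seed)
        GU = np.zeros_like(U)
        GV = np.zeros_like(V)

        def obj(U, V):
            return objective(U, V, Y, h.c, h.lambda_r, h.lambda_d, h.alpha, h.beta, L_r, L_d)

        trace = [obj(U, V)]
        for it in range(h.max_iter):
            P = association_probability(U, V)
            dU = _grad_U(U, V, Y, P, h.c, h.lambda_r, h.alpha, L_r)
            GU = GU + dU * dU
            U = U - h.gamma * dU / np.sqrt(GU + _ADAGRAD_EPS)
            P = association_probability(U, V)
            dV = _grad_V(U, V, Y, P, h.c, h.lambda_d, h.beta, L_d)
            GV = GV + dV * dV
            V = V - h.gamma * dV / np.sqrt(GV + _ADAGRAD_EPS)
            f = obj(U, V)
            if not np.isfinite(f):
                raise FloatingPointError(
                    f"objective became non-finite at iteration {it + 1}; "
                    "try a smaller learning rate gamma"
                )
            trace.append(f)
        factors = LatentFactors(U=U, V=V, grad_accum_U=GU, grad_accum_V=GV)
        return NRLMFResults(model=self, factors=factors, objective_trace=np.array(trace))


@dataclass
class NRLMFResults:
    """Fitted factors plus diagnostics; prediction applies cold-start smoothing."""

    model: NRLMF
    factors: LatentFactors
    objective_trace: np.ndarray
    _smoothed: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    @property
    def U(self) -> np.ndarray:
        return self.factors.U

    @property
    def V(self) -> np.ndarray:
        return self.factors.V

    @property
    def positive_mirnas(self) -> np.ndarray:
        return np.flatnonzero(self.model.Y.values.sum(axis=1) > 0)

    @property
    def positive_diseases(self) -> np.ndarray:
        return np.flatnonzero(self.model.Y.values.sum(axis=0) > 0)

    def smoothed_factors(self, k2: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        if self._smoothed is None or k2 is not None:
            k2 = self.model.hyper.K2 if k2 is None else k2
            sm = smooth_latent(
                self.U, self.V, self.model.Y.values,
                self.model.SR.values, self.model.SD.values, k2,
            )
            if k2 == self.model.hyper.K2:
                self._smoothed = sm
            return sm
        return self._smoothed

    def predict(self, smooth: bool = True) -> np.ndarray:
        """Association probability for every pair, in (0, 1)."""
        if smooth:
            U, V = self.smoothed_factors()
        else:
            U, V = self.U, self.V
        return association_probability(U, V)

    def summary(self) -> str:
        h = self.model.hyper
        m, n = self.model.Y.shape
        k = self.model.Y.n_associations
        lines = [
            "Neighborhood-Regularized Logistic Matrix Factorization",
            "=" * 54,
            f"{'miRNAs (m)':<28}{m:>10}",
            f"{'diseases (n)':<28}{n:>10}",
            f"{'known associations':<28}{k:>10}",
            f"{'density':<28}{k / (m * n):>10.4f}",
            f"{'latent dimension r':<28}{h.r:>10}",
            f"{'lambda_r / lambda_d':<28}{f'{h.lambda_r:g} / {h.lambda_d:g}':>10}",
            f"{'alpha / beta':<28}{f'{h.alpha:g} / {h.beta:g}':>10}",
            f"{'importance level c':<28}{h.c:>10g}",
            f"{'K1 / K2':<28}{f'{h.K1} / {h.K2}':>10}",
            f"{'learning rate gamma':<28}{h.gamma:>10g}",
            f"{'iterations':<28}{h.max_iter:>10}",
            f"{'initial objective':<28}{self.objective_trace[0]:>10.4f}",
            f"{'final objective':<28}{self.objective_trace[-1]:>10.4f}",
            f"{'cold-start miRNAs':<28}{m - len(self.positive_mirnas):>10}",
            f"{'cold-start diseases':<28}{n - len(self.positive_diseases):>10}",
        ]
        return "\n".join(lines)


def grid_points(grid: dict[str, list] | None = None, base: Hyperparameters | None = None) -> Iterator[Hyperparameters]:
    """Expand a search grid (keys r/lambda/alpha/beta/gamma) to settings."""
    grid = DEFAULT_GRID if grid is None else grid
    base = base or Hyperparameters()
    for r, lam, alpha, beta, gamma in product(
        grid.get("r", [base.r]),
        grid.get("lambda", [base.lambda_r]),
        grid.get("alpha", [base.alpha]),
        grid.get("beta", [base.beta]),
        grid.get("gamma", [base.gamma]),
    ):
        yield base.replace(
            r=int(r), lambda_r=float(lam), lambda_d=float(lam),
            alpha=float(alpha), beta=float(beta), gamma=float(gamma),
        )
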