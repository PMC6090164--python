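"""Cross-validation protocols and ranking metrics.

Three schemes are provided. Global leave-one-out hides each known
association in turn, retrains, and ranks its score against every pair that
is unknown in the full matrix. Local leave-one-out ranks the held-out pair
only against the unknown pairs of the same disease. Repeated k-fold
partitions the known associations (the 1-cells, not rows or columns) into k
parts per repeat and hides each part in turn.

The AUC is rank-based: the probability that a held-out positive outscores a
random candidate, ties counted 1/2 — identical to the area under the
threshold-swept ROC. Leave-one-out rounds are pooled into a single AUC;
k-fold reports a per-repeat AUC with mean and standard deviation.

By default every round rebuilds the interaction-profile kernel (and hence
the integrated similarities) from the round's training matrix so no
information about the hidden pairs leaks into the features
(``leakage="recompute"``); ``leakage="fixed"`` computes them once from the
full matrix, which is cheaper and mirrors protocols that do not re-derive
features per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AssociationMatrix, DiseaseOntology, SimilarityMatrix
from .model import NRLMF, Hyperparameters, grid_points
from .profiles import integrated_similarities
from .semantic import semantic_similarity_matrices

__all__ = [
    "CVResult",
    "roc_auc",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "new_entity_validation",
    "grid_search",
]


@dataclass
class CVResult:
    scheme: str
    ranks: pd.DataFrame
    roc: np.ndarray
    auc: float
    seed: int
    repeat_aucs: np.ndarray | None = None

    @property
    def auc_std(self) -> float | None:
        if self.repeat_aucs is None:
            return None
        return float(self.repeat_aucs.std(ddof=1)) if len(self.repeat_aucs) > 1 else 0.0


# ---------------------------------------------------------------------------
# metrics


def _percentile(score: float, candidates: np.ndarray) -> float:
    """Fraction of candidates strictly below the score, ties counted 1/2."""
    below = np.count_nonzero(candidates < score)
    ties = np.count_nonzero(candidates == score)
    return (below + 0.5 * ties) / candidates.size


def _rank(score: float, candidates: np.ndarray) -> float:
    """1-based competition rank among the candidates, ties averaged."""
    greater = np.count_nonzero(candidates > score)
    ties = np.count_nonzero(candidates == score)
    return greater + 1.0 + 0.5 * ties


def roc_auc(
    test_scores: np.ndarray, candidate_scores: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points and rank-based AUC of positives vs candidates."""
    pos = np.asarray(test_scores, dtype=float)
    neg = np.asarray(candidate_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise ValueError("scores must be finite")
    # threshold sweep over descending unique scores
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(scores)), scores.size - 1]
    tps = np.cumsum(labels)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / pos.size]
    fpr = np.r_[0.0, fps / neg.size]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _roc_from_percentiles(u: np.ndarray) -> np.ndarray:
    """Pooled ROC over normalized ranks: FPR threshold vs fraction of
    positives whose candidate-exceedance is below it."""
    q = np.sort(1.0 - u)  # per-positive fraction of candidates at/above it
    xs = np.r_[0.0, np.unique(q), 1.0]
    ys = np.searchsorted(q, xs, side="right") / q.size
    ys[0] = 0.0
    return np.column_stack([xs, ys])


# ---------------------------------------------------------------------------
# shared per-round training pipeline


class _Pipeline:
    """Precomputes Y-independent features; builds similarities per round."""

    def __init__(
        self,
        Y: AssociationMatrix,
        ms: SimilarityMatrix | None,
        ontology: DiseaseOntology | None,
        hyper: Hyperparameters,
        leakage: str = "recompute",
        delta: float = 0.5,
        beta_prime: float = 1.0,
    ):
        if leakage not in ("recompute", "fixed"):
            raise ValueError("leakage mode must be 'recompute' or 'fixed'")
        self.Y = Y
        self.hyper = hyper
        self.leakage = leakage
        self.beta_prime = beta_prime
        m = len(Y.mirna_index)
        if ms is None:
            self.ms = SimilarityMatrix(np.zeros((m, m)), Y.mirna_index, role="MS")
            self.functional_mask = np.zeros(m, dtype=bool)
        else:
            self.ms, self.functional_mask = _align_ms(ms, Y)
        if ontology is None:
            n = len(Y.disease_index)
            zeros = np.zeros((n, n))
            self.ss1 = SimilarityMatrix(zeros, Y.disease_index, role="SS1")
            self.ss2 = SimilarityMatrix(zeros.copy(), Y.disease_index, role="SS2")
            self.covered_mask = np.zeros(n, dtype=bool)
        else:
            self.ss1, self.ss2, self.covered_mask = semantic_similarity_matrices(
                ontology, Y.disease_index, delta
            )
        self._fixed = None
        if leakage == "fixed":
            self._fixed = self._similarities(Y)

    def _similarities(self, Y: AssociationMatrix):
        return integrated_similarities(
            Y, self.ms, self.functional_mask, self.ss1, self.ss2, self.covered_mask,
            beta_prime=self.beta_prime, on_zero="identity",
        )

    def fit_score(self, train_values: np.ndarray, seed) -> np.ndarray:
        """Train on a masked copy of Y and return smoothed scores."""
        Yt = AssociationMatrix(train_values, self.Y.mirna_index, self.Y.disease_index)
        sr, sd = self._fixed if self._fixed is not None else self._similarities(Yt)
        res = NRLMF(Yt, sr, sd, self.hyper).fit(seed=seed)
        return res.predict(smooth=True)


def _align_ms(
    ms: SimilarityMatrix, Y: AssociationMatrix
) -> tuple[SimilarityMatrix, np.ndarray]:
    """Embed a (possibly partial) functional-similarity matrix into the full
    miRNA index; the mask marks miRNAs present in the supplied matrix."""
    if ms.index == Y.mirna_index:
        return ms, np.ones(len(Y.mirna_index), dtype=bool)
    full = np.zeros((len(Y.mirna_index), len(Y.mirna_index)))
    mask = np.array([r in ms.index for r in Y.mirna_index.ids], dtype=bool)
    rows = [Y.mirna_index.position[r] for r in ms.index.ids if r in Y.mirna_index]
    src = [ms.index.position[r] for r in ms.index.ids if r in Y.mirna_index]
    full[np.ix_(rows, rows)] = ms.values[np.ix_(src, src)]
    return SimilarityMatrix(full, Y.mirna_index, role="MS"), mask


def _positives(Y: AssociationMatrix) -> np.ndarray:
    return np.argwhere(Y.values == 1.0)


# ---------------------------------------------------------------------------
# schemes


def _loocv(
    Y: AssociationMatrix,
    ms: SimilarityMatrix | None,
    ontology: DiseaseOntology | None,
    hyper: Hyperparameters | None,
    leakage: str,
    seed: int,
    local: bool,
    delta: float = 0.5,
) -> CVResult:
    hyper = hyper or Hyperparameters()
    pipe = _Pipeline(Y, ms, ontology, hyper, leakage, delta)
    positives = _positives(Y)
    if positives.size == 0:
        raise ValueError("leave-one-out requires at least one known association")
    cand_mask = Y.values == 0.0
    records = []
    for round_idx, (i, j) in enumerate(positives):
        if local and not cand_mask[:, j].any():
            warnings.warn(
                f"disease {Y.disease_index[j]!r} has no candidate miRNAs; round skipped"
            )
            continue
        train = Y.values.copy()
        train[i, j] = 0.0
        scores = pipe.fit_score(train, np.random.SeedSequence([seed, round_idx]))
        cand = scores[:, j][cand_mask[:, j]] if local else scores[cand_mask]
        records.append(
            (
                Y.mirna_index[i],
                Y.disease_index[j],
                _rank(scores[i, j], cand),
                cand.size,
                _percentile(scores[i, j], cand),
            )
        )
    ranks = pd.DataFrame(
        records, columns=["mirna", "disease", "rank", "n_candidates", "percentile"]
    )
    u = ranks["percentile"].to_numpy()
    return CVResult(
        scheme="local_loocv" if local else "global_loocv",
        ranks=ranks,
        roc=_roc_from_percentiles(u),
        auc=float(u.mean()),
        seed=seed,
    )


def global_loocv(
    Y: AssociationMatrix,
    ms: SimilarityMatrix | None = None,
    ontology: DiseaseOntology | None = None,
    hyper: Hyperparameters | None = None,
    leakage: str = "recompute",
    seed: int = 0,
) -> CVResult:
    """Each known association left out in turn, ranked against all pairs
    unknown in the full matrix; one pooled AUC."""
    return _loocv(Y, ms, ontology, hyper, leakage, seed, local=False)


def local_loocv(
    Y: AssociationMatrix,
    ms: SimilarityMatrix | None = None,
    ontology: DiseaseOntology | None = None,
    hyper: Hyperparameters | None = None,
    leakage: str = "recompute",
    seed: int = 0,
) -> CVResult:
    """As global LOOCV, but ranked only against the unknown pairs of the
    held-out pair's own disease."""
    return _loocv(Y, ms, ontology, hyper, leakage, seed, local=True)


def kfold_cv(
    Y: AssociationMatrix,
    ms: SimilarityMatrix | None = None,
    ontology: DiseaseOntology | None = None,
    hyper: Hyperparameters | None = None,
    k: int = 5,
    repeats: int = 100,
    leakage: str = "recompute",
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold over the known associations; mean +/- sd AUC."""
    if k < 2:
        raise ValueError("k must be at least 2")
    hyper = hyper or Hyperparameters()
    pipe = _Pipeline(Y, ms, ontology, hyper, leakage)
    positives = _positives(Y)
    if len(positives) < k:
        raise ValueError(f"need at least k={k} known associations, have {len(positives)}")
    cand_mask = Y.values == 0.0
    rng = np.random.default_rng(seed)
    records = []
    repeat_aucs = []
    for rep in range(repeats):
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, k)
        us = []
        for fold_id, fold in enumerate(folds):
            train = Y.values.copy()
            pairs = positives[fold]
            train[pairs[:, 0], pairs[:, 1]] = 0.0
            scores = pipe.fit_score(
                train, np.random.SeedSequence([seed, rep, fold_id])
            )
            cand = scores[cand_mask]
            for i, j in pairs:
                u = _percentile(scores[i, j], cand)
                us.append(u)
                records.append(
                    (
                        rep,
                        fold_id,
                        Y.mirna_index[i],
                        Y.disease_index[j],
                        _rank(scores[i, j], cand),
                        cand.size,
                        u,
                    )
                )
        repeat_aucs.append(float(np.mean(us)))
    ranks = pd.DataFrame(
        records,
        columns=["repeat", "fold", "mirna", "disease", "rank", "n_candidates", "percentile"],
    )
    repeat_aucs = np.array(repeat_aucs)
    return CVResult(
        scheme="kfold",
        ranks=ranks,
        roc=_roc_from_percentiles(ranks["percentile"].to_numpy()),
        auc=float(repeat_aucs.mean()),
        seed=seed,
        repeat_aucs=repeat_aucs,
    )


def new_entity_validation(
    Y: AssociationMatrix,
    ms: SimilarityMatrix | None,
    ontology: DiseaseOntology | None,
    hyper: Hyperparameters | None,
    disease: str,
    leakage: str = "recompute",
    seed: int = 0,
) -> pd.DataFrame:
    """Hide every association of one disease, retrain, rank all miRNAs.

    The disease's training column is all-zero, so its latent vector comes
    entirely from the cold-start smoothing path. Returns one row per miRNA
    with its score and 1-based rank (descending score, ties by index).
    """
    if disease not in Y.disease_index:
        raise ValueError(f"unknown disease id {disease!r}")
    j = Y.disease_index.position[disease]
    if not (Y.values[:, j] == 1.0).any():
        raise ValueError(f"disease {disease!r} has no known association to hide")
    hyper = hyper or Hyperparameters()
    pipe = _Pipeline(Y, ms, ontology, hyper, leakage)
    train = Y.values.copy()
    train[:, j] = 0.0
    scores = pipe.fit_score(train, np.random.SeedSequence([seed, j]))
    col = scores[:, j]
    order = np.argsort(-col, kind="stable")
    return pd.DataFrame(
        {
            "mirna": [Y.mirna_index[i] for i in order],
            "score": col[order],
            "rank": np.arange(1, len(order) + 1),
            "known": Y.values[order, j].astype(int),
        }
    )


def grid_search(
    Y: AssociationMatrix,
    ms: SimilarityMatrix | None = None,
    ontology: DiseaseOntology | None = None,
    grid: dict[str, list] | None = None,
    base: Hyperparameters | None = None,
    k: int = 5,
    repeats: int = 2,
    leakage: str = "recompute",
    seed: int = 0,
    evaluator=None,
) -> tuple[Hyperparameters, pd.DataFrame]:
    """Exhaustive grid evaluation by repeated k-fold CV.

    Returns the argmax-mean-AUC setting (ties broken toward smaller r, then
    smaller lambda, by iteration order over the sorted grid) and the full
    table. ``evaluator`` may replace the default CV scorer with any
    callable mapping a Hyperparameters to an AUC (used for cheap selection
    protocols).
    """
    if grid is not None and not grid:
        raise ValueError("grid must be nonempty")
    if grid is not None:
        grid = {key: sorted(vals) for key, vals in grid.items()}
    if evaluator is None:
        def evaluator(h: Hyperparameters) -> float:
            return kfold_cv(Y, ms, ontology, h, k=k, repeats=repeats,
                            leakage=leakage, seed=seed).auc

    rows = []
    best: tuple[float, Hyperparameters] | None = None
    for h in grid_points(grid, base):
        auc = float(evaluator(h))
        rows.append((h.r, h.lambda_r, h.alpha, h.beta, h.gamma, auc))
        if best is None or auc > best[0]:
            best = (auc, h)
    table = pd.DataFrame(rows, columns=["r", "lambda", "alpha", "beta", "gamma", "auc"])
    return best[1], table
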