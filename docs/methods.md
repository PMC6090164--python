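# Methods

## Model

The package predicts missing edges of a sparse bipartite graph: `m` miRNAs
× `n` diseases with a binary adjacency matrix `Y` of experimentally
confirmed associations. Each entity gets a latent vector in a shared
`r`-dimensional space, and a pair's association probability is the
logistic of the inner product, `p_ij = σ(u_i·v_j)`. Three assumptions
drive the design:

1. **Positive-unlabeled data.** The zeros of `Y` mix true negatives with
   undiscovered positives. The likelihood therefore counts every confirmed
   association `c` times (importance level, default 5), which biases the
   fit toward respecting the trustworthy ones.
2. **Gaussian priors.** Latent vectors are a priori zero-mean Gaussian
   with variance `1/λ` per coordinate, giving Frobenius penalties
   `λ_r‖U‖²/2`, `λ_d‖V‖²/2`.
3. **Neighborhood smoothness.** Functionally similar miRNAs (and
   semantically similar diseases) should have nearby latent vectors. For
   each entity the `K1` most similar others (self excluded, ties to the
   lower index) define a directed KNN adjacency `A`; the penalty
   `α/2 Σ a_iμ‖u_i−u_μ‖²` equals `α/2 tr(UᵀL_rU)` with the Laplacian
   `L = (diag(row sums) + diag(col sums)) − (A + Aᵀ)`, which is symmetric,
   positive semidefinite and annihilates constants.

The objective is minimized by alternating gradient descent: per iteration
a U-step with the current probabilities, then a V-step with probabilities
recomputed after the U update. Step sizes are AdaGrad:
`U ← U − γ·dU/√(G_U + ε)` with `G_U` the running sum of squared gradients.

## Similarities

- **Disease semantic similarity** operates on per-disease DAGs (the
  disease plus its ancestors in a MeSH-style child→parent hierarchy). Two
  contribution models: geometric decay (the disease contributes 1, an
  ancestor `max(Δ·child)` over its children inside the DAG; Δ default 0.5)
  and information content (`−ln(fraction of disease DAGs containing the
  term)`, natural log — any fixed base cancels in the similarity ratio).
  The similarity of two diseases is the summed contribution of the shared
  DAG terms over the two total semantic values; the matrix uses the
  average of both models. The "children of a term" are restricted to
  children within the disease's own DAG, and the DAG-count denominator is
  the number of diseases possessing DAGs.
- **GIP kernel.** `exp(−β‖IV(a)−IV(b)‖²)` over interaction profiles
  (rows/columns of `Y`), with `β = β′ / mean‖IV‖²` and `β′ = 1`. A fully
  empty training matrix leaves the bandwidth undefined; the default is to
  raise, with an explicit identity-kernel fallback reserved for
  pathological cross-validation folds.
- **Integration.** Disease pairs in which both diseases have a DAG use the
  semantic average; miRNA pairs in which both miRNAs appear in the
  functional-similarity matrix use that value (membership decides, so a
  recorded similarity of exactly 0 is still used); all other pairs fall
  back to the GIP kernel.

## Cold start

Entities whose training row/column is all zero are fitted against
unlabeled data only, so before prediction their latent vector is replaced
by the similarity-weighted average of their `K2` nearest neighbors among
entities that do have associations (weights renormalized; if every
neighbor similarity is 0 the plain mean is used; `K2` is capped at the
pool size). Warm entities keep their fitted vectors.

## Parameters

| name | meaning | default | why |
|---|---|---|---|
| `r` | latent dimension | 50 | search domain {50, 100} |
| `lambda_r = lambda_d` | prior precision | 2⁻² | center of the 2⁻⁵..2¹ domain |
| `alpha`, `beta` | miRNA / disease neighborhood weight | 2⁻³ | domains 2⁻⁵..2², 2⁻⁵..2⁰ |
| `c` | importance of confirmed pairs | 5 | standard empirical choice |
| `K1`, `K2` | neighborhood sizes | 5 | standard empirical choice |
| `gamma` | AdaGrad learning rate | 2⁻¹ | domain 2⁻³..2⁰ |
| `max_iter` | training iterations | 100 | converges on the shipped fixtures |
| `delta` | semantic decay factor | 0.5 | standard choice for MeSH DAGs |

All are dimensionless. `grid_search` evaluates the full factorial domain
by repeated k-fold CV, ties broken toward smaller `r` then smaller `λ`.

## Numerical choices

- Initialization: i.i.d. zero-mean Gaussian with sd `1/√r`, so initial
  inner products are O(1) regardless of `r`; seeded, and identical seeds
  reproduce `U`, `V` bitwise.
- `softplus` via `log1p`/`logaddexp`; probabilities computed with the
  overflow-stable logistic and clamped one ulp inside (0, 1) so ranking
  never sees saturated 0/1 scores.
- AdaGrad `ε = 1e-10` inside the square root (avoids 0/0 at the first
  step without changing the scale of later steps).
- Fixed iteration count, no early stopping: keeps per-round training in
  cross-validation deterministic.
- Ties everywhere (KNN selection, smoothing neighbors, output ranking)
  break toward the lower entity index; AUC handles score ties as 1/2.
- A non-finite objective aborts training with advice to lower `γ`.

## Cross-validation protocols

Global LOOCV hides each known association in turn and ranks its
retrained score against all pairs unknown in the *full* matrix (one
pooled AUC over rounds). Local LOOCV ranks only against the unknown pairs
of the same disease. k-fold partitions the known associations (cells, not
rows) into k parts per repeat and reports mean ± sd AUC over repeats. By
default (`leakage="recompute"`) the GIP kernel and integrated similarities
are rebuilt from each round's training matrix, so hidden pairs cannot leak
through the features; `leakage="fixed"` computes them once from the full
matrix, matching cheaper published protocols. Whether the original
protocol retrained per round is not documented anywhere we know of;
retraining with recomputation is the statistically honest default. All
schemes derive every round's fit seed from the scheme seed, so results are
reproducible end to end.

## Synthetic worlds

The generator plants the exact structure the model assumes: factors
`U* ∈ R^{m×10}`, `V*` i.i.d. standard normal, `y_ij ~ Bernoulli(σ(u_i·v_j + b))`
with the intercept `b` solved so the expected density matches a target
(default 3%, close to curated miRNA–disease catalogs). The functional
similarity is a radial kernel over the true miRNA factors
(median-heuristic bandwidth), so KNN graphs carry genuine neighborhood
signal. The disease hierarchy is a random k-ary tree (default depth 4,
branching 3) whose leaf attachment follows a recursive random-hyperplane
partition of the true disease factors: diseases that separate only deep in
the tree are latently close, making semantic similarity informative at
every scale, as MeSH is for real diseases. A coverage fraction (default
0.9, mirroring that nearly all curated diseases carry MeSH descriptors)
leaves some diseases out of the hierarchy to exercise the kernel fallback.
`shuffle_labels` permutes the cells of `Y` uniformly as a negative
control.

What the worlds do **not** emulate: the heavy-tailed degree distribution
of real catalogs, study-driven discovery bias (well-studied diseases
accumulate associations), multiple descriptors per disease, and noise in
the functional similarity (the kernel is computed from the true factors,
i.e. it is optimistic). Passing tests on these worlds therefore
demonstrate correctness of the machinery and recoverability of planted
structure, not real-data performance.

## Scale dependence of ranking accuracy

Ranking accuracy under cross-validation depends strongly on the number of
associations *per entity*, not only on density. At a fixed 3% density a
100×80 world holds ~2.6 associations per miRNA, whereas a catalog-sized
495×383 world at the same density holds ~11 — roughly four times the
information for identifying each latent vector. `scripts/acceptance.py`
computes the repeated 5-fold AUC at both sizes with identical, untuned
default hyperparameters; the catalog-scale run scores substantially
higher, and the desk-scale run sits well above its label-shuffled control
but below published catalog-scale figures. Desk-scale CV numbers should
therefore be read as relative (against controls and between variants),
not as absolute performance estimates.

## Known limitations

- The GIP similarity of an entity with an empty profile decays only with
  the *other* entity's degree, so it carries no information about which
  neighbors are relevant; cold-start quality therefore rests entirely on
  the semantic/functional channel. With shallow hierarchies the
  decay-model similarity of same-branch diseases is bounded near 0.5 and
  can be outranked by those spurious kernel values on mixed
  covered/uncovered pairs.
- LOOCV retrains once per known association; at catalog scale this is
  thousands of fits and is best run with `leakage="fixed"` or replaced by
  k-fold.
- Hyperparameter search is exhaustive; no smarter search is provided.
- One DAG per disease; mapping disease names to hierarchy terms is the
  caller's responsibility.
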