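# Methods

## Problem and model

`trilink` predicts disease-associated (lncRNA, miRNA) pairs by
completing a binary 3-way association tensor. The underlying
assumptions are the field's usual ones: functionally similar entities
tend to associate with similar diseases, and the joint association
structure is approximately low multilinear rank, so a small nonnegative
Tucker model can interpolate unobserved triples from observed ones.

The pipeline has four stages.

### 1. Tensor construction

Three bipartite association networks (disease–lncRNA, disease–miRNA,
lncRNA–miRNA) are read from tab-separated edge lists (deduplicated in
file order, identifiers treated as opaque strings; no identifier
harmonization is attempted). A triple (d, l, m) enters the tripartite
network exactly when its three projected pairs are edges — the
construction is implemented as an order-independent exhaustive triangle
enumeration so the result is deterministic; entities participating in
no triangle are dropped. Index maps are ordered by first appearance in
the input files and recorded in every export, so slices are
reproducible.

### 2. Similarity matrices

* **Disease semantic similarity.** Each disease spans a DAG of itself
  and its ancestors, derived from MeSH tree-number prefixes. An
  ancestor's contribution decays multiplicatively with depth,
  D_d(a) = max{Δ·D_d(c)} over children c on paths toward d, with
  Δ = 0.5 (the conventional value for this decay). Pair similarity is
  the shared-ancestor contribution sum normalised by DV(d_i) + DV(d_j).
  Diseases absent from the vocabulary are flagged; their combined
  similarity falls back to the GIP value alone (pairwise: the average
  is used only when both diseases have a DAG).
* **GIP kernels.** exp(−γ‖p_i − p_j‖²) on binary association profiles,
  with bandwidth γ = n/Σᵢ‖p_i‖² recomputed per profile matrix. Disease
  profiles are the rows of the disease×lncRNA and disease×miRNA
  adjacency matrices (their kernels are averaged); lncRNA/miRNA
  profiles are the corresponding columns. Bandwidths are never
  recomputed after smoothing — similarities are a fixed preprocessing
  product of the training data.
* **Functional similarity.** Best-match average: each entity is its
  associated-disease set; a pair is scored by the mean over both sets
  of the best semantic match in the other set. Entities with no
  associated disease get similarity 0 with a warning. The miRNA case
  is defined as the exact symmetric analogue of the lncRNA case.
* All combined matrices are elementwise means, clipped to [0, 1] to
  absorb floating-point rounding.

### 3. WKNNP smoothing

For each entity along each axis, the K = 3 most similar *other*
entities that carry at least one known association are selected
(similarity descending, ties broken by index order; fewer if fewer are
eligible). The axis estimate is Σ w_t·slice_t / Q with
w_t = α^(t−1)·sim_t, α = 0.1, and Q = Σ sim_t. The normaliser
deliberately uses undecayed similarities, so the weights sum to Q only
when α → 1; this asymmetry is part of the procedure's definition and
is implemented as such rather than "corrected". The three axis
estimates are blended with weights (1, 1, 1) and fused into the tensor
by an elementwise maximum, which guarantees observed 1-entries survive
and all entries stay in [0, 1].

### 4. Nonnegative Tucker completion

T̂ = G ×₁ Z₁ ×₂ Z₂ ×₃ Z₃ with ranks (5, 5, 5) by default. Fitting
alternates multiplicative updates — modes 1→2→3, then the core:

* factor: Zₙ ← Zₙ ∗ (T₍ₙ₎Sₙᵀ)/(ZₙSₙSₙᵀ + 1e−12), with
  Sₙ = G₍ₙ₎·(⊗ other factors)ᵀ;
* core: G ← G ∗ (T ×ₙ Zₙᵀ ∀n)/(G ×ₙ ZₙᵀZₙ ∀n + 1e−12), the tensorised
  form of the vectorised NMF step with Q = Z₃⊗Z₂⊗Z₁. The core update
  is stated in the literature in a shorthand whose denominator is
  dimensionally ambiguous; the implementation uses the NMF-consistent
  gram form, verified in tests against the explicit Kronecker/vec
  expression on small instances.

Although the alternating scheme is organised like a higher-order
iteration, the updates are NMF-style and never orthogonalise the
factors; no orthogonalization is added.

**Unfolding convention.** `unfold(T, n)` flattens the remaining axes in
ascending order (C order), under which
unfold(G ×₁Z₁ ×₂Z₂ ×₃Z₃, 1) = Z₁·G₍₁₎·(Z₂⊗Z₃)ᵀ holds with the
Kronecker factors in ascending mode order.

**Initialisation.** Default is a nonnegative HOSVD-style init: absolute
values of the truncated left singular vectors of each unfolding, plus a
1e−2 offset, with the matching contracted core. This choice is
deliberate: zeros (and near-zeros) are absorbing under multiplicative
updates, and with uniform random init on data whose communities have
disjoint support the fit reliably collapses onto a single community —
on an ideal two-block tensor every random seed tried converged to
explaining exactly one block (relative residual 0.68), while the HOSVD
init reaches ~1e−13. The init also makes the default fit fully
deterministic. Uniform (0.1, 1.1) random init remains available as
`init="random"` with a seed.

**Stopping.** Default: relative squared residual
‖T − T̂‖²_F/‖T‖²_F < 1e−4 or 500 iterations. An absolute threshold
(`epsilon`) is available to match the "repeat until ‖T − T̂‖² < ε"
formulation literally; the literature leaves the ε convention
unstated, so both are exposed. The per-iteration squared residual is
recorded (`residual_trace_`); the fit aborts with the trace if the
residual ever increases beyond numerical tolerance, and non-finite
values raise immediately.

## Cross-validation protocol

* **Global/local LOOCV.** Each known triple is masked in turn and the
  *entire* pipeline is refitted on the masked tensor: WKNNP smoothing
  is always recomputed (a leakage test asserts the masked entry's
  smoothed value actually changes), and in strict mode (the default)
  the GIP kernels are recomputed from the masked tensor's unfoldings.
  Semantic and functional similarities stay frozen: masking one triple
  does not delete the underlying pairwise database edges, which exist
  independently of the triple. A fast mode freezes all similarities.
* **Candidate set.** The masked triple is ranked against all triples
  that are zero in its training tensor — globally, or restricted to the
  same disease for the local protocol. Because scores from different
  refits are not mutually calibrated, each held-out triple contributes
  its normalised rank (midrank on ties) among its own negatives; the
  pooled AUC is the mean normalised rank and the ROC curve its
  exceedance curve.
* **k-fold CV.** Known triples are partitioned (stratified per disease
  by default, so no fold empties a disease), each fold masked and
  scored against the common negative set within its own fit, and the
  partition repeated with fresh sub-seeds. The summary is the
  mean ± sd over repeat-level means.
* **Baseline.** `permuted_score_auc` scores the same positives with a
  seeded random tensor, giving the ≈0.5 no-signal reference without
  refitting.

## Synthetic data generator

The generator emulates the structural premise of the model — shared
community membership drives co-association — not any real database's
degree distribution. Entities of each kind are split into contiguous
latent blocks; bipartite edges are Bernoulli with probability 0.85
within a block and 0.05 across; each edge indicator is then flipped
independently with probability 0.05. Noise acts at the *edge* level so
the triangle-closure stage is genuinely exercised. Triangles of the
noiseless networks are the ground truth; triangles lost to noise form
the held-out "future" set for recovery experiments. A toy MeSH-style
descriptor file places same-block diseases under a shared ancestor so
semantic similarity correlates with block identity. Defaults
(12×10×15, 2 blocks, seed mandatory) yield ~200–300 training triples —
large enough for nondegenerate cross-validation, small enough that a
full LOOCV refit loop runs in seconds.

What passing tests on these fixtures does **not** show: performance on
real association data, whose similarity structure is far weaker and
whose degree distributions are heavy-tailed; the planted-block
signal is deliberately strong. Note also that Bernoulli sampling makes
the generated tensor only *approximately* low-rank: the mean block
structure is exactly rank-(#blocks), but sampling variation adds
full-rank mass (at the default densities roughly a third of the
squared Frobenius mass), which is the realistic regime for a completion
method rather than a defect.

## Numerical choices and degenerate inputs

* Denominator guard 1e−12 in both multiplicative updates.
* Similarities clipped to [0, 1]; GIP diagonal pinned to 1.
* All-zero profile matrices make the GIP bandwidth undefined and raise.
* Entities with no eligible WKNNP neighbour (or all-zero similarity
  row) keep a zero estimate, with a warning.
* Similarity ties in neighbour selection and score ties in rankings
  break by index order; ranking tables always have contiguous ranks.
* Ranks exceeding tensor dimensions trigger a warning, not an error
  (overcomplete fits are legitimate in tests).

## Problem sizes used in the shipped analyses

The acceptance script and test suite run the default 12×10×15 fixture
(LOOCV over ~250 triples with a 200-iteration cap per refit), repeated
2-fold (10 repeats) and 10-fold (5 repeats) CV, and planted-model
recovery on 12×10×15 rank-(2,2,2) tensors with up to 20 000 iterations;
these sizes keep every analysis in the seconds-to-a-minute range while
leaving all qualitative behaviour (signal recovery, chance-level nulls,
monotone residuals) observable.

## Known limitations

* Multiplicative updates converge slowly near stationary points;
  reaching relative residuals below ~1e−3 can take tens of thousands
  of iterations on small dense tensors.
* The miRNA functional-similarity formula and the core-update
  denominator are implemented in their internally consistent symmetric
  forms; the source formulations are ambiguous, so other readings are
  conceivable.
* K and α are global (one value for all three axes) and are not
  learned from data.
* No regularisation or weighting in the factorization; no GPU path.
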