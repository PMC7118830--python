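# Methods

## Problem and model

The package scores unobserved circRNA–disease pairs by completing a sparse
binary association matrix `A` (m circRNAs × n diseases) under the inductive
matrix completion (IMC) assumption: the rows of `A` lie in the span of
disease feature vectors and its columns in the span of circRNA feature
vectors, so `A ≈ C Z Dᵀ` for a small latent matrix `Z`. The estimator is

    min_Z  λ‖Z‖_* + ½ ‖R_Ω(C Z Dᵀ − A)‖_F² ,

where `Ω` is the set of known associations, `R_Ω` zeroes residuals outside
`Ω` (unknown pairs are unlabelled, not negative), and the nuclear norm
`‖Z‖_*` is the convex surrogate for rank. The modelling assumptions are
therefore: (i) association structure is low-rank, (ii) similar circRNAs
associate with similar diseases (encoded through the features), and (iii)
zeros in `A` are missing labels rather than true negatives.

## Similarity kernels

**Sequence (circRNA side).** Weighted Levenshtein distance with insertion
and deletion cost 1 and substitution cost 2, normalised as
`1 − dist/(len_a + len_b)` so values lie in [0, 1]. With this cost triple a
substitution is exactly as expensive as a delete-plus-insert, which ties the
distance to the longest common subsequence (`dist = len_a + len_b − 2·LCS`);
the test suite exploits that identity as an independent oracle while the
implementation itself is the classical dynamic program (rows vectorised,
with a running-minimum transform resolving the in-row insertion
dependency). Sequences are normalised to uppercase DNA (U→T) at read time so
the distance is alphabet-stable.

**Semantic (disease side).** The Wang measure on the disease ontology's
is_a DAG. The contribution of ancestor `t` to term `d` is the maximum over
directed paths of `w_e^(path length)`, computed by topological traversal of
the ancestor closure (children finalised before parents), with `w_e = 0.7`.
Similarity is the shared-ancestor contribution sum divided by the two total
contribution sums. Multi-parent terms propagate along every path and the
maximum wins; terms sharing no ancestor get similarity 0 (the degenerate
disconnected case, which a single-rooted ontology never produces).

**Interaction profiles (both sides).** Gaussian kernel on binary
row/column profiles with bandwidth `γ = 1 / mean(‖IP‖²)`, so the kernel
adapts to matrix density. Zero profiles are legal inputs (they arise inside
cross-validation); only an all-zero matrix is an error.

**Integration.** `CS = w·Sim_lev + (1−w)·Gkl_c` and
`DS = w·Sim_Wang + (1−w)·Gkl_d` with `w = 0.5` by default; `w` is exposed
because the relative informativeness of the two kernels is data-dependent.
Exact symmetry is enforced by computing one triangle and mirroring, with the
diagonal set to exactly 1.

## Feature extraction

Features are the leading left singular vectors of `CS` and `DS`, with rank
chosen by the dominating-energy rule: the smallest `f` such that the first
`f` singular values carry at least a fraction `α` of the spectrum's total.
Defaults `α_c = 0.6`, `α_d = 0.9`. Numerical choices:

* no mean-centering before the SVD — the unit diagonal of a similarity
  matrix is structural, and centering would destroy it;
* feature columns are unscaled orthonormal singular vectors (not scaled by
  `√σ`); this makes the data-fit gradient's Lipschitz constant exactly 1,
  so the automatic proximal parameter is 1;
* a deterministic sign convention (largest-magnitude entry of each column
  positive) makes results independent of the SVD backend;
* the energy comparison uses a 1e−12 slack so spectra that hit `α` exactly
  (e.g. equal singular values) are not tipped by cumulative-sum rounding;
* retained energy is stored on the feature object so the effective
  dimensionality of any run can be audited.

## Solver

Accelerated proximal gradient with singular value thresholding:
`Z_{k} = SVT(Y_k − ∇f(Y_k)/τ, λ/τ)` with Nesterov momentum
`t_{k+1} = (1 + √(1+4t_k²))/2` on the extrapolation point `Y`. Choices:

* `τ = ‖C‖₂²·‖D‖₂²`, the Lipschitz constant of `∇f` (exactly 1 for
  orthonormal features); a fixed positive `τ` can be supplied instead;
* monotone safeguard: if a step would increase the objective, momentum is
  restarted (`Y ← Z`, `t ← 1`) and the step retried, so the recorded
  objective trace is non-increasing by construction;
* initialisation `Z₀ = 0`, deterministic; `λ = 1` by default;
* stopping when `1 − obj_k/obj_{k−1} < 10⁻⁵` (relative objective gap),
  guarded for `obj = 0`, with a 500-iteration cap. On the bundled
  benchmarks the solver converges in ~20–30 iterations.

The SVT step is validated in two independent ways: against the closed-form
diagonal case, and against an L-BFGS minimiser of the smooth factored
surrogate `t/2(‖A‖_F²+‖B‖_F²) + ½‖AB − M‖_F²`, whose global minimum equals
the nuclear-norm proximal point.

## Evaluation protocol

Leave-one-out cross validation over known associations. For each fold
(i, j): the entry is zeroed in the training matrix; the GIP kernels,
integrated similarities, features and solver are all recomputed from the
training matrix (sequence and ontology similarities are label-independent
and cached across folds); the held-out pair is the fold's positive and
every circRNA never associated with disease j is a candidate negative. A
candidate appearing in several folds keeps its maximum score across folds
(`aggregate="max"`; the protocol sentence admits a within-run averaging
reading, so `aggregate="mean"` is available behind the flag). AUC uses the
trapezoidal rule with the half-credit tie convention; the PR sweep stops at
the threshold first achieving full recall.

**Known limitation — cold-entity ranking bias.** When an entity's only
association is held out, its training profile is all-zero. A zero profile
sits at squared distance `‖IP‖²` from every other profile, whereas a
profile committed to a *different* disease sits at squared distance
`‖IP‖² + ‖IP′‖²`; under the GIP kernel the cold positive is therefore
systematically more similar to the held-out disease's remaining partners
than a miscommitted negative is. On data dominated by degree-1 circRNAs
this inflates LOOCV AUC above 0.5 even for completely random association
placements (measured ≈ 0.67–0.81 on the bundled 40×10 null, where every
circRNA has degree exactly 1). The bias shrinks as entity degrees grow,
because held-out positives then retain other associations and look like
ordinary committed rows. Any LOOCV figure on sparse association data —
synthetic or real — should be read against this baseline, not against 0.5;
the signal-free null run in `scripts/acceptance.py` computes the relevant
baseline for the bundled conditions.

## Synthetic study conditions

The generator produces all three pipeline inputs from one seed
(per-component sub-seeds are derived deterministically, so each artifact is
individually reproducible):

* **Associations.** CircRNAs and diseases are assigned uniform cluster
  memberships among `rank` clusters; a `rank×rank` Gaussian core `B` sets
  cluster-pair affinity; the signal matrix is `signal · B[g_i, h_j]` plus
  unit Gaussian noise; the top `⌈density·m·n⌉` entries become known
  associations. A repair pass guarantees every row and column keeps at
  least one association, then excess entries are trimmed lowest-signal
  first (never re-emptying a row/column), so the realised count stays at
  the target. Defaults: 40×10, rank 2, density 0.1, signal 3 — a desk-scale
  caricature of curated collections, which are larger (up to 512×71) but
  sparser (densities 0.017–0.032).
* **Sequences.** Uniform A/C/G/T strings with lengths in (50, 100) —
  desk-scale rather than realistic circRNA lengths, chosen to keep the
  quadratic edit-distance cost trivial. In coupled mode each circRNA
  cluster shares a template and members are mutated copies at per-base rate
  0.15, giving within-cluster identity ≈ 0.85 against a random-pair
  background ≈ 0.65 — enough contrast for the sequence kernel to carry
  cluster signal without making clusters trivially separable.
* **Ontology.** A rooted random DAG of 30 terms; each non-root term takes
  1–2 parents among earlier terms (acyclic by construction). Disease ids
  are a seeded sample of non-root terms. The topology is *not* coupled to
  the planted clusters, so the semantic kernel contributes realistic
  nuisance variation rather than signal.

What passing tests on these fixtures do and do not show: they demonstrate
that the pipeline recovers planted low-rank, kernel-aligned structure and
that every computational contract holds; they do not demonstrate
performance on real curated collections, whose similarity structure,
degree distributions, ontology topology and annotation biases differ
(real runs consume user-supplied files through the same interfaces).

## Degenerate inputs and tie-breaking

Empty sequences are rejected where a length-normalised similarity would be
undefined; an all-zero association matrix has no defined GIP bandwidth and
is rejected; single-class label vectors are rejected by ROC/PR; ranking
ties are broken lexicographically by (circ_id, disease_id) so all outputs
are byte-reproducible; similarity-matrix symmetry violations and
out-of-range entries are rejected at construction rather than silently
clipped (only sub-1e-12 float noise is clipped).

## Parameter summary

| parameter | default | meaning |
|---|---|---|
| `w_e` | 0.7 | per-edge semantic decay in the Wang measure |
| edit costs | 1, 1, 2 | insertion, deletion, substitution weights |
| `weight` | 0.5 | sequence/semantic share of the integrated kernels |
| `alpha_circ` | 0.6 | circRNA spectral-energy threshold |
| `alpha_disease` | 0.9 | disease spectral-energy threshold |
| `lambda` | 1 | nuclear-norm regularisation weight |
| `tau` | auto | proximal parameter (Lipschitz constant of the gradient) |
| `tolerance` | 1e−5 | relative objective-gap stopping rule |
| `max_iterations` | 500 | solver iteration cap |
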