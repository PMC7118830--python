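# circimc

Prediction of circRNA–disease associations by nuclear-norm-regularized
inductive matrix completion over integrated similarity kernels.

Circular RNAs (circRNAs) are covalently closed noncoding RNAs increasingly
implicated in human disease, but experimentally validated circRNA–disease
associations are scarce: curated collections sit at matrix densities of only
1.7–3.2%. `circimc` treats candidate prioritisation as a recommendation
problem — complete the sparse binary association matrix using side
information about how similar circRNAs and diseases are to each other — and
is aimed at computational biologists who want ranked disease–circRNA
candidates from three standard inputs: an association table, circRNA
sequences (FASTA), and a disease ontology (OBO).

## Model

Let `A ∈ {0,1}^{m×n}` be the known association matrix over `m` circRNAs and
`n` diseases, with `Ω` the set of observed (known-association) entries.

**Similarity kernels.** Three pairwise similarities feed the model:

* sequence similarity `Sim_lev(i,j) = 1 − dist(i,j) / (len_i + len_j)`,
  where `dist` is a weighted Levenshtein distance (insertion 1, deletion 1,
  substitution 2);
* Wang semantic similarity on the disease ontology DAG, where each ancestor
  `t` of a term `d` contributes `S_d(t) = max{w_e · S_d(t′) : t′ ∈
  children(t)}` with `S_d(d) = 1` and edge factor `w_e = 0.7`, and
  `Sim_Wang(d_i,d_j)` is the shared-ancestor contribution fraction;
* Gaussian interaction profile (GIP) kernels
  `Gkl(i,j) = exp(−γ‖IP_i − IP_j‖²)` on the rows and columns of `A`, with
  bandwidth `γ` the reciprocal mean squared profile norm.

The integrated similarities are the means `CS = (Sim_lev + Gkl_c)/2` and
`DS = (Sim_Wang + Gkl_d)/2` (the weight is adjustable).

**Features.** Orthonormal feature matrices `C` (m×f_c) and `D` (n×f_d) are
the leading left singular vectors of `CS` and `DS`, with ranks chosen by the
dominating-energy rule: the smallest `f` whose cumulative singular-value
fraction reaches a threshold `α` (defaults `α_c = 0.6`, `α_d = 0.9`).

**Completion.** The latent matrix `Z` solves

    min_Z  λ‖Z‖_* + ½‖R_Ω(C Z Dᵀ − A)‖_F²,      λ = 1 by default,

via accelerated proximal gradient descent whose proximal step is singular
value thresholding (SVT), with a monotone restart safeguard and the stopping
rule `1 − obj_k/obj_{k−1} < 10⁻⁵`. The dense matrix `C Z Dᵀ` scores every
pair; evaluation is leave-one-out cross validation (LOOCV) in which each
known association is held out, all label-dependent quantities (GIP kernels,
integrated similarities, features, solver) are recomputed from the training
matrix, and the held-out pair is ranked against the same disease's
never-associated circRNAs.

## Worked example

The bundled generator creates a complete synthetic benchmark (40 circRNAs ×
10 diseases, planted rank-2 block structure at density 0.1, cluster-coupled
sequences, signal three times the noise scale):

```python
from circimc import CircDiseaseIMC
from circimc.synthetic import SyntheticSpec, generate_all

data = generate_all(SyntheticSpec(coupled=True, seed=7))
model = CircDiseaseIMC(data.dataset, data.sequences, data.ontology)
results = model.fit()
print(results.summary())
```

```
Inductive Matrix Completion Results
========================================================
circRNAs                                              40
diseases                                              10
known associations                                    40
matrix density                                    0.1000
circ features (alpha)                            2 (0.6)
disease features (alpha)                         8 (0.9)
circ retained energy                              0.6163
disease retained energy                           0.9282
nuclear-norm weight                                    1
iterations                                            22
converged                                           True
final objective                                13.170045
========================================================
```

The solver keeps 2 circRNA and 8 disease singular vectors (61.6% and 92.8%
of spectral energy), converges in 22 iterations under the 10⁻⁵ relative-gap
rule, and scores all 400 pairs. Ranking and cross-validation:

```python
print(results.top_k(5).to_string(index=False))
cv = model.loocv()
print(f"LOOCV AUC over {cv.n_folds} folds: {cv.auc:.4f}")
```

```
 rank   circ_id    disease_id    score  known
    1 circ_0014 SYNDO:0000012 0.722706   True
    2 circ_0035 SYNDO:0000012 0.716994  False
    3 circ_0018 SYNDO:0000012 0.715473  False
    4 circ_0033 SYNDO:0000012 0.708220   True
    5 circ_0028 SYNDO:0000012 0.706625  False
```

```
LOOCV AUC over 40 folds: 0.8235
```

High-scoring unknown pairs (e.g. rank 2 and 3) are the model's candidate
associations; the LOOCV AUC of 0.82 says held-out known associations are
ranked above never-associated candidates far more often than chance.

The same pipeline is scriptable from a shell:

```sh
circimc simulate --out fixture --seed 7 --coupled
circimc train  --associations fixture/associations.tsv \
               --fasta fixture/circ.fasta --obo fixture/disease.obo --out run
circimc loocv  --associations fixture/associations.tsv \
               --fasta fixture/circ.fasta --obo fixture/disease.obo --out cv
circimc topk   --scores run/scores.tsv --k 30 --out ranks
```

Real-data runs consume user-supplied files in the same three formats
(`circ_id`/`disease_id` TSV, FASTA with circBase-style ids, OBO 1.2 with
DOID terms); no external database is bundled or downloaded.

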