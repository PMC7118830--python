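"""Seeded synthetic fixtures: sequences, ontology DAGs and planted associations.

The generator emulates the three inputs of the pipeline at desk scale so that
every stage is exercisable without any download:

* random A/C/G/T sequences (optionally "coupled": circRNAs in the same
  planted cluster are mutated copies of a shared template, so sequence
  similarity carries association signal),
* a rooted random DAG ontology in OBO-compatible form (each non-root term has
  one or two parents among earlier terms, hence acyclic by construction),
* a binary association matrix planted with low-rank block structure: circRNAs
  and diseases are assigned latent clusters, a rank x rank Gaussian core sets
  the affinity between cluster pairs, unit Gaussian noise is added, and the
  top ``density * m * n`` entries of the resulting signal become the known
  associations (with a repair pass so no entity ends up associationless).

A single global seed drives everything; per-component sub-seeds are derived
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import AssociationDataset, SequenceRecord
from .similarity import OntologyGraph

__all__ = [
    "SyntheticSpec",
    "SyntheticData",
    "generate_sequences",
    "generate_ontology",
    "generate_associations",
    "generate_all",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults describe a 40 circRNA x 10 disease benchmark with a planted
    rank-2 block structure at density 0.1 and a signal-to-noise ratio of 3,
    mirroring the sparse, low-rank regime of real association matrices
    (which sit at densities of a few percent).
    """

    n_circ: int = 40
    n_disease: int = 10
    seq_length_range: tuple[int, int] = (50, 100)
    ontology_size: int = 30
    rank: int = 2
    density: float = 0.1
    signal: float = 3.0
    coupled: bool = False
    mutation_rate: float = 0.15
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.seq_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid sequence length range")
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.rank > min(self.n_circ, self.n_disease):
            raise ValueError("rank exceeds matrix dimensions")
        if self.density * self.n_circ * self.n_disease < max(
            self.n_circ, self.n_disease
        ):
            raise ValueError(
                "infeasible density: fewer planted associations than entities"
            )
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticData:
    """A complete consistent fixture: all three inputs plus ground truth."""

    dataset: AssociationDataset
    sequences: list[SequenceRecord]
    ontology: OntologyGraph
    truth: np.ndarray  # noiseless planted signal, m x n
    circ_clusters: np.ndarray
    disease_clusters: np.ndarray


def _component_rng(spec: SyntheticSpec, offset: int) -> np.random.Generator:
    # deterministic per-component sub-seed derived from the global seed
    return np.random.default_rng(np.random.SeedSequence([spec.seed, offset]))


def _circ_ids(n: int) -> list[str]:
    return [f"circ_{i:04d}" for i in range(n)]


def _term_ids(n: int) -> list[str]:
    return [f"SYNDO:{i:07d}" for i in range(n)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, template: str, rate: float) -> str:
    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    arr[hit] = _ALPHABET[rng.integers(0, 4, size=int(hit.sum()))]
    return arr.tobytes().decode()


def generate_sequences(
    spec: SyntheticSpec, clusters: np.ndarray | None = None
) -> list[SequenceRecord]:
    """Random nucleotide sequences, uniform over A/C/G/T.

    In coupled mode (``spec.coupled`` with a cluster assignment) each cluster
    shares a template of the maximum length and members are independently
    mutated copies, so within-cluster sequence identity is about
    ``1 - mutation_rate`` while across-cluster pairs are unrelated.
    """
    rng = _component_rng(spec, 1)
    lo, hi = spec.seq_length_range
    ids = _circ_ids(spec.n_circ)
    if spec.coupled and clusters is not None:
        templates = {
            int(g): _random_seq(rng, hi) for g in np.unique(clusters)
        }
        return [
            SequenceRecord(cid, _mutate(rng, templates[int(g)], spec.mutation_rate))
            for cid, g in zip(ids, clusters)
        ]
    lengths = rng.integers(lo, hi + 1, size=spec.n_circ)
    return [SequenceRecord(cid, _random_seq(rng, int(L))) for cid, L in zip(ids, lengths)]


def generate_ontology(spec: SyntheticSpec) -> OntologyGraph:
    """Rooted random DAG: term t > 0 gets 1-2 parents among terms < t."""
    if spec.ontology_size < 1:
        raise ValueError("ontology_size must be >= 1")
    rng = _component_rng(spec, 2)
    terms = _term_ids(spec.ontology_size)
    parents: dict[str, set[str]] = {terms[0]: set()}
    for t in range(1, spec.ontology_size):
        k = int(rng.integers(1, min(2, t) + 1))
        chosen = rng.choice(t, size=k, replace=False)
        parents[terms[t]] = {terms[int(c)] for c in chosen}
    return OntologyGraph(parents)


def _plant(spec: SyntheticSpec):
    rng = _component_rng(spec, 3)
    m, n, r = spec.n_circ, spec.n_disease, spec.rank
    g = rng.integers(0, r, size=m)  # circRNA cluster memberships
    h = rng.integers(0, r, size=n)  # disease cluster memberships
    B = rng.normal(size=(r, r))  # cluster-pair affinity core
    signal = spec.signal * B[np.ix_(g, h)]
    M = signal + rng.normal(size=(m, n))
    q = int(np.ceil(spec.density * m * n))
    A = np.zeros((m, n), dtype=np.int8)
    top = np.argsort(M, axis=None)[::-1][:q]
    A.flat[top] = 1
    # repair: every circRNA and disease keeps at least one association
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        A[i, int(np.argmax(M[i]))] = 1
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        A[int(np.argmax(M[:, j])), j] = 1
    # trim back towards the target count, lowest-signal entries first, never
    # re-emptying a row or column
    if A.sum() > q:
        order = sorted(zip(*np.nonzero(A)), key=lambda ij: M[ij])
        for i, j in order:
            if A.sum() <= q:
                break
            if A[i].sum() > 1 and A[:, j].sum() > 1:
                A[i, j] = 0
    return A, signal, g, h


def generate_associations(
    spec: SyntheticSpec,
) -> tuple[AssociationDataset, np.ndarray]:
    """Planted low-rank association matrix and its continuous ground truth.

    The known-association count is ``ceil(density * m * n)`` plus any repair
    additions needed to keep every row and column nonempty.
    """
    A, signal, _, _ = _plant(spec)
    dataset = AssociationDataset(
        _circ_ids(spec.n_circ), _term_ids_subset(spec), A
    )
    return dataset, signal


def _term_ids_subset(spec: SyntheticSpec) -> list[str]:
    """Disease ids: a deterministic sample of ontology term ids.

    The root term is excluded so diseases sit inside the DAG rather than at
    its apex.  Requires ``ontology_size > n_disease``.
    """
    if spec.ontology_size <= spec.n_disease:
        raise ValueError("ontology_size must exceed n_disease")
    rng = _component_rng(spec, 4)
    terms = _term_ids(spec.ontology_size)
    chosen = rng.choice(
        np.arange(1, spec.ontology_size), size=spec.n_disease, replace=False
    )
    return [terms[int(c)] for c in sorted(chosen)]


def generate_all(spec: SyntheticSpec) -> SyntheticData:
    """All three inputs, mutually consistent, plus the planted ground truth."""
    ontology = generate_ontology(spec)
    A, signal, g, h = _plant(spec)
    dataset = AssociationDataset(_circ_ids(spec.n_circ), _term_ids_subset(spec), A)
    sequences = generate_sequences(spec, clusters=g)
    return SyntheticData(
        dataset=dataset,
        sequences=sequences,
        ontology=ontology,
        truth=signal,
        circ_clusters=g,
        disease_clusters=h,
    )
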