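"""Similarity kernels: weighted Levenshtein, Wang ontology-semantic, and GIP.

Three pairwise similarity notions feed the matrix-completion model:

* sequence similarity between circRNAs, from a weighted Levenshtein edit
  distance normalised by the summed sequence lengths,
* semantic similarity between diseases, from the Wang measure on the disease
  ontology DAG (each ancestor's contribution decays by a factor ``w_e`` per
  is_a edge, maximised over paths),
* Gaussian interaction profile (GIP) kernel similarity for both circRNAs and
  diseases, computed from the rows/columns of the association matrix itself.

The integrated circRNA similarity CS averages the sequence and GIP kernels;
the integrated disease similarity DS averages the semantic and GIP kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import AssociationDataset, SequenceRecord

__all__ = [
    "EditCosts",
    "OntologyGraph",
    "SimilarityMatrix",
    "edit_distance",
    "sequence_similarity",
    "sequence_similarity_matrix",
    "wang_contributions",
    "wang_similarity",
    "wang_similarity_matrix",
    "gip_bandwidth",
    "gip_similarity_matrix",
    "integrate_similarity",
]


@dataclass(frozen=True)
class EditCosts:
    """Weights of the three single-character edit operations.

    The defaults (insertion 1, deletion 1, substitution 2) make a substitution
    exactly as expensive as a delete-plus-insert, which ties the distance to
    the longest common subsequence: dist = len_a + len_b - 2*LCS.
    """

    insertion: float = 1.0
    deletion: float = 1.0
    substitution: float = 2.0

    def __post_init__(self) -> None:
        if min(self.insertion, self.deletion, self.substitution) < 0:
            raise ValueError("edit costs must be non-negative")


class OntologyGraph:
    """A rooted is_a DAG of ontology terms.

    Parameters
    ----------
    parents : mapping from each term to the set of its direct is_a parents
        (roots map to an empty set).
    w_e : semantic contribution factor per edge, in (0, 1].
    """

    def __init__(self, parents: Mapping[str, Iterable[str]], w_e: float = 0.7):
        if not 0 < w_e <= 1:
            raise ValueError(f"w_e must be in (0, 1], got {w_e}")
        self.w_e = float(w_e)
        self.parents: dict[str, frozenset[str]] = {}
        for term, ps in parents.items():
            ps = frozenset(str(p) for p in ps)
            self.parents[str(term)] = ps
        # parents referenced but not declared become roots
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, frozenset())
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        try:
            list(TopologicalSorter(self.parents).static_order())
        except Exception as exc:  # CycleError carries the offending cycle
            raise ValueError(f"ontology is not a DAG: {exc}") from exc

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` along is_a edges, including itself."""
        if term not in self.parents:
            raise KeyError(f"term {term!r} not in ontology")
        seen = {term}
        stack = [term]
        while stack:
            for p in self.parents[stack.pop()]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}


@dataclass
class SimilarityMatrix:
    """Labeled square symmetric similarity matrix with unit diagonal."""

    ids: tuple[str, ...]
    S: np.ndarray

    def __init__(self, ids: Sequence[str], S: np.ndarray):
        self.ids = tuple(str(x) for x in ids)
        S = np.asarray(S, dtype=float)
        n = len(self.ids)
        if S.shape != (n, n):
            raise ValueError(f"similarity matrix shape {S.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in similarity matrix")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.S = np.clip(S, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=list(self.ids), columns=list(self.ids))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.S[i, j])


def _mirror_unit_diag(S: np.ndarray) -> np.ndarray:
    """Enforce exact symmetry (upper triangle wins) and a unit diagonal."""
    out = np.triu(S, 1)
    out = out + out.T
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------

def edit_distance(seq_a: str, seq_b: str, costs: EditCosts | None = None) -> float:
    """Minimum total cost of editing ``seq_a`` into ``seq_b``.

    Classic dynamic program over insertions, deletions and substitutions with
    per-operation weights.  Rows are vectorised; the in-row insertion
    dependency is resolved with a running-minimum transform, so the cost is
    O(len_a * len_b) with numpy-scale constants.
    """
    costs = costs or EditCosts()
    if not seq_a:
        return len(seq_b) * costs.insertion
    if not seq_b:
        return len(seq_a) * costs.deletion
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    nb = len(b)
    ins_steps = np.arange(nb + 1) * costs.insertion
    prev = ins_steps.copy()  # d[0][j] = j * insertion
    row = np.empty(nb + 1)
    for ca in seq_a.encode():
        sub = prev[:-1] + np.where(b == ca, 0.0, costs.substitution)
        row[0] = prev[0] + costs.deletion
        row[1:] = np.minimum(prev[1:] + costs.deletion, sub)
        # row[j] = min(row[j], min_{k<j} row[k] + (j-k)*insertion)
        shifted = np.minimum.accumulate(row - ins_steps)
        row = shifted + ins_steps
        prev, row = row, prev
    return float(prev[-1])


def sequence_similarity(
    seq_a: str, seq_b: str, costs: EditCosts | None = None
) -> float:
    """Length-normalised edit similarity: ``1 - dist / (len_a + len_b)``."""
    if not seq_a or not seq_b:
        raise ValueError("sequence similarity undefined for empty sequences")
    dist = edit_distance(seq_a, seq_b, costs)
    return 1.0 - dist / (len(seq_a) + len(seq_b))


def sequence_similarity_matrix(
    records: Sequence[SequenceRecord], costs: EditCosts | None = None
) -> SimilarityMatrix:
    """Pairwise normalised edit similarity over a sequence collection.

    Only the upper triangle is computed and mirrored; the diagonal is exactly 1.
    """
    if not records:
        raise ValueError("need at least one sequence record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(records)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = sequence_similarity(
                records[i].sequence, records[j].sequence, costs
            )
    return SimilarityMatrix(ids, _mirror_unit_diag(S))


# ---------------------------------------------------------------------------
# ontology semantic similarity (Wang measure)
# ---------------------------------------------------------------------------

def wang_contributions(ontology: OntologyGraph, term: str) -> dict[str, float]:
    """Semantic contribution of every ancestor of ``term`` to ``term``.

    The query term contributes 1 to itself; each ancestor ``t`` contributes
    the maximum over is_a paths of ``w_e`` raised to the path length, realised
    as ``max(w_e * S(child))`` over children of ``t`` lying on a path to the
    query.  Ancestors are processed in topological order (children first) so
    each score is final before it propagates.
    """
    if term not in ontology:
        raise KeyError(f"term {term!r} not in ontology")
    anc = ontology.ancestors(term)
    # predecessors of a parent are its children within the ancestor closure,
    # so static_order() finalises every child before its parents
    children: dict[str, set[str]] = {t: set() for t in anc}
    for t in anc:
        for p in ontology.parents[t] & anc:
            children[p].add(t)
    scores: dict[str, float] = {term: 1.0}
    for t in TopologicalSorter(children).static_order():
        if t == term:
            continue
        scores[t] = max(ontology.w_e * scores[c] for c in children[t])
    return scores


def wang_similarity(ontology: OntologyGraph, d_i: str, d_j: str) -> float:
    """Wang semantic similarity between two ontology terms.

    The shared ancestors' contributions to both terms, as a fraction of the
    total semantic contribution of each term's full ancestor set.  Terms with
    no common ancestor (disconnected components) get similarity 0.
    """
    s_i = wang_contributions(ontology, d_i)
    s_j = wang_contributions(ontology, d_j)
    shared = set(s_i) & set(s_j)
    if not shared:
        return 0.0
    num = sum(s_i[t] + s_j[t] for t in shared)
    den = sum(s_i.values()) + sum(s_j.values())
    return num / den


def wang_similarity_matrix(
    ontology: OntologyGraph, terms: Sequence[str]
) -> SimilarityMatrix:
    """Pairwise Wang similarity for an ordered list of ontology terms."""
    if not terms:
        raise ValueError("need at least one term")
    contribs = [wang_contributions(ontology, t) for t in terms]
    totals = [sum(c.values()) for c in contribs]
    n = len(terms)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(contribs[i]) & set(contribs[j])
            if shared:
                num = sum(contribs[i][t] + contribs[j][t] for t in shared)
                S[i, j] = num / (totals[i] + totals[j])
    return SimilarityMatrix(terms, _mirror_unit_diag(S))


# ---------------------------------------------------------------------------
# Gaussian interaction profile kernel
# ---------------------------------------------------------------------------

def _profiles(dataset: AssociationDataset, axis: str) -> np.ndarray:
    if axis in ("rows", "circ"):
        return dataset.A.astype(float)
    if axis in ("columns", "disease"):
        return dataset.A.T.astype(float)
    raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")


def gip_bandwidth(dataset: AssociationDataset, axis: str = "rows") -> float:
    """Kernel bandwidth: reciprocal of the mean squared profile norm.

    For binary profiles the squared norm of a profile is its number of ones,
    so the bandwidth adapts to the overall density of the association matrix.
    """
    P = _profiles(dataset, axis)
    mean_sq = float((P * P).sum(axis=1).mean())
    if mean_sq == 0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    return 1.0 / mean_sq


def gip_similarity_matrix(
    dataset: AssociationDataset, axis: str = "rows"
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel: exp(-gamma * ||IP_i - IP_j||^2)."""
    P = _profiles(dataset, axis)
    gamma = gip_bandwidth(dataset, axis)
    sq = (P * P).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    S = np.exp(-gamma * d2)
    ids = dataset.circ_ids if axis in ("rows", "circ") else dataset.disease_ids
    return SimilarityMatrix(ids, _mirror_unit_diag(S))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_similarity(
    sim_a: SimilarityMatrix, sim_b: SimilarityMatrix, weight: float = 0.5
) -> SimilarityMatrix:
    """Convex combination ``weight * sim_a + (1 - weight) * sim_b``.

    The default weight 0.5 is the plain arithmetic mean used to build the
    integrated circRNA similarity CS (sequence + GIP) and disease similarity
    DS (semantic + GIP).
    """
    if not 0 <= weight <= 1:
        raise ValueError(f"weight must be in [0, 1], got {weight}")
    if sim_a.ids != sim_b.ids:
        raise ValueError("similarity matrices carry different ids")
    S = weight * sim_a.S + (1.0 - weight) * sim_b.S
    return SimilarityMatrix(sim_a.ids, _mirror_unit_diag(S))
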