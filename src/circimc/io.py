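"""Readers, writers and dataset assembly.

Association tables are TSV/CSV files with header columns ``circ_id`` and
``disease_id``; sequences are FASTA (circBase-style ids); the disease
ontology is OBO 1.2 with ``is_a`` edges (obsolete terms skipped).  All
user-facing I/O speaks ids; indices are internal and 0-based.
"""

from __future__ import annotations

import csv
import io as _stdio
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO

from .data import AssociationDataset, SequenceRecord
from .similarity import OntologyGraph, SimilarityMatrix

__all__ = [
    "read_associations",
    "write_associations",
    "read_fasta",
    "write_fasta",
    "read_obo",
    "write_obo",
    "filter_complete",
    "merge_datasets",
    "matrix_density",
    "sparsify",
    "read_similarity",
    "write_similarity",
    "write_scores",
]

_VALID_RESIDUES = frozenset("ACGT")


def _sniff_delimiter(header: str, fmt: str | None) -> str:
    if fmt in ("\t", ","):
        return fmt
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    if fmt is None:
        return "\t" if "\t" in header else ","
    raise ValueError(f"unknown association table format {fmt!r}")


def read_associations(path: str | Path, fmt: str | None = None) -> AssociationDataset:
    """Read a circRNA-disease association table.

    The file must have header columns ``circ_id`` and ``disease_id``
    (additional columns are ignored).  Pairs are deduplicated and rows/columns
    are ordered lexicographically by id so the matrix is reproducible.

    Parameters
    ----------
    fmt : ``"tsv"``, ``"csv"``, a literal delimiter, or None to sniff from
        the header line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty association file")
    delim = _sniff_delimiter(text.splitlines()[0], fmt)
    reader = csv.DictReader(_stdio.StringIO(text), delimiter=delim)
    if reader.fieldnames is None or not {"circ_id", "disease_id"} <= set(
        reader.fieldnames
    ):
        raise ValueError(
            f"{path}: header must contain 'circ_id' and 'disease_id' columns"
        )
    pairs = []
    for row in reader:
        c = (row.get("circ_id") or "").strip()
        d = (row.get("disease_id") or "").strip()
        if not c or not d:
            raise ValueError(f"{path}: malformed row at line {reader.line_num}")
        pairs.append((c, d))
    if not pairs:
        raise ValueError(f"{path}: no association pairs")
    return AssociationDataset.from_pairs(pairs)


def write_associations(dataset: AssociationDataset, path: str | Path) -> None:
    """Write the known pairs as a TSV with ``circ_id`` / ``disease_id`` columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["circ_id", "disease_id"])
        for c, d in dataset.pairs():
            w.writerow([c, d])


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read sequences, uppercasing and mapping RNA U to DNA T.

    Residues outside {A, C, G, T} after normalisation are rejected with the
    offending record named.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-IUPAC-DNA residues {sorted(bad)}"
            )
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[k : k + 70] + "\n")


def read_obo(path: str | Path, w_e: float = 0.7) -> OntologyGraph:
    """Read an OBO ontology into an is_a DAG.

    Obsolete terms are skipped (obonet default); a cycle among is_a edges is
    an error naming one offending cycle.
    """
    import networkx as nx

    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    isa = nx.DiGraph()
    isa.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
            isa.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise ValueError(f"{path}: is_a cycle detected: {cycle}")
    return OntologyGraph(parents, w_e=w_e)


def write_obo(ontology: OntologyGraph, path: str | Path, name: str = "synthetic disease ontology") -> None:
    """Serialise an ontology as minimal OBO 1.2 stanzas."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {name}\n\n")
        for term in sorted(ontology.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            for p in sorted(ontology.parents[term]):
                fh.write(f"is_a: {p}\n")
            fh.write("\n")


def filter_complete(
    dataset: AssociationDataset,
    sequences: Sequence[SequenceRecord],
    ontology: OntologyGraph,
) -> AssociationDataset:
    """Drop associations lacking a circRNA sequence or a disease ontology term.

    Rows and columns left without any association disappear with their
    entities (the rebuilt matrix only contains entities that still carry at
    least one association).
    """
    with_seq = {r.id for r in sequences}
    kept = [
        (c, d)
        for c, d in dataset.pairs()
        if c in with_seq and d in ontology
    ]
    if not kept:
        raise ValueError("filtering removed every association")
    return AssociationDataset.from_pairs(kept)


def merge_datasets(datasets: Sequence[AssociationDataset]) -> AssociationDataset:
    """Union of entity sets and association pairs, exact string id match."""
    if not datasets:
        raise ValueError("need at least one dataset to merge")
    pairs: set[tuple[str, str]] = set()
    for ds in datasets:
        pairs |= set(ds.pairs())
    return AssociationDataset.from_pairs(pairs)


def matrix_density(dataset: AssociationDataset) -> float:
    """Fraction of known entries: ``|omega| / (m * n)``."""
    return dataset.density


def sparsify(
    dataset: AssociationDataset, target_density: float, seed: int
) -> AssociationDataset:
    """Remove uniformly random known associations until density <= target.

    Used to probe how performance degrades as the supervision matrix thins
    out.  Never removes the final association.
    """
    if target_density <= 0:
        raise ValueError("target_density must be positive")
    if target_density > dataset.density + 1e-12:
        raise ValueError(
            f"target density {target_density} exceeds current {dataset.density:.4f}"
        )
    m, n = dataset.shape
    A = dataset.A.copy()
    rng = np.random.default_rng(seed)
    ones = np.flatnonzero(A)
    rng.shuffle(ones)
    k = 0
    while A.sum() / (m * n) > target_density and A.sum() > 1:
        A.flat[ones[k]] = 0
        k += 1
    return AssociationDataset(dataset.circ_ids, dataset.disease_ids, A)


# ---------------------------------------------------------------------------
# similarity / score tables
# ---------------------------------------------------------------------------

def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    sim.to_frame().to_csv(path, sep="\t", index_label="id")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_scores(score_table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format score table sorted by descending score."""
    cols = ["circ_id", "disease_id", "score", "known"]
    out = score_table[cols].sort_values(
        ["score", "circ_id", "disease_id"], ascending=[False, True, True]
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
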