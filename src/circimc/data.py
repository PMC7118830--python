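"""Core containers: sequence records and the binary association matrix.

The association matrix ``A`` (m circRNAs x n diseases) is the supervision
signal of the whole pipeline: ``A[i, j] = 1`` means circRNA ``i`` is a known
partner of disease ``j``, ``0`` means the association is unobserved.  The set
of observed entries (``omega``) is what the matrix-completion data-fit term is
restricted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SequenceRecord", "AssociationDataset"]


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with its identifier.

    Sequences are stored uppercase over the DNA alphabet {A, C, G, T}; RNA
    input is normalised (U -> T) at read time so edit distances are well
    defined regardless of the source alphabet.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence for {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


class AssociationDataset:
    """Labeled binary circRNA-disease association matrix.

    Parameters
    ----------
    circ_ids : ordered circRNA labels (rows)
    disease_ids : ordered disease labels (columns)
    A : binary matrix of shape ``(len(circ_ids), len(disease_ids))``

    Row and column order is whatever the caller supplies; the constructors
    :meth:`from_pairs` and the readers in :mod:`circimc.io` sort ids
    lexicographically so matrices are reproducible across runs.
    """

    def __init__(
        self,
        circ_ids: Sequence[str],
        disease_ids: Sequence[str],
        A: np.ndarray,
    ) -> None:
        self.circ_ids = tuple(str(c) for c in circ_ids)
        self.disease_ids = tuple(str(d) for d in disease_ids)
        A = np.asarray(A)
        if A.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise ValueError(
                f"matrix shape {A.shape} does not match "
                f"{len(self.circ_ids)} circRNAs x {len(self.disease_ids)} diseases"
            )
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValueError("duplicate circRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.A = A.astype(np.int8)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationDataset":
        """Build a dataset from (circ_id, disease_id) pairs.

        Pairs are deduplicated; row/column order is the sorted order of ids.
        """
        unique = sorted({(str(c), str(d)) for c, d in pairs})
        if not unique:
            raise ValueError("no association pairs supplied")
        circ_ids = sorted({c for c, _ in unique})
        disease_ids = sorted({d for _, d in unique})
        ci = {c: i for i, c in enumerate(circ_ids)}
        di = {d: j for j, d in enumerate(disease_ids)}
        A = np.zeros((len(circ_ids), len(disease_ids)), dtype=np.int8)
        for c, d in unique:
            A[ci[c], di[d]] = 1
        return cls(circ_ids, disease_ids, A)

    # -- basic views ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    @property
    def n_circ(self) -> int:
        return self.A.shape[0]

    @property
    def n_disease(self) -> int:
        return self.A.shape[1]

    @property
    def omega(self) -> set[tuple[int, int]]:
        """Set of observed (row, col) index pairs where ``A == 1``."""
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.A))}

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    @property
    def density(self) -> float:
        """Fraction of observed entries, ``|omega| / (m * n)``."""
        m, n = self.A.shape
        return self.n_associations / (m * n)

    def pairs(self) -> list[tuple[str, str]]:
        """Known associations as (circ_id, disease_id) pairs, row-major order."""
        return [
            (self.circ_ids[i], self.disease_ids[j])
            for i, j in zip(*np.nonzero(self.A))
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.A, index=list(self.circ_ids), columns=list(self.disease_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationDataset):
            return NotImplemented
        return (
            self.circ_ids == other.circ_ids
            and self.disease_ids == other.disease_ids
            and np.array_equal(self.A, other.A)
        )

    def __repr__(self) -> str:
        m, n = self.shape
        return (
            f"AssociationDataset({m} circRNAs x {n} diseases, "
            f"{self.n_associations} associations, density {self.density:.3f})"
        )
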