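"""Feature extraction from similarity matrices by SVD energy thresholding.

The integrated similarity matrices are redundant: nearby entities carry
near-identical rows.  The dominating-energy rule keeps the smallest number of
leading singular vectors whose cumulative singular-value fraction reaches a
threshold ``alpha``, and those orthonormal left singular vectors become the
entity feature matrix handed to the matrix-completion solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["FeatureMatrix", "energy_rank", "extract_features"]

# slack against cumulative-sum rounding when a spectrum hits alpha exactly
_ENERGY_EPS = 1e-12


@dataclass(frozen=True)
class FeatureMatrix:
    """Orthonormal entity features plus the spectrum that selected them.

    ``F`` has one row per entity and ``f`` mutually orthonormal columns, the
    leading left singular vectors of the similarity matrix.  The full singular
    spectrum and the energy threshold are retained so the retained-energy
    fraction can be audited.
    """

    ids: tuple[str, ...]
    F: np.ndarray
    singular_values: np.ndarray
    alpha: float

    @property
    def rank(self) -> int:
        return self.F.shape[1]

    @property
    def retained_energy(self) -> float:
        f = self.rank
        return float(self.singular_values[:f].sum() / self.singular_values.sum())


def energy_rank(singular_values, alpha: float) -> int:
    """Smallest ``f`` with ``sum(s[:f]) / sum(s) >= alpha``.

    ``singular_values`` must be non-increasing and non-negative with at least
    one positive entry; ``alpha`` lies in (0, 1].
    """
    s = np.asarray(singular_values, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("need a 1-d, nonempty spectrum")
    if (s < 0).any() or (np.diff(s) > 1e-12).any():
        raise ValueError("spectrum must be non-increasing and non-negative")
    total = s.sum()
    if total <= 0:
        raise ValueError("all singular values are zero")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    frac = np.cumsum(s) / total
    return int(np.argmax(frac >= alpha - _ENERGY_EPS)) + 1


def extract_features(sim: SimilarityMatrix, alpha: float) -> FeatureMatrix:
    """Leading left singular vectors of a similarity matrix.

    The SVD is taken of the similarity matrix as-is (no centering: the unit
    diagonal is structural and centering would destroy it).  Column signs are
    fixed deterministically — the largest-magnitude entry of each retained
    column is made positive — so results do not depend on the SVD backend.
    """
    U, s, _ = np.linalg.svd(sim.S, full_matrices=False)
    f = energy_rank(s, alpha)
    F = U[:, :f].copy()
    for k in range(f):
        j = int(np.argmax(np.abs(F[:, k])))
        if F[j, k] < 0:
            F[:, k] = -F[:, k]
    return FeatureMatrix(sim.ids, F, s.copy(), float(alpha))
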