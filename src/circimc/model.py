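"""Model/Results interface wiring the whole pipeline.

``CircDiseaseIMC`` holds the data (association matrix, sequences, ontology)
and the pipeline hyperparameters; ``fit()`` runs similarity integration,
feature extraction and the inductive matrix-completion solver and returns an
``IMCResults`` carrying the latent solution, the dense score matrix,
convergence diagnostics and ranking/evaluation helpers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data import AssociationDataset, SequenceRecord
from .evaluation import EvaluationResult, loocv, top_k
from .features import FeatureMatrix, extract_features
from .imc import SolverConfig, SolverResult, score_matrix, solve_imc
from .similarity import (
    OntologyGraph,
    SimilarityMatrix,
    gip_similarity_matrix,
    integrate_similarity,
    sequence_similarity_matrix,
    wang_similarity_matrix,
)

__all__ = ["CircDiseaseIMC", "IMCResults"]


class CircDiseaseIMC:
    """Inductive matrix completion model for circRNA-disease associations.

    Parameters
    ----------
    dataset : binary association matrix with entity labels.
    sequences : circRNA nucleotide sequences (one per dataset row).  When
        omitted, the circRNA side falls back to the GIP kernel alone.
    ontology : disease ontology; dataset disease ids must be term ids.  When
        omitted, the disease side falls back to the GIP kernel alone.
    alpha_circ, alpha_disease : SVD energy thresholds for the circRNA and
        disease feature matrices (defaults 0.6 and 0.9).
    weight : convex weight of the sequence/semantic kernel against the GIP
        kernel in the integrated similarities (default 0.5, the plain mean).
    config : solver configuration (nuclear-norm weight, tolerance, cap).
    """

    def __init__(
        self,
        dataset: AssociationDataset,
        sequences: Sequence[SequenceRecord] | None = None,
        ontology: OntologyGraph | None = None,
        *,
        alpha_circ: float = 0.6,
        alpha_disease: float = 0.9,
        weight: float = 0.5,
        config: SolverConfig | None = None,
    ) -> None:
        if not 0 < alpha_circ <= 1 or not 0 < alpha_disease <= 1:
            raise ValueError("energy thresholds must lie in (0, 1]")
        if not 0 <= weight <= 1:
            raise ValueError("kernel weight must lie in [0, 1]")
        self.dataset = dataset
        self.sequences = list(sequences) if sequences is not None else None
        self.ontology = ontology
        self.alpha_circ = float(alpha_circ)
        self.alpha_disease = float(alpha_disease)
        self.weight = float(weight)
        self.config = config or SolverConfig()
        self._sequence_sim: SimilarityMatrix | None = None
        self._semantic_sim: SimilarityMatrix | None = None

    @classmethod
    def from_files(
        cls,
        associations,
        fasta=None,
        obo=None,
        *,
        filter_incomplete: bool = True,
        **kwargs,
    ) -> "CircDiseaseIMC":
        """Build a model from an association table, FASTA and OBO paths.

        With ``filter_incomplete`` (default) associations whose circRNA lacks
        a sequence or whose disease is absent from the ontology are dropped
        before modelling, as are entities left without associations.
        """
        from . import io

        dataset = io.read_associations(associations)
        sequences = io.read_fasta(fasta) if fasta else None
        ontology = io.read_obo(obo) if obo else None
        if filter_incomplete and sequences is not None and ontology is not None:
            dataset = io.filter_complete(dataset, sequences, ontology)
        return cls(dataset, sequences, ontology, **kwargs)

    # -- fold-invariant kernels (cached) ----------------------------------

    @property
    def sequence_sim(self) -> SimilarityMatrix | None:
        """Pairwise normalised edit similarity of the circRNA sequences."""
        if self._sequence_sim is None and self.sequences is not None:
            by_id = {r.id: r for r in self.sequences}
            missing = [c for c in self.dataset.circ_ids if c not in by_id]
            if missing:
                raise ValueError(f"missing sequences for circRNAs: {missing[:5]}")
            ordered = [by_id[c] for c in self.dataset.circ_ids]
            self._sequence_sim = sequence_similarity_matrix(ordered)
        return self._sequence_sim

    @property
    def semantic_sim(self) -> SimilarityMatrix | None:
        """Pairwise Wang semantic similarity of the disease terms."""
        if self._semantic_sim is None and self.ontology is not None:
            self._semantic_sim = wang_similarity_matrix(
                self.ontology, list(self.dataset.disease_ids)
            )
        return self._semantic_sim

    def integrated_similarities(
        self, dataset: AssociationDataset | None = None
    ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        """Integrated CS and DS for the given (default: training) matrix."""
        ds = dataset or self.dataset
        gip_c = gip_similarity_matrix(ds, "rows")
        gip_d = gip_similarity_matrix(ds, "columns")
        CS = (
            integrate_similarity(self.sequence_sim, gip_c, self.weight)
            if self.sequence_sim is not None
            else gip_c
        )
        DS = (
            integrate_similarity(self.semantic_sim, gip_d, self.weight)
            if self.semantic_sim is not None
            else gip_d
        )
        return CS, DS

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "IMCResults":
        """Run the full pipeline and return results."""
        CS, DS = self.integrated_similarities()
        C = extract_features(CS, self.alpha_circ)
        D = extract_features(DS, self.alpha_disease)
        solver_result = solve_imc(C, D, self.dataset, self.config)
        return IMCResults(self, C, D, solver_result)

    def loocv(self, **kwargs) -> EvaluationResult:
        """Leave-one-out cross validation under this model's parameters."""
        return loocv(
            self.dataset,
            config=self.config,
            alpha_circ=self.alpha_circ,
            alpha_disease=self.alpha_disease,
            weight=self.weight,
            sequence_sim=self.sequence_sim,
            semantic_sim=self.semantic_sim,
            **kwargs,
        )


class IMCResults:
    """Fitted model results: latent matrix, scores, diagnostics, rankings."""

    def __init__(
        self,
        model: CircDiseaseIMC,
        circ_features: FeatureMatrix,
        disease_features: FeatureMatrix,
        solver_result: SolverResult,
    ) -> None:
        self.model = model
        self.circ_features = circ_features
        self.disease_features = disease_features
        self.solver_result = solver_result

    # -- solution views ---------------------------------------------------

    @property
    def Z(self) -> np.ndarray:
        return self.solver_result.Z

    @property
    def scores(self) -> pd.DataFrame:
        """Dense score matrix as a labeled DataFrame (circRNAs x diseases)."""
        ds = self.model.dataset
        return pd.DataFrame(
            self.solver_result.scores,
            index=list(ds.circ_ids),
            columns=list(ds.disease_ids),
        )

    def score_table(self) -> pd.DataFrame:
        """Long-format table: circ_id, disease_id, score, known."""
        return score_matrix(self.solver_result, self.model.dataset)

    def predict(self, circ_id: str, disease_id: str) -> float:
        ds = self.model.dataset
        i = ds.circ_ids.index(circ_id)
        j = ds.disease_ids.index(disease_id)
        return float(self.solver_result.scores[i, j])

    def top_k(self, k: int, include_known: bool = True) -> pd.DataFrame:
        """Top-k ranked pairs; set ``include_known=False`` for candidates only."""
        return top_k(self.score_table(), k, include_known=include_known)

    # -- diagnostics ------------------------------------------------------

    @property
    def objective_trace(self) -> list[float]:
        return self.solver_result.objective_trace

    @property
    def iterations(self) -> int:
        return self.solver_result.iterations

    @property
    def converged(self) -> bool:
        return self.solver_result.converged

    def summary(self) -> str:
        """Human-readable fit summary."""
        ds = self.model.dataset
        cfg = self.model.config
        lines = [
            "Inductive Matrix Completion Results",
            "=" * 56,
            f"{'circRNAs':<28}{ds.n_circ:>28}",
            f"{'diseases':<28}{ds.n_disease:>28}",
            f"{'known associations':<28}{ds.n_associations:>28}",
            f"{'matrix density':<28}{ds.density:>28.4f}",
            f"{'circ features (alpha)':<28}"
            f"{f'{self.circ_features.rank} ({self.model.alpha_circ})':>28}",
            f"{'disease features (alpha)':<28}"
            f"{f'{self.disease_features.rank} ({self.model.alpha_disease})':>28}",
            f"{'circ retained energy':<28}{self.circ_features.retained_energy:>28.4f}",
            f"{'disease retained energy':<28}{self.disease_features.retained_energy:>28.4f}",
            f"{'nuclear-norm weight':<28}{cfg.lambda_:>28g}",
            f"{'iterations':<28}{self.iterations:>28}",
            f"{'converged':<28}{str(self.converged):>28}",
            f"{'final objective':<28}{self.objective_trace[-1]:>28.6f}",
            "=" * 56,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<IMCResults: {self.model.dataset.shape[0]}x"
            f"{self.model.dataset.shape[1]}, iterations={self.iterations}, "
            f"converged={self.converged}>"
        )
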