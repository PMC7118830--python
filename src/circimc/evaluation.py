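"""Leave-one-out cross validation and ranking metrics.

The LOOCV protocol: each known association (circ i, disease j) is removed
from the matrix in turn and the whole pipeline — GIP kernels, integrated
similarities, feature extraction, solver — is rerun on the training matrix,
so no information about the held-out label leaks into its own score.  The
held-out pair is the fold's positive; every circRNA never associated with
disease j is a candidate negative.  A candidate scored in several folds (one
per known association of its disease) keeps, by default, its maximum score
across folds.  ROC/AUC and precision-recall are computed over the pooled
scored pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .data import AssociationDataset, SequenceRecord
from .features import extract_features
from .imc import SolverConfig, solve_imc
from .similarity import (
    OntologyGraph,
    SimilarityMatrix,
    gip_similarity_matrix,
    integrate_similarity,
    sequence_similarity_matrix,
    wang_similarity_matrix,
)

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "sensitivity_specificity",
    "roc_auc",
    "pr_curve",
    "loocv",
    "top_k",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP))."""
    if counts.TP + counts.FN == 0:
        raise ValueError("sensitivity undefined: no positives")
    if counts.TN + counts.FP == 0:
        raise ValueError("specificity undefined: no negatives")
    return (
        counts.TP / (counts.TP + counts.FN),
        counts.TN / (counts.TN + counts.FP),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """AUC (trapezoidal; ties get half credit) and the ROC polyline.

    Returns ``(auc, points)`` where points run from (0, 0) to (1, 1) in
    (1 - specificity, sensitivity) coordinates.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("ROC needs at least one positive and one negative label")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def pr_curve(scores: Sequence[float], labels: Sequence[int]):
    """Precision-recall points at each distinct threshold, descending score."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0:
        raise ValueError("PR curve needs at least one positive label")
    precision, recall, _ = precision_recall_curve(y, s)
    # sklearn orders by increasing threshold and appends a (recall 0,
    # precision 1) anchor; drop the anchor, reverse to descending-threshold
    # order, and stop once full recall is reached (lower thresholds only
    # dilute precision at recall 1)
    pts = list(zip(recall[:-1].tolist(), precision[:-1].tolist()))[::-1]
    out = []
    for r, p in pts:
        out.append((r, p))
        if r >= 1.0:
            break
    return out


@dataclass
class EvaluationResult:
    """Pooled LOOCV scores with ROC/PR summaries."""

    scored_pairs: pd.DataFrame  # circ_id, disease_id, score, label
    auc: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    n_folds: int

    def top_candidates(self, k: int) -> pd.DataFrame:
        return top_k(
            self.scored_pairs.rename(columns={"label": "known"}).assign(
                known=lambda d: d["known"].astype(bool)
            ),
            k,
        )


def loocv(
    dataset: AssociationDataset,
    sequences: Sequence[SequenceRecord] | None = None,
    ontology: OntologyGraph | None = None,
    config: SolverConfig | None = None,
    *,
    alpha_circ: float = 0.6,
    alpha_disease: float = 0.9,
    weight: float = 0.5,
    aggregate: str = "max",
    sequence_sim: SimilarityMatrix | None = None,
    semantic_sim: SimilarityMatrix | None = None,
) -> EvaluationResult:
    """Leave-one-out cross validation of the full pipeline.

    Sequence and ontology similarities do not depend on the association
    labels, so they are computed once (or accepted precomputed); the GIP
    kernels, integrated similarities, features and solver are recomputed per
    fold from the training matrix with the held-out entry zeroed.

    aggregate : how a candidate negative scored in several folds is pooled:
        ``"max"`` keeps its best score across folds (default), ``"mean"``
        averages.
    """
    if dataset.n_associations < 2:
        raise ValueError("LOOCV needs at least two known associations")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    config = config or SolverConfig()

    if sequence_sim is None and sequences is not None:
        sequence_sim = sequence_similarity_matrix(_ordered(sequences, dataset))
    if semantic_sim is None and ontology is not None:
        semantic_sim = wang_similarity_matrix(ontology, list(dataset.disease_ids))
    if sequence_sim is not None and sequence_sim.ids != dataset.circ_ids:
        raise ValueError("sequence similarity ids do not match dataset circRNAs")
    if semantic_sim is not None and semantic_sim.ids != dataset.disease_ids:
        raise ValueError("semantic similarity ids do not match dataset diseases")

    pos_records: list[tuple[int, int, float]] = []
    neg_scores: dict[tuple[int, int], list[float]] = {}
    folds = sorted(dataset.omega)
    A_full = dataset.A

    for i, j in folds:
        A_train = A_full.copy()
        A_train[i, j] = 0
        train = AssociationDataset(dataset.circ_ids, dataset.disease_ids, A_train)
        scores = _fit_scores(
            train,
            sequence_sim,
            semantic_sim,
            alpha_circ,
            alpha_disease,
            weight,
            config,
        )
        pos_records.append((i, j, float(scores[i, j])))
        for i2 in np.flatnonzero(A_full[:, j] == 0):
            neg_scores.setdefault((int(i2), j), []).append(float(scores[i2, j]))

    rows = []
    for i, j, s in pos_records:
        rows.append((dataset.circ_ids[i], dataset.disease_ids[j], s, 1))
    for (i, j), vals in sorted(neg_scores.items()):
        s = max(vals) if aggregate == "max" else float(np.mean(vals))
        rows.append((dataset.circ_ids[i], dataset.disease_ids[j], s, 0))
    scored = pd.DataFrame(rows, columns=["circ_id", "disease_id", "score", "label"])

    auc, roc_pts = roc_auc(scored["score"], scored["label"])
    pr_pts = pr_curve(scored["score"], scored["label"])
    return EvaluationResult(
        scored_pairs=scored,
        auc=auc,
        roc_points=roc_pts,
        pr_points=pr_pts,
        n_folds=len(folds),
    )


def _ordered(
    sequences: Sequence[SequenceRecord], dataset: AssociationDataset
) -> list[SequenceRecord]:
    by_id = {r.id: r for r in sequences}
    missing = [c for c in dataset.circ_ids if c not in by_id]
    if missing:
        raise ValueError(f"missing sequences for circRNAs: {missing[:5]}")
    return [by_id[c] for c in dataset.circ_ids]


def _fit_scores(
    train: AssociationDataset,
    sequence_sim: SimilarityMatrix | None,
    semantic_sim: SimilarityMatrix | None,
    alpha_circ: float,
    alpha_disease: float,
    weight: float,
    config: SolverConfig,
) -> np.ndarray:
    """One pipeline pass: GIP -> integration -> features -> solver -> scores."""
    gip_c = gip_similarity_matrix(train, "rows")
    gip_d = gip_similarity_matrix(train, "columns")
    CS = (
        integrate_similarity(sequence_sim, gip_c, weight)
        if sequence_sim is not None
        else gip_c
    )
    DS = (
        integrate_similarity(semantic_sim, gip_d, weight)
        if semantic_sim is not None
        else gip_d
    )
    C = extract_features(CS, alpha_circ)
    D = extract_features(DS, alpha_disease)
    return solve_imc(C, D, train, config).scores


def top_k(score_table: pd.DataFrame, k: int, include_known: bool = True) -> pd.DataFrame:
    """Top-k pairs by descending score, ties broken by (circ_id, disease_id).

    With ``include_known=False`` only unknown (candidate) pairs are ranked;
    by default all pairs are ranked with known associations flagged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    table = score_table if include_known else score_table[~score_table["known"]]
    ranked = table.sort_values(
        ["score", "circ_id", "disease_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out = ranked.head(k).copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
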