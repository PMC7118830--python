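"""Nuclear-norm-regularized inductive matrix completion.

Given entity feature matrices C (m x f_c) and D (n x f_d) and a partially
observed binary association matrix A, the solver seeks a small latent matrix
Z minimising

    lambda * ||Z||_*  +  1/2 * || R_Omega(C Z D^T - A) ||_F^2

where ``||.||_*`` is the nuclear norm (sum of singular values, the convex
surrogate for rank) and ``R_Omega`` zeroes residuals outside the observed
entry set Omega.  The dense score matrix ``C Z D^T`` ranks every
circRNA-disease pair, including the unobserved ones.

The minimisation uses accelerated proximal gradient descent whose proximal
step is singular value thresholding (SVT): soft-thresholding the singular
values of the gradient-stepped iterate.  A monotone safeguard restarts the
momentum whenever a step would increase the objective, so the objective trace
is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import AssociationDataset
from .features import FeatureMatrix

__all__ = [
    "SolverConfig",
    "SolverResult",
    "objective",
    "gradient",
    "svt_prox",
    "solve_imc",
    "score_matrix",
]


@dataclass(frozen=True)
class SolverConfig:
    """Solver hyperparameters.

    lambda_ : nuclear-norm weight (default 1).
    tau : proximal step parameter, or "auto" for the gradient's Lipschitz
        constant ``||C||_2^2 * ||D||_2^2`` (exactly 1 for orthonormal
        features).
    tolerance : relative objective-gap stopping rule
        ``1 - obj_k / obj_{k-1} < tolerance``.
    max_iterations : iteration cap.
    seed : reserved for randomised initialisation; the default start is Z = 0
        and deterministic.
    """

    lambda_: float = 1.0
    tau: float | str = "auto"
    tolerance: float = 1e-5
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tau != "auto" and not (
            isinstance(self.tau, (int, float)) and self.tau > 0
        ):
            raise ValueError("tau must be 'auto' or a positive number")


@dataclass
class SolverResult:
    """Latent solution, objective trace and the dense score matrix."""

    Z: np.ndarray
    objective_trace: list[float]
    iterations: int
    converged: bool
    scores: np.ndarray  # m x n, C @ Z @ D.T


def _feature_array(F) -> np.ndarray:
    return F.F if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)


def _mask(dataset: AssociationDataset) -> np.ndarray:
    return dataset.A != 0


def objective(
    Z: np.ndarray,
    C,
    D,
    dataset: AssociationDataset,
    lambda_: float = 1.0,
) -> float:
    """lambda * (sum of singular values of Z) + 1/2 * masked squared residual."""
    C = _feature_array(C)
    D = _feature_array(D)
    Z = np.asarray(Z, dtype=float)
    if Z.shape != (C.shape[1], D.shape[1]):
        raise ValueError(
            f"Z shape {Z.shape} incompatible with features "
            f"({C.shape[1]} x {D.shape[1]})"
        )
    R = (C @ Z @ D.T - dataset.A) * _mask(dataset)
    nuc = float(np.linalg.svd(Z, compute_uv=False).sum())
    return lambda_ * nuc + 0.5 * float((R * R).sum())


def gradient(Y: np.ndarray, C, D, dataset: AssociationDataset) -> np.ndarray:
    """Gradient of the data-fit term at Y: ``C^T R_Omega(C Y D^T - A) D``."""
    C = _feature_array(C)
    D = _feature_array(D)
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (C.shape[1], D.shape[1]):
        raise ValueError(
            f"Y shape {Y.shape} incompatible with features "
            f"({C.shape[1]} x {D.shape[1]})"
        )
    R = (C @ Y @ D.T - dataset.A) * _mask(dataset)
    return C.T @ R @ D


def svt_prox(M: np.ndarray, threshold: float) -> np.ndarray:
    """Singular value thresholding: the proximal operator of the nuclear norm.

    Soft-thresholds the singular values of M; the result is the minimiser of
    ``threshold * ||Z||_* + 1/2 * ||Z - M||_F^2``.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    M = np.asarray(M, dtype=float)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - threshold, 0.0)
    return (U * s) @ Vt


def solve_imc(
    C,
    D,
    dataset: AssociationDataset,
    config: SolverConfig | None = None,
) -> SolverResult:
    """Accelerated proximal gradient with singular value thresholding.

    Iterates ``Z_k = svt_prox(Y_k - grad(Y_k)/tau, lambda/tau)`` with Nesterov
    momentum on the extrapolation point Y.  On any step that would raise the
    objective the momentum is restarted (Y reset to the last accepted Z), so
    the recorded trace is non-increasing.  Stops when the relative objective
    gap ``1 - obj_k/obj_{k-1}`` drops below the configured tolerance, or at
    the iteration cap.
    """
    config = config or SolverConfig()
    Ca = _feature_array(C)
    Da = _feature_array(D)
    if Ca.shape[0] != dataset.n_circ or Da.shape[0] != dataset.n_disease:
        raise ValueError("feature row counts do not match the dataset")
    if config.tau == "auto":
        tau = (
            np.linalg.norm(Ca, 2) ** 2 * np.linalg.norm(Da, 2) ** 2
        )
    else:
        tau = float(config.tau)
    if tau <= 0:
        raise ValueError("tau must be positive")
    lam = config.lambda_

    Z = np.zeros((Ca.shape[1], Da.shape[1]))
    Y = Z
    t = 1.0
    obj = objective(Z, Ca, Da, dataset, lam)
    trace = [obj]
    converged = False
    iterations = 0

    def _step(Y):
        G = gradient(Y, Ca, Da, dataset)
        Zn = svt_prox(Y - G / tau, lam / tau)
        return Zn, objective(Zn, Ca, Da, dataset, lam)

    for _ in range(config.max_iterations):
        Zn, obj_n = _step(Y)
        if obj_n > obj:
            # monotone safeguard: drop momentum, retry from the last accepted Z
            Y, t = Z, 1.0
            Zn, obj_n = _step(Y)
            if obj_n > obj:
                Zn, obj_n = Z, obj  # no descent available; stall -> stop below
        if not np.isfinite(obj_n):
            raise FloatingPointError("objective became non-finite")
        iterations += 1
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Y = Zn + ((t - 1.0) / t_next) * (Zn - Z)
        rel_gap = 1.0 if obj == 0 else 1.0 - obj_n / obj
        Z, obj, t = Zn, obj_n, t_next
        trace.append(obj)
        if obj == 0 or rel_gap < config.tolerance:
            converged = True
            break

    scores = Ca @ Z @ Da.T
    return SolverResult(
        Z=Z,
        objective_trace=trace,
        iterations=iterations,
        converged=converged,
        scores=scores,
    )


def score_matrix(result: SolverResult, dataset: AssociationDataset) -> pd.DataFrame:
    """Long-format score table with ids and known-association flags."""
    m, n = dataset.shape
    if result.scores.shape != (m, n):
        raise ValueError("solver result shape does not match dataset")
    ci = np.repeat(np.arange(m), n)
    dj = np.tile(np.arange(n), m)
    return pd.DataFrame(
        {
            "circ_id": [dataset.circ_ids[i] for i in ci],
            "disease_id": [dataset.disease_ids[j] for j in dj],
            "score": result.scores.ravel(),
            "known": dataset.A.ravel().astype(bool),
        }
    )
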