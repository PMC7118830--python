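"""Independent numerical oracles shared across test modules."""

import numpy as np
from scipy.optimize import minimize


def prox_oracle(M: np.ndarray, t: float, rng: np.random.Generator,
                inner_rank: int | None = None, starts: int = 3) -> np.ndarray:
    """Minimise ``t*||Z||_* + 1/2*||Z - M||_F^2`` without singular value
    thresholding.

    Uses the variational characterisation of the nuclear norm,
    ``||Z||_* = min_{Z=AB} (||A||_F^2 + ||B||_F^2) / 2``, giving the smooth
    surrogate ``t/2(||A||^2+||B||^2) + 1/2||AB - M||^2`` minimised by L-BFGS
    from several random starts; with full inner rank its global minimum is the
    proximal point.
    """
    m, n = M.shape
    k = inner_rank or min(m, n)

    def fg(x):
        A = x[: m * k].reshape(m, k)
        B = x[m * k:].reshape(k, n)
        R = A @ B - M
        f = 0.5 * t * ((A * A).sum() + (B * B).sum()) + 0.5 * (R * R).sum()
        gA = t * A + R @ B.T
        gB = t * B + A.T @ R
        return f, np.concatenate([gA.ravel(), gB.ravel()])

    best = None
    for _ in range(starts):
        x0 = rng.normal(size=m * k + k * n)
        res = minimize(fg, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    A = best.x[: m * k].reshape(m, k)
    B = best.x[m * k:].reshape(k, n)
    return A @ B


def pairwise_auc(scores, labels) -> float:
    """Exhaustive concordant/discordant pair count (Mann-Whitney, ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
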