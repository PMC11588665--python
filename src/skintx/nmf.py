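"""Multiplicative-update nonnegative matrix factorization.

Shared numerical core for intratumor expression programs (genes x cells)
and spatial co-occurrence microenvironments (cell types x spots).  Lee-Seung
multiplicative updates minimize the Frobenius reconstruction error; each
update is guaranteed not to increase the objective, which the test suite
checks directly on the recorded objective trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NMFResult", "nmf_factorize"]

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray            # rows x k, factors ranked by explained energy
    H: np.ndarray            # k x cols
    objective: list[float]   # Frobenius error ||A - WH||_F per iteration
    n_iter: int
    converged: bool


def nmf_factorize(
    A: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> NMFResult:
    """Factorize a nonnegative matrix A ~ W @ H with k factors.

    Deterministic given ``seed`` (uniform random initialization scaled to
    the data).  Stops when the relative change of the Frobenius error falls
    below ``tol`` or after ``max_iter`` updates.  Factors are returned
    ranked by explained energy ||W_j|| * ||H_j||, descending.

    Raises ValueError on negative input (clipping negatives is the caller's
    explicit preprocessing step) and when k exceeds min(A.shape).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be a 2-D matrix")
    if A.size and A.min() < 0:
        raise ValueError("NMF input must be nonnegative; clip negatives first")
    n, m = A.shape
    if k < 1 or k > min(n, m):
        raise ValueError(f"k must lie in [1, min(A.shape)]={min(n, m)}, got {k}")

    norm_A = float(np.linalg.norm(A))
    if norm_A == 0.0:
        return NMFResult(
            W=np.zeros((n, k)), H=np.zeros((k, m)), objective=[0.0], n_iter=0,
            converged=True,
        )

    rng = np.random.default_rng(seed)
    scale = np.sqrt(A.mean() / k)
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale + _EPS

    objective = [float(np.linalg.norm(A - W @ H))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # H <- H * (W^T A) / (W^T W H)
        H *= (W.T @ A) / np.maximum(W.T @ W @ H, _EPS)
        # W <- W * (A H^T) / (W H H^T)
        W *= (A @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
        err = float(np.linalg.norm(A - W @ H))
        objective.append(err)
        prev = objective[-2]
        if prev > 0 and abs(prev - err) / max(prev, _EPS) < tol:
            converged = True
            break

    # rank factors by explained energy
    energy = np.linalg.norm(W, axis=0) * np.linalg.norm(H, axis=1)
    order = np.argsort(-energy, kind="stable")
    return NMFResult(
        W=W[:, order], H=H[order, :], objective=objective, n_iter=it,
        converged=converged,
    )
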