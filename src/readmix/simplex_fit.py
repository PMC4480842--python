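"""Core fitting kernels on the admixture simplex.

Three primitives drive the decomposition:

* a penalized squared-error loss ``L(d)`` on a residual vector that
  punishes overshooting any component by more than a tolerance epsilon,
* the affinity score: the mixing proportion ``alpha`` of a candidate
  population that minimizes ``L(T - alpha * P)`` against the current
  residual, and
* the Chebyshev (minimax / L-infinity) weight fit: given a fixed subset
  S of reference populations, the convex-combination weights A minimizing
  ``max_k |(R_S^T A)_k - T_k|``, solved exactly as a linear program.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "FitParams",
    "FitResult",
    "loss_fn",
    "affinity_score",
    "chebyshev_weights",
]


@dataclasses.dataclass(frozen=True)
class FitParams:
    """Tunables for the penalized loss and affinity search.

    epsilon
        Overshoot tolerance: a residual component below ``-epsilon``
        triggers the sparsity penalty term.
    alpha_grid
        Step of the coarse grid scan over alpha in [0, 1]; a fine local
        scan one coarse step wide refines the optimum.
    """

    epsilon: float = 0.01
    alpha_grid: float = 1e-4

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0 < self.alpha_grid <= 0.1:
            raise ValueError("alpha_grid must be in (0, 0.1]")


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of a Chebyshev weight fit for a fixed population subset."""

    weights: np.ndarray
    minimax_error: float
    approximation: np.ndarray


def loss_fn(d: Sequence[float], epsilon: float = 0.01) -> float:
    """Penalized squared-error loss on a residual vector.

    ``sum_i d_i^2`` plus, for every component overshot beyond the
    tolerance (``d_i < -epsilon``), a penalty ``1 + 2|d_i|``.  The unit
    offset makes including a population that overshoots any component
    strictly worse than leaving it out, which is what keeps the greedy
    construction sparse.
    """
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("residual vector contains non-finite values")
    over = d < -epsilon
    return float(np.sum(d * d) + np.sum(over) + 2.0 * np.sum(np.abs(d[over])))


def _loss_profile(T: np.ndarray, P: np.ndarray, alphas: np.ndarray, epsilon: float) -> np.ndarray:
    # vectorized loss_fn over a batch of alphas
    d = T[None, :] - alphas[:, None] * P[None, :]
    over = d < -epsilon
    return np.sum(d * d, axis=1) + np.sum(over, axis=1) + 2.0 * np.sum(
        np.where(over, np.abs(d), 0.0), axis=1
    )


def affinity_score(
    P: Sequence[float],
    T: Sequence[float],
    params: FitParams | None = None,
) -> tuple[float, float]:
    """Best mixing proportion of candidate ``P`` against residual ``T``.

    Minimizes ``loss_fn(T - alpha * P)`` over ``alpha`` in [0, 1] by a
    deterministic grid scan at ``params.alpha_grid`` resolution followed
    by a 100x finer scan in the bracket around the coarse optimum (the
    loss is piecewise smooth but its penalty term is discontinuous, so a
    derivative-based refinement is not reliable).

    Returns ``(alpha, loss)``.
    """
    if params is None:
        params = FitParams()
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    if P.shape != T.shape:
        raise ValueError("P and T must have the same length")
    step = params.alpha_grid
    coarse = np.arange(0.0, 1.0 + step / 2, step)
    coarse[-1] = 1.0
    losses = _loss_profile(T, P, coarse, params.epsilon)
    i = int(np.argmin(losses))
    lo = max(coarse[i] - step, 0.0)
    hi = min(coarse[i] + step, 1.0)
    fine = np.linspace(lo, hi, 201)
    fl = _loss_profile(T, P, fine, params.epsilon)
    j = int(np.argmin(fl))
    return float(fine[j]), float(fl[j])


def chebyshev_weights(
    S: Sequence[int],
    panel,
    T: Sequence[float],
    allow_deficient: bool = False,
) -> FitResult:
    """Optimal convex-combination weights for a fixed population subset.

    Solves ``min_A max_k |(sum_i A_i r_{S(i)})_k - T_k|`` subject to
    ``A >= 0`` and ``sum(A) = 1`` as a linear program in ``(A, t)``:
    minimize ``t`` with ``-t <= (R_S^T A - T)_k <= t``.  The minimax
    value is unique even when the weight vector is not; ties among
    optimal weight vectors are resolved by the solver.

    With ``allow_deficient=True`` the equality constraint is relaxed to
    ``sum(A) <= 1`` (diagnostic use only).
    """
    S = tuple(int(i) for i in S)
    if not S:
        raise ValueError("S must be non-empty")
    if len(set(S)) != len(S):
        raise ValueError(f"duplicate indices in S: {S}")
    T = np.asarray(T, dtype=float)
    R_S = panel.R[list(S), :]  # (p, K)
    p, K = R_S.shape
    if T.size != K:
        raise ValueError(f"T has {T.size} components, panel has K={K}")

    # variables x = (a_1..a_p, t); minimize t
    c = np.zeros(p + 1)
    c[-1] = 1.0
    # R_S^T A - T <= t  and  T - R_S^T A <= t
    A_ub = np.vstack(
        [
            np.hstack([R_S.T, -np.ones((K, 1))]),
            np.hstack([-R_S.T, -np.ones((K, 1))]),
        ]
    )
    b_ub = np.concatenate([T, -T])
    ones = np.hstack([np.ones(p), 0.0])
    if allow_deficient:
        A_ub = np.vstack([A_ub, ones])
        b_ub = np.concatenate([b_ub, [1.0]])
        A_eq, b_eq = None, None
    else:
        A_eq, b_eq = ones[None, :], np.array([1.0])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * p + [(0, None)],
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9},
    )
    if not res.success:
        raise RuntimeError(
            f"Chebyshev LP failed for S={S}: {res.message} (status {res.status})"
        )
    weights = np.clip(res.x[:p], 0.0, None)
    if not allow_deficient:
        weights = weights / weights.sum()
    approx = weights @ R_S
    # recompute the minimax error from the weights so the reported value
    # is exactly consistent with them
    err = float(np.max(np.abs(approx - T)))
    return FitResult(weights=weights, minimax_error=err, approximation=approx)
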