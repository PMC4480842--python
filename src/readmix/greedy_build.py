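"""Phase 1: greedy construction of the first candidate solution.

Populations are added one at a time: each step picks the panel row with
the highest affinity score against the current residual, assigns it the
largest weight that keeps every residual component above ``-epsilon``
(scaled back by a safety factor beta), and subtracts its contribution.
The residual is a raw difference vector and may leave the simplex; the
affinity and weight rules are defined on differences, so it is never
renormalized.  After the set is built, the weights are re-fit by the
Chebyshev program on the full set, and a best-improvement swap pass
exchanges members for outside populations while that reduces the
minimax error.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .simplex_fit import FitParams, affinity_score, chebyshev_weights

__all__ = [
    "GreedyParams",
    "Solution",
    "pick_next_population",
    "population_weight",
    "build_initial_solution",
    "swap_improve",
]

#: a swap must reduce the minimax error by more than this to be applied
SWAP_TOL = 1e-9
#: greedy stops adding populations once the re-fit error is this small
STOP_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class GreedyParams:
    """Knobs of the greedy construction.

    beta
        Safety scaling of the subtraction weight (0 < beta <= 1).  The
        raw weight is the largest w keeping ``w * r < T + epsilon``
        componentwise; scaling it back leaves headroom so a single
        greedy step never fully consumes a component that later
        populations also need.
    epsilon
        Overshoot tolerance shared with the loss.
    max_pops
        Maximum number of ancestral populations p.  Four covers the
        grandparent generation, the deepest family structure the method
        is meant to resolve.
    """

    beta: float = 0.95
    epsilon: float = 0.01
    max_pops: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if self.max_pops < 1:
            raise ValueError("max_pops must be >= 1")


@dataclasses.dataclass(frozen=True)
class Solution:
    """A candidate decomposition: population indices S with weights A."""

    indices: tuple[int, ...]
    weights: np.ndarray
    minimax_error: float

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.weights):
            raise ValueError("indices and weights must have equal length")

    def pruned(self, tol: float = 1e-6) -> "Solution":
        """Drop members whose weight is below ``tol`` and renormalize."""
        keep = self.weights >= tol
        if keep.all() or not keep.any():
            return self
        w = self.weights[keep]
        return Solution(
            indices=tuple(np.asarray(self.indices)[keep]),
            weights=w / w.sum(),
            minimax_error=self.minimax_error,
        )


def pick_next_population(
    panel,
    T_residual: Sequence[float],
    exclude: set[int] | Sequence[int] = (),
    params: FitParams | None = None,
) -> int:
    """Index of the non-excluded population with the highest affinity.

    Ties are broken toward the lowest panel index.  The affinity of a
    candidate is the loss at its best mixing proportion, so "highest
    affinity" means lowest achievable penalized loss.
    """
    if params is None:
        params = FitParams()
    exclude = set(exclude)
    best_j, best_loss = -1, np.inf
    for j in range(len(panel)):
        if j in exclude:
            continue
        _, loss = affinity_score(panel.R[j], T_residual, params)
        if loss < best_loss - 1e-15:
            best_j, best_loss = j, loss
    if best_j < 0:
        raise ValueError("all populations excluded")
    return best_j


def population_weight(
    r: Sequence[float],
    T_residual: Sequence[float],
    params: GreedyParams | None = None,
) -> float:
    """Largest admissible subtraction weight for population vector ``r``.

    Returns ``beta * min(1, min_{k: r_k > 0} (t_k + epsilon) / r_k)``
    floored at zero: the biggest w (scaled back by beta) such that
    subtracting ``w * r`` keeps every residual component above
    ``-epsilon``.
    """
    if params is None:
        params = GreedyParams()
    r = np.asarray(r, dtype=float)
    t = np.asarray(T_residual, dtype=float)
    pos = r > 0
    if not pos.any():
        raise ValueError("reference vector is all-zero")
    w = np.min((t[pos] + params.epsilon) / r[pos])
    return params.beta * float(np.clip(w, 0.0, 1.0))


def _refit(
    S: Sequence[int], panel, T: Sequence[float], cache: dict | None = None
) -> Solution:
    key = tuple(sorted(int(i) for i in S))
    if cache is not None and key in cache:
        return cache[key]
    fit = chebyshev_weights(key, panel, T)
    sol = Solution(key, fit.weights, fit.minimax_error)
    if cache is not None:
        cache[key] = sol
    return sol


def build_initial_solution(
    panel,
    T: Sequence[float],
    fixed: Sequence[int] = (),
    params: GreedyParams | None = None,
) -> Solution:
    """Greedily grow a candidate set and re-fit its weights.

    Starts from the user-fixed (prior) populations, whose weights are
    computed and subtracted first in the given order, then repeatedly
    adds the best-affinity population until ``max_pops`` members are
    reached or the re-fit minimax error is already negligible.  The
    final weights always come from the Chebyshev re-fit on the full set.
    """
    if params is None:
        params = GreedyParams()
    if len(panel) == 0:
        raise ValueError("empty panel")
    fixed = [int(i) for i in fixed]
    if len(fixed) > params.max_pops:
        raise ValueError(
            f"{len(fixed)} fixed populations exceed max_pops={params.max_pops}"
        )
    fit_params = FitParams(epsilon=params.epsilon)
    T = np.asarray(T, dtype=float)
    residual = T.copy()
    S: list[int] = []
    for j in fixed:
        w = population_weight(panel.R[j], residual, params)
        residual = residual - w * panel.R[j]
        S.append(j)
    if S:
        sol = _refit(S, panel, T)
        if sol.minimax_error <= STOP_TOL:
            return sol
    while len(S) < params.max_pops and len(S) < len(panel):
        j = pick_next_population(panel, residual, exclude=S, params=fit_params)
        w = population_weight(panel.R[j], residual, params)
        residual = residual - w * panel.R[j]
        S.append(j)
        sol = _refit(S, panel, T)
        if sol.minimax_error <= STOP_TOL:
            break
    return sol


def swap_improve(
    solution: Solution,
    panel,
    T: Sequence[float],
    params: GreedyParams | None = None,
    fixed: Sequence[int] = (),
    cache: dict | None = None,
) -> Solution:
    """Best-improvement swap search around a candidate solution.

    Repeatedly evaluates every exchange of a member x for an outside
    population y (re-fitting weights each time) and applies the swap
    with the largest reduction in minimax error, until no swap improves
    by more than a small tolerance.  Fixed (prior) populations are never
    swapped out.
    """
    fixed = set(int(i) for i in fixed)
    current = solution
    N = len(panel)
    while True:
        best_swap: Solution | None = None
        in_set = set(current.indices)
        for x_pos, x in enumerate(current.indices):
            if x in fixed:
                continue
            for y in range(N):
                if y in in_set:
                    continue
                cand_idx = list(current.indices)
                cand_idx[x_pos] = y
                cand = _refit(cand_idx, panel, T, cache)
                if cand.minimax_error < current.minimax_error - SWAP_TOL and (
                    best_swap is None or cand.minimax_error < best_swap.minimax_error
                ):
                    best_swap = cand
        if best_swap is None:
            return current
        current = best_swap
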