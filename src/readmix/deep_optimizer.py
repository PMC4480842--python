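"""Differential Evolution Entirely Parallel (DEEP) global search.

A differential-evolution variant that, per generation, builds two trial
vectors for every member — the classic rand/1 difference vector and a
trigonometric-mutation vector biased toward the best of three random
members — combines them by binomial or exponential recombination, and
accepts the combined trial only on strict improvement of the objective.
Every fixed number of generations the oldest members (those longest
without an accepted update) are overwritten with copies of the current
best members.

Candidate decompositions are encoded for DEEP as continuous vectors in
``[0, N)``: each coordinate decodes to a panel index by flooring with
wrap-around, and duplicate indices are repaired by advancing to the
next unused index.  The objective of an encoded vector is the Chebyshev
minimax error of the decoded population set.

All trial vectors of a generation are generated from the seeded RNG in
member order before any objective evaluation, so evaluations may be
dispatched to worker threads without perturbing the random stream: the
trajectory is bit-identical for any worker count.
"""

from __future__ import annotations

import dataclasses
from concurrent.futures import ThreadPoolExecutor
from typing import Callable, Sequence

import numpy as np

from .simplex_fit import chebyshev_weights

__all__ = [
    "DEConfig",
    "DEState",
    "Member",
    "mutate_rand1",
    "mutate_trigonometric",
    "recombine",
    "select_replace",
    "substitute_oldest",
    "run_deep",
    "decode_indices",
    "make_index_objective",
]


@dataclasses.dataclass(frozen=True)
class DEConfig:
    """DEEP hyperparameters.

    NP            set size (number of evolving vectors)
    S_const       scaling constant of the rand/1 difference mutation
    crossover_p   probability of taking a coordinate from the first trial
    G_max         number of generations
    M             extra random candidate solutions seeded alongside the
                  greedy one (the ensemble averages over M + 1 results)
    recombination 'binomial' or 'exponential'
    substitution_period / substitution_count
                  every `period` generations the `count` oldest members
                  are replaced by copies of the `count` best
    workers       thread-pool slots for objective evaluation; has no
                  effect on the trajectory, only on wall time
    """

    NP: int = 30
    S_const: float = 0.9
    crossover_p: float = 0.5
    G_max: int = 100
    M: int = 10
    recombination: str = "binomial"
    substitution_period: int = 20
    substitution_count: int = 3
    seed: int | None = None
    workers: int = 5

    def __post_init__(self) -> None:
        if self.NP < 4:
            raise ValueError("NP must be >= 4")
        if not 0 < self.crossover_p < 1:
            raise ValueError("crossover_p must be in (0, 1)")
        if self.substitution_count >= self.NP:
            raise ValueError("substitution_count must be < NP")
        if self.recombination not in ("binomial", "exponential"):
            raise ValueError("recombination must be 'binomial' or 'exponential'")


@dataclasses.dataclass
class Member:
    """One evolving vector with its objective value and age."""

    vector: np.ndarray
    value: float
    age: int = 0


@dataclasses.dataclass
class DEState:
    """The evolving set: vectors, objective values, ages, generation."""

    members: np.ndarray  # (NP, dim)
    values: np.ndarray  # (NP,)
    ages: np.ndarray  # (NP,) generations since last accepted update
    generation: int = 0
    best_trace: list = dataclasses.field(default_factory=list)

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.values))


def mutate_rand1(
    q_r1: np.ndarray, q_r2: np.ndarray, q_r3: np.ndarray, S_const: float
) -> np.ndarray:
    """Classic rand/1 mutation: ``q_r1 + S * (q_r2 - q_r3)``."""
    return np.asarray(q_r1) + S_const * (np.asarray(q_r2) - np.asarray(q_r3))


def mutate_trigonometric(
    q_r1: np.ndarray,
    q_r2: np.ndarray,
    q_r3: np.ndarray,
    F_vals: Sequence[float],
) -> np.ndarray:
    """Trigonometric mutation of three members.

    The centroid of the three vectors plus difference terms weighted by
    the normalized objective magnitudes ``phi_i = |F_i| / sum_j |F_j|``,
    which pulls the trial toward the better members.  When all three
    objective values are zero the trial is the plain centroid.
    """
    q1, q2, q3 = (np.asarray(q, dtype=float) for q in (q_r1, q_r2, q_r3))
    F1, F2, F3 = (abs(float(f)) for f in F_vals)
    total = F1 + F2 + F3
    centroid = (q1 + q2 + q3) / 3.0
    if total == 0.0:
        return centroid
    p1, p2, p3 = F1 / total, F2 / total, F3 / total
    return (
        centroid
        + (p2 - p1) * (q1 - q2)
        + (p3 - p2) * (q2 - q3)
        + (p1 - p3) * (q3 - q1)
    )


def recombine(
    v: np.ndarray,
    z: np.ndarray,
    crossover_p: float,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Combine the two trial vectors coordinate-wise.

    binomial: one uniform draw per coordinate; take ``v_j`` with
    probability ``crossover_p``, else ``z_j``.  exponential: take ``v_j``
    while successive draws stay below ``crossover_p``, then ``z_j`` for
    the remainder.
    """
    v = np.asarray(v, dtype=float)
    z = np.asarray(z, dtype=float)
    if v.shape != z.shape:
        raise ValueError("trial vectors must have the same shape")
    n = v.size
    if mode == "binomial":
        u = rng.random(n)
        return np.where(u < crossover_p, v, z)
    if mode == "exponential":
        u = rng.random(n)
        below = u < crossover_p
        cut = n if below.all() else int(np.argmin(below))
        out = z.copy()
        out[:cut] = v[:cut]
        return out
    raise ValueError(f"unknown recombination mode {mode!r}")


def select_replace(
    current: Member,
    trial: np.ndarray,
    objective: Callable[[np.ndarray], float],
    trial_value: float | None = None,
    extra_objectives: Sequence[tuple[Callable[[np.ndarray], float], float]] = (),
    rng: np.random.Generator | None = None,
) -> Member:
    """Flexible selection: accept the trial on strict decrease of the
    main objective.

    When the main objective did not improve, each optional
    ``(objective, acceptance_probability)`` pair in ``extra_objectives``
    is consulted in order: the trial is still accepted if that objective
    strictly improved and a uniform draw falls below the pair's
    predefined probability.  The decomposition pipeline defines a single
    objective, so the hook is unused by default.  On acceptance the
    member's age resets; otherwise it increments.
    """
    if trial_value is None:
        trial_value = objective(trial)
    accept = trial_value < current.value
    if not accept and extra_objectives:
        if rng is None:
            rng = np.random.default_rng(0)
        for extra, prob in extra_objectives:
            if extra(trial) < extra(current.vector) and rng.random() < prob:
                accept = True
                break
    if accept:
        return Member(vector=np.asarray(trial, dtype=float), value=trial_value, age=0)
    return Member(vector=current.vector, value=current.value, age=current.age + 1)


def substitute_oldest(state: DEState, count: int) -> DEState:
    """Overwrite the ``count`` oldest members with copies of the best.

    Age ties break toward the lower slot index, as do objective ties
    among the best.  Overwritten slots get age zero.
    """
    if count == 0:
        return state
    if count >= len(state.values):
        raise ValueError("count must be < NP")
    oldest = np.argsort(-state.ages, kind="stable")[:count]
    best = np.argsort(state.values, kind="stable")[:count]
    members = state.members.copy()
    values = state.values.copy()
    ages = state.ages.copy()
    for slot, src in zip(oldest, best):
        members[slot] = state.members[src]
        values[slot] = state.values[src]
        ages[slot] = 0
    return DEState(
        members=members,
        values=values,
        ages=ages,
        generation=state.generation,
        best_trace=state.best_trace,
    )


def _wrap(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + np.mod(x - lo, hi - lo)


def run_deep(
    objective: Callable[[np.ndarray], float],
    init: Sequence[np.ndarray],
    config: DEConfig,
    bounds: tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, DEState]:
    """Run DEEP from an initial candidate list.

    ``init`` is padded with uniform-random vectors (within ``bounds``)
    up to ``config.NP``.  Returns the best vector, its objective value,
    and the final state; ``state.best_trace`` records the best value per
    generation and is non-increasing.
    """
    if not init:
        raise ValueError("init must contain at least one vector")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = bounds
    dim = np.asarray(init[0]).size
    vecs = [np.asarray(v, dtype=float).ravel() for v in init]
    if any(v.size != dim for v in vecs):
        raise ValueError("init vectors must share one length")
    while len(vecs) < config.NP:
        vecs.append(rng.uniform(lo, hi, size=dim))
    vecs = vecs[: config.NP]

    pool = ThreadPoolExecutor(max_workers=config.workers) if config.workers > 1 else None
    try:
        def evaluate(batch: list[np.ndarray]) -> list[float]:
            if pool is not None:
                return list(pool.map(objective, batch))
            return [objective(v) for v in batch]

        values = np.array(evaluate(vecs), dtype=float)
        state = DEState(
            members=np.vstack(vecs),
            values=values,
            ages=np.zeros(config.NP, dtype=int),
        )
        state.best_trace.append(float(values.min()))

        NP = config.NP
        for g in range(1, config.G_max + 1):
            # draw all trials first; evaluation order then cannot touch the RNG
            trials = []
            for i in range(NP):
                r1, r2, r3 = _pick_distinct(rng, NP, i)
                v = mutate_rand1(
                    state.members[r1], state.members[r2], state.members[r3],
                    config.S_const,
                )
                z = mutate_trigonometric(
                    state.members[r1], state.members[r2], state.members[r3],
                    (state.values[r1], state.values[r2], state.values[r3]),
                )
                w = recombine(v, z, config.crossover_p, config.recombination, rng)
                trials.append(_wrap(w, lo, hi))
            trial_values = evaluate(trials)
            for i in range(NP):
                m = Member(state.members[i], float(state.values[i]), int(state.ages[i]))
                m = select_replace(m, trials[i], objective, trial_values[i])
                state.members[i] = m.vector
                state.values[i] = m.value
                state.ages[i] = m.age
            state.generation = g
            if (
                config.substitution_period > 0
                and g % config.substitution_period == 0
                and config.substitution_count > 0
            ):
                state = substitute_oldest(state, config.substitution_count)
            state.best_trace.append(float(state.values.min()))
    finally:
        if pool is not None:
            pool.shutdown()

    b = state.best_index
    return state.members[b].copy(), float(state.values[b]), state


def _pick_distinct(rng: np.random.Generator, NP: int, i: int) -> tuple[int, int, int]:
    # three distinct indices, all different from i
    idx = rng.permutation(NP)[:4]
    picked = [j for j in idx if j != i][:3]
    return int(picked[0]), int(picked[1]), int(picked[2])


# ---------------------------------------------------------------------------
# encoding of population-index sets as continuous DE vectors


def decode_indices(
    x: np.ndarray, N: int, exclude: Sequence[int] = ()
) -> tuple[int, ...]:
    """Decode a continuous vector in [0, N) to distinct panel indices.

    Each coordinate floors (with wrap-around) to an index; duplicates —
    including collisions with ``exclude`` — are repaired by advancing to
    the next unused index.
    """
    used = set(int(i) for i in exclude)
    out = []
    for xi in np.asarray(x, dtype=float).ravel():
        j = int(np.floor(xi)) % N
        while j in used:
            j = (j + 1) % N
        used.add(j)
        out.append(j)
    return tuple(out)


def make_index_objective(
    panel,
    T: np.ndarray,
    fixed: Sequence[int] = (),
    equal_weights: bool = False,
    fit: Callable[[tuple[int, ...]], float] | None = None,
) -> Callable[[np.ndarray], float]:
    """Objective for encoded index vectors: minimax error of the decoded set.

    Fixed (prior) populations are appended to every decoded set.  With
    ``equal_weights`` the weights are frozen at 1/p and the error is the
    plain L-infinity distance of the equal-weight mixture; otherwise the
    Chebyshev LP supplies the optimal weights.  ``fit`` can inject an
    externally cached fit; results are memoized per index set either
    way — the landscape is piecewise constant, so evolving vectors
    revisit the same sets constantly.
    """
    N = len(panel)
    T = np.asarray(T, dtype=float)
    fixed = tuple(int(i) for i in fixed)
    cache: dict[tuple[int, ...], float] = {}

    def objective(x: np.ndarray) -> float:
        S = tuple(sorted(decode_indices(x, N, exclude=fixed) + fixed))
        val = cache.get(S)
        if val is None:
            if fit is not None:
                val = float(fit(S))
            elif equal_weights:
                w = np.full(len(S), 1.0 / len(S))
                val = float(np.max(np.abs(w @ panel.R[list(S)] - T)))
            else:
                val = chebyshev_weights(S, panel, T).minimax_error
            cache[S] = val
        return val

    return objective
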