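"""End-to-end decomposition: greedy init, DEEP search, local refinement,
ensemble averaging.

The full procedure for one query vector T runs three phases:

1. greedy construction of an initial population set plus best-improvement
   swaps;
2. the initial solution is pooled with M random candidate sets, evolved
   by DEEP, and each of the best M + 1 resulting sets is polished by a
   local search over geographically and admixture-wise nearby
   populations;
3. populations present in at least 75% of the refined solutions are
   reported as the stable ancestry estimate with their weights averaged
   over the solutions containing them; the rest are listed as regional
   candidates.

Modes: unconditional (no prior), conditional (user-supplied prior
populations are forced into every candidate set, and dropped if they
demonstrably degrade the fit), and equal-weights (mixture proportions
known to be uniform a priori, only the population set is optimized).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .greedy_build import GreedyParams, Solution, build_initial_solution, swap_improve
from .deep_optimizer import DEConfig, decode_indices, make_index_objective, run_deep
from .simplex_fit import FitParams, chebyshev_weights


__all__ = [
    "ReAdmixConfig",
    "EnsembleReport",
    "run_readmix",
    "apply_prior",
    "local_refine",
    "ensemble_average",
    "classify_unmixed",
]

#: solution members below this weight are dropped before averaging
WEIGHT_PRUNE_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class ReAdmixConfig:
    """All tunables of the three-phase decomposition.

    stable_membership_frac
        Minimum share of refined solutions a population must appear in
        to be reported as stable (the 75% rule).
    unmixed_tol
        If the best single-population fit has minimax error at or below
        this, the individual is reported as unmixed and the search is
        skipped.
    prior_discard_margin
        A conditional fit may exceed the unconditional minimax error by
        at most this much; beyond it the prior contradicts the genotype
        and is discarded.
    prior_min_weight
        A forced prior population must carry at least this mean mixture
        weight across the conditional solutions; below it the data has
        effectively zeroed the prior out, which is the same
        contradiction expressed through the weights.
    local_radius_km / local_knn
        Neighborhood for the local refinement: populations within this
        great-circle radius of any solution member, plus this many
        nearest neighbors per member in L-infinity admixture distance.
    """

    greedy: GreedyParams = dataclasses.field(default_factory=GreedyParams)
    fit: FitParams = dataclasses.field(default_factory=FitParams)
    # memoized index-set objectives evaluate in well under a millisecond,
    # so thread dispatch costs more than it saves; worker counts > 1 give
    # an identical trajectory, only different wall time
    de: DEConfig = dataclasses.field(default_factory=lambda: DEConfig(workers=1))
    stable_membership_frac: float = 0.75
    unmixed_tol: float = 0.02
    prior_discard_margin: float = 0.05
    prior_min_weight: float = 0.01
    equal_weights: bool = False
    local_radius_km: float = 500.0
    local_knn: int = 10

    def __post_init__(self) -> None:
        if not 0.5 <= self.stable_membership_frac <= 1.0:
            raise ValueError("stable_membership_frac must be in [0.5, 1]")
        for attr in ("unmixed_tol", "prior_discard_margin", "local_radius_km"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")


@dataclasses.dataclass
class EnsembleReport:
    """Phase-3 output: the stable ancestry estimate and its provenance."""

    stable: list[tuple[str, float, float]]  # (name, mean weight, membership frac)
    regional: list[tuple[str, float]]  # (name, membership frac) below threshold
    mode: str
    prior_discarded: bool
    unmixed: bool
    solutions: list[Solution]
    minimax_error: float
    panel_names: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )

    def stable_with_coords(self):
        for name, w, frac in self.stable:
            yield name, w, frac, self.panel_names.get(name, (float("nan"),) * 2)

    @property
    def stable_names(self) -> list[str]:
        return [name for name, _, _ in self.stable]

    def weight_of(self, name: str) -> float:
        for n, w, _ in self.stable:
            if n == name:
                return w
        return 0.0


def classify_unmixed(
    T: Sequence[float], panel, config: ReAdmixConfig | None = None
) -> tuple[bool, int, float]:
    """Best single-population fit and the unmixed call.

    Returns ``(is_unmixed, best_index, minimax_error)`` where the error
    is the L-infinity distance of T to the closest panel row and the
    individual is called unmixed iff it is at or below ``unmixed_tol``.
    """
    if config is None:
        config = ReAdmixConfig()
    T = np.asarray(T, dtype=float)
    dists = np.max(np.abs(panel.R - T[None, :]), axis=1)
    j = int(np.argmin(dists))
    err = float(dists[j])
    # inclusive threshold with headroom for representation error
    return err <= config.unmixed_tol + 1e-12, j, err


def _fit_solution(
    S: Sequence[int],
    panel,
    T: np.ndarray,
    equal_weights: bool,
    cache: dict | None = None,
) -> Solution:
    S = tuple(sorted(int(i) for i in S))
    if cache is not None:
        hit = cache.get(S)
        if hit is not None:
            return hit
    if equal_weights:
        w = np.full(len(S), 1.0 / len(S))
        err = float(np.max(np.abs(w @ panel.R[list(S)] - T)))
        sol = Solution(S, w, err)
    else:
        fit = chebyshev_weights(S, panel, T)
        sol = Solution(S, fit.weights, fit.minimax_error)
    if cache is not None:
        cache[S] = sol
    return sol


def _neighborhood(solution: Solution, panel, config: ReAdmixConfig) -> set[int]:
    km = panel.pairwise_km()
    hood: set[int] = set()
    for m in solution.indices:
        hood.update(np.flatnonzero(km[m] <= config.local_radius_km).tolist())
        d = np.max(np.abs(panel.R - panel.R[m][None, :]), axis=1)
        hood.update(
            int(j) for j in np.argsort(d, kind="stable")[: config.local_knn + 1]
        )
    return hood


def local_refine(
    solution: Solution,
    panel,
    T: Sequence[float],
    config: ReAdmixConfig | None = None,
    fixed: Sequence[int] = (),
    cache: dict | None = None,
) -> Solution:
    """Exhaustive single-replacement search over nearby populations.

    The candidate pool is the union of populations within
    ``local_radius_km`` of any solution member and the ``local_knn``
    nearest populations in L-infinity admixture distance per member.
    This is what separates closely related neighbors (the classic
    Belorussian / Russian / Ukrainian confusion) that the global search
    may have interchanged.  Repeats best-improvement replacement to a
    fixed point; never removes fixed (prior) members.
    """
    if config is None:
        config = ReAdmixConfig()
    T = np.asarray(T, dtype=float)
    fixed = set(int(i) for i in fixed)
    current = solution
    while True:
        hood = _neighborhood(current, panel, config)
        hood -= set(current.indices)
        best: Solution | None = None
        for pos, x in enumerate(current.indices):
            if x in fixed:
                continue
            for y in hood:
                cand_idx = list(current.indices)
                cand_idx[pos] = y
                cand = _fit_solution(cand_idx, panel, T, config.equal_weights, cache)
                if cand.minimax_error < current.minimax_error - 1e-9 and (
                    best is None or cand.minimax_error < best.minimax_error
                ):
                    best = cand
        if best is None:
            return current
        current = best


def ensemble_average(
    solutions: Sequence[Solution],
    panel,
    config: ReAdmixConfig | None = None,
) -> EnsembleReport:
    """Phase 3: stable-membership averaging across candidate solutions.

    A population's membership fraction is the share of solutions that
    contain it with non-negligible weight.  Populations at or above
    ``stable_membership_frac`` form the stable set; their weights are
    averaged over the solutions containing them and renormalized to sum
    to one.  The remainder are reported as regional candidates.
    """
    if config is None:
        config = ReAdmixConfig()
    if not solutions:
        raise ValueError("need at least one solution to average")
    pruned = [s.pruned(WEIGHT_PRUNE_TOL) for s in solutions]
    n = len(pruned)
    counts: dict[int, int] = {}
    weight_sums: dict[int, float] = {}
    for sol in pruned:
        for idx, w in zip(sol.indices, sol.weights):
            counts[idx] = counts.get(idx, 0) + 1
            weight_sums[idx] = weight_sums.get(idx, 0.0) + float(w)
    stable_idx = sorted(
        (i for i, c in counts.items() if c / n >= config.stable_membership_frac),
        key=lambda i: -weight_sums[i] / counts[i],
    )
    regional_idx = sorted(
        (i for i in counts if i not in set(stable_idx)),
        key=lambda i: -counts[i],
    )
    stable: list[tuple[str, float, float]] = []
    if stable_idx:
        means = np.array([weight_sums[i] / counts[i] for i in stable_idx])
        means = means / means.sum()
        stable = [
            (panel.names[i], float(w), counts[i] / n)
            for i, w in zip(stable_idx, means)
        ]
    regional = [(panel.names[i], counts[i] / n) for i in regional_idx]
    best_err = min(s.minimax_error for s in pruned)
    return EnsembleReport(
        stable=stable,
        regional=regional,
        mode="unconditional",
        prior_discarded=False,
        unmixed=False,
        solutions=list(solutions),
        minimax_error=best_err,
        panel_names={panel.names[i]: tuple(panel.coords[i]) for i in counts},
    )


def _singleton_report(panel, j: int, err: float, mode: str) -> EnsembleReport:
    name = panel.names[j]
    sol = Solution((j,), np.array([1.0]), err)
    return EnsembleReport(
        stable=[(name, 1.0, 1.0)],
        regional=[],
        mode=mode,
        prior_discarded=False,
        unmixed=True,
        solutions=[sol],
        minimax_error=err,
        panel_names={name: tuple(panel.coords[j])},
    )


def _run_phases(
    T: np.ndarray,
    panel,
    fixed: tuple[int, ...],
    config: ReAdmixConfig,
    rng: np.random.Generator,
) -> EnsembleReport:
    N = len(panel)
    cache: dict = {}
    # Phase 1: greedy + swaps
    initial = build_initial_solution(panel, T, fixed=fixed, params=config.greedy)
    initial = swap_improve(
        initial, panel, T, params=config.greedy, fixed=fixed,
        cache=None if config.equal_weights else cache,
    )
    if config.equal_weights:
        initial = _fit_solution(initial.indices, panel, T, True, cache)

    p_free = len(initial.indices) - len(fixed)
    if p_free <= 0:
        # prior fills the whole set; nothing for the global search to move
        refined = local_refine(initial, panel, T, config, fixed=fixed, cache=cache)
        return ensemble_average([refined] * (config.de.M + 1), panel, config)

    # Phase 2: DEEP over encoded index vectors, then local refinement
    objective = make_index_objective(
        panel,
        T,
        fixed=fixed,
        equal_weights=config.equal_weights,
        fit=lambda S: _fit_solution(S, panel, T, config.equal_weights, cache).minimax_error,
    )
    free_members = [i for i in initial.indices if i not in set(fixed)]
    seed_vec = np.array(free_members, dtype=float) + 0.5
    init_vecs = [seed_vec] + [
        rng.uniform(0.0, N, size=p_free) for _ in range(config.de.M)
    ]
    _, _, state = run_deep(
        objective, init_vecs, config.de, bounds=(0.0, N), rng=rng
    )
    order = np.argsort(state.values, kind="stable")[: config.de.M + 1]
    refined: list[Solution] = []
    for slot in order:
        S = tuple(sorted(decode_indices(state.members[slot], N, exclude=fixed) + fixed))
        sol = _fit_solution(S, panel, T, config.equal_weights, cache)
        refined.append(local_refine(sol, panel, T, config, fixed=fixed, cache=cache))

    # Phase 3
    return ensemble_average(refined, panel, config)


def apply_prior(
    T: Sequence[float],
    panel,
    priors: Sequence[str],
    config: ReAdmixConfig,
    unconditional_error: float,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, ...], bool, EnsembleReport | None]:
    """Resolve prior population names and test them against the data.

    Runs the conditional fit seeded with the priors.  The prior
    contradicts the genotype — and is discarded — when either the
    conditional minimax error exceeds the unconditional error by more
    than ``prior_discard_margin``, or any forced prior population ends
    up carrying less than ``prior_min_weight`` mean weight across the
    conditional solutions (the optimizer has zeroed it out).  Returns
    ``(fixed_indices, prior_discarded, conditional_report)`` — the
    report is None when discarded.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    fixed = tuple(panel.index_of(name) for name in priors)
    T = np.asarray(T, dtype=float)
    report = _run_phases(T, panel, fixed, config, rng)
    if report.minimax_error > unconditional_error + config.prior_discard_margin:
        return fixed, True, None
    for j in fixed:
        mean_w = float(
            np.mean(
                [
                    sum(
                        w
                        for i, w in zip(sol.indices, sol.weights)
                        if i == j
                    )
                    for sol in report.solutions
                ]
            )
        )
        if mean_w < config.prior_min_weight:
            return fixed, True, None
    return fixed, False, report


def run_readmix(
    T: Sequence[float],
    panel,
    priors: Sequence[str] = (),
    config: ReAdmixConfig | None = None,
    seed: int | None = None,
) -> EnsembleReport:
    """Decompose one admixture vector against a reference panel.

    ``priors`` switches on conditional mode; ``config.equal_weights``
    freezes the mixture proportions at 1/p.  The seed controls the
    random candidates of the global search; a fixed seed gives an
    identical report on every run.
    """
    if config is None:
        config = ReAdmixConfig()
    T = np.asarray(T, dtype=float)
    if T.size != panel.K:
        raise ValueError(f"query has {T.size} components, panel K={panel.K}")
    fixed = tuple(panel.index_of(name) for name in priors)  # fail fast
    mode = (
        "equal_weights"
        if config.equal_weights
        else ("conditional" if priors else "unconditional")
    )

    is_unmixed, j, err = classify_unmixed(T, panel, config)
    if is_unmixed and not priors:
        return _singleton_report(panel, j, err, mode)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng_uncond, rng_cond = (
        np.random.default_rng(s) for s in ss.spawn(2)
    )
    report = _run_phases(T, panel, (), config, rng_uncond)
    report.mode = mode
    if not priors:
        return report

    fixed, discarded, cond_report = apply_prior(
        T, panel, priors, config, report.minimax_error, rng=rng_cond
    )
    if discarded:
        report.prior_discarded = True
        return report
    cond_report.mode = mode
    return cond_report
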