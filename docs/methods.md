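# Methods

## Problem and model

An individual's genome-wide ancestry is summarized by an admixture
vector **T** ∈ Δ^(K−1): K nonnegative proportions over putative
ancestral components, summing to 1. A reference panel supplies N modern
populations, each with a mean admixture vector **r**ᵢ on the same
simplex, geographic coordinates (decimal degrees, WGS84) and optionally
per-component variances σ²(**r**ᵢ) of the within-population admixture
proportions.

The inference task is a sparse convex decomposition: find a small index
set S = (s₁…s_p) and weights A on the simplex such that
P = Σ aᵢ **r**_{s(i)} is close to **T** in the L∞ (Chebyshev) sense,

    f(S, T) = min_A max_k |P_k − T_k|,  aᵢ ≥ 0, Σ aᵢ = 1.

L∞ is the right norm here because admixture proportions are maximum
likelihood estimates with component-wise error; a fit is only as good
as its worst component. For fixed S the inner problem is a linear
program in (A, t): minimize t subject to −t ≤ (R_Sᵀ A − T)_k ≤ t. We
solve it with `scipy.optimize.linprog` (HiGHS). The minimax value is
unique; the weight vector need not be when p > K + 1 or the references
are affinely dependent, in which case the solver's optimum is reported
and the ensemble stage (below) absorbs the ambiguity.

## Search procedure

Three phases produce the reported decomposition.

**Phase 1 — greedy construction.** Starting from the user-fixed prior
populations (conditional mode) or the empty set, repeatedly add the
panel row with the best *affinity* to the current residual. The
affinity of a candidate P against residual T is the minimum over
α ∈ [0, 1] of the penalized loss

    L(d) = Σ dᵢ² + Σ_{i : dᵢ < −ε} (1 + 2|dᵢ|),  d = T − αP,

whose second term makes overshooting any component by more than ε
strictly worse than excluding the population — the pressure that keeps
solutions sparse. The chosen population receives weight
w = β · min(1, min_{k : r_k > 0} (t_k + ε)/r_k) and w·**r** is
subtracted from the residual. The residual is a raw difference vector
and is deliberately not renormalized. Growth stops at `max_pops`
(default 4) or as soon as the Chebyshev re-fit of the current set is
numerically exact (≤ 1e-9) — the aim is the smallest subset that
explains the data within tolerance, so there is nothing to gain from
padding an exact fit. A best-improvement swap pass then exchanges
members against all outside populations while the re-fit error
decreases by more than 1e-9.

**Phase 2 — global and local search.** The Phase-1 solution is encoded
as a vector of population indices and pooled with M (default 10)
random index vectors of the same length. DEEP evolves the padded set
(NP = 30) for G_max = 100 generations: per member, a rand/1 trial
v = q_r1 + S(q_r2 − q_r3) and a trigonometric trial
z = centroid + (φ₂−φ₁)(q_r1−q_r2) + (φ₃−φ₂)(q_r2−q_r3) + (φ₁−φ₃)(q_r3−q_r1),
with φᵢ the normalized objective magnitudes of the three donors, are
combined coordinate-wise (binomial crossover, p = 0.5) and accepted
only on strict objective decrease. Every 20 generations the 3 members
longest without an accepted update are overwritten with copies of the
current best. Index vectors live in [0, N) continuously; decoding
floors with wrap-around and repairs duplicates by advancing to the
next unused index. The objective of a decoded set is its Chebyshev
minimax error (with prior populations appended in conditional mode),
memoized per set since the landscape is piecewise constant. All trial
vectors of a generation are drawn before any evaluation, so the random
stream is independent of evaluation order and the trajectory is
bit-identical for any worker count. The M + 1 best final members are
each polished by an exhaustive single-replacement search over the
union of populations within 500 km of any member and the 10 nearest
neighbors per member in L∞ admixture distance — the step that
separates closely related neighbors (the classic Belorussian /
Russian / Ukrainian confusion).

**Phase 3 — ensemble averaging.** Populations appearing (with weight
≥ 1e-6) in at least 75% of the M + 1 refined solutions form the stable
set; their weights are averaged over the solutions containing them and
renormalized. The rest are listed as regional candidates. Averaging
over ≥ 11 solutions is what makes the report reproducible despite the
combinatorial non-uniqueness of individual solutions.

**Modes.** If the best single-population fit has error ≤ `unmixed_tol`
(default 0.02, conservative relative to the few-percent
within-population variability of admixture estimates), the individual
is reported as unmixed and the search is skipped. With priors, the
conditional fit is compared against the unconditional one: the prior is
discarded (and flagged) when it worsens the minimax error by more than
0.05, or when any forced prior ends up with mean weight below 0.01 —
with p ≤ 4 slots of headroom the optimizer can always zero out a bad
prior without degrading the fit, so the weight clause is what actually
detects contradiction. In equal-weights mode A is frozen at 1/p and
only S is optimized.

## Ancestry-group composition

Benchmark comparisons of four-way mixtures are made in the space of the
K ancestry components, not in population space: when K is small and the
panel contains several admixed populations, many different population
subsets reproduce the same test vector exactly (replacing a pure source
e_j with any full-support distractor d works whenever
j = argmax_k d_k/T_k), so the specific population set is not
identifiable — but the composition P of any exact fit is. We therefore
report `ancestry_composition`: the fitted approximation Σ aᵢ r_{s(i)}
of each ensemble solution, averaged over the M + 1 solutions. For
panels whose sources are simplex vertices this coincides with summing
population weights by group.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| ε (loss tolerance) | 0.01 | overshoot allowed before the sparsity penalty; matches the rounding scale of published admixture tables |
| α grid | 1e-4 | resolution of the affinity line search (with a 100× finer local pass) |
| β | 0.95 | safety scaling of the greedy subtraction weight; < 1 leaves headroom so one step cannot fully consume a component later populations need |
| max_pops | 4 | maximum ancestral populations — the grandparent generation |
| NP, S, p, G_max | 30, 0.9, 0.5, 100 | conventional differential-evolution settings (set size, scale, crossover, generations) |
| M | 10 | extra candidate solutions; the ensemble averages M + 1 |
| substitution period / count | 20 / 3 | age-based member replacement cadence |
| stable membership | 0.75 | ensemble fraction required to report a population |
| unmixed_tol | 0.02 | single-population L∞ error below which the query is unmixed |
| prior margin / min weight | 0.05 / 0.01 | conditional-mode contradiction tests |
| local radius / kNN | 500 km / 10 | refinement neighborhood (geographic ∪ admixture-space) |

## Synthetic data

`generate_panel` draws admixture vectors from a symmetric Dirichlet
(concentration 0.5 by default: strongly differentiated populations),
uniform coordinates over inhabited latitudes, and per-component
variances in [1e-5, 1e-3] — the scale of sampling noise on a
population mean estimated from a handful of individuals.
`simulate_mixture` implements the marriage model
T = Σ wᵢ **r**ᵢ + ε·N(0, Σ wᵢ² σ²(**r**ᵢ)) with ε ∈ {0, 0.01, 0.03,
0.05}; negative draws are clipped and the vector renormalized onto the
simplex (the model itself is silent on out-of-simplex draws, and at
these noise scales the correction is second-order). `zombie_genotypes`
samples synthetic ancestral individuals locus-wise from
Binomial(2, P(j, k)) given an L×K allele-frequency matrix.
`four_way_benchmark_panel` builds the K = 4 surrogate panels used in
the benchmark reproductions: designated sources at simplex vertices
(pure in one ancestry group), distractors predominantly of one group
(0.55 weight plus a Dirichlet remainder) placed near continental
anchor coordinates.

What the synthetic layer does *not* emulate: linkage and haplotype
structure (admixture vectors carry none), correlated errors between
components, panel misspecification (a true source absent from the
panel), and the size/geography of real curated panels (hundreds of
populations, K ≈ 9–14). Passing tests therefore demonstrate the
correctness and stability of the decomposition machinery under the
stated noise model, not field accuracy on real genotypes.

## Evaluation metrics

Per simulated case: *correct populations* (predicted stable set equals
the true source set), *at least one correct origin* (any true source
predicted), and for each true source the great-circle distance
(haversine, R = 6371 km) to the nearest predicted population; the case
counts as a *correct position* when the mean of those distances is
within 320 km, and the mean itself is the reported distance. The
multi-origin aggregation (mean of per-source nearest distances) is one
defensible reading of the 320-km rule; per-origin counting would be
another. Batch metrics are plain averages over cases.

## Numerical choices and limitations

- LP feasibility tolerance 1e-9; weights are clipped at 0 and
  renormalized after solving, and the reported minimax error is
  recomputed from the final weights so it is always consistent.
- Ties in the greedy affinity argmax break to the lowest panel index;
  swap and refinement passes use best-improvement order; DE age and
  objective ties break to the lower slot index — all for determinism.
- The affinity search is grid-based because the penalty term makes the
  loss discontinuous; derivative-based refinement is unreliable there.
- Problem sizes in the test suite (panels of 12–30 populations,
  K = 4–6, 100-case noisy batches) are chosen so the whole evaluation
  runs comfortably on a laptop-class single core while still exercising
  every phase; they are an order of magnitude below real panels.
- With max_pops = 4 and K ≤ 6 the decomposition is generically unique
  for well-separated noiseless mixtures, but near-duplicate panel rows
  (sister populations) make weights between them arbitrary; the
  ensemble reports whichever is stable and lists the rest as regional,
  which is the intended behavior, not an error.
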