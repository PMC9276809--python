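# Methods

This note records the modeling choices, algorithms and numerical
conventions behind `vaxwill`, in the order the pipeline uses them.

## Willingness dynamics

The population is an undirected, connected graph with a structural
self-loop at every node; influence weights are uniform over the
self-inclusive neighborhood, `w_ij = 1/|N_i|`, making `W` row-stochastic.
Willingness is identified with the probability `p_i(k) ∈ [0,1]` of
accepting a jab and evolves by the Friedkin–Johnsen update

    p(k+1) = Λ W p(k) + (I − Λ) p(0),

a per-agent convex combination of the neighborhood average (weight
`λ_i`, the susceptibility) and the innate probability (weight `1 − λ_i`).
Because each row of `ΛW` sums to `λ_i ≤ 1` and at least one agent has
`λ_i < 1` on a connected graph, the spectral radius of `ΛW` is below
one; the steady state `p̄ = (I − ΛW)⁻¹(I − Λ)p(0)` is computed by a
sparse LU solve of `(I − ΛW)p̄ = (I − Λ)p(0)`, never by forming the
inverse. A fixed-point iteration (∞-norm tolerance 1e-12, cap 10⁶
steps — geometric convergence makes the cap generous) serves as an
independent oracle in the tests; the two routes agree to ~1e-12 on
random instances.

Willingness `x_i` and probability `p_i` are related by an (unspecified)
linear map; since the dynamics are closed in `p`, the package never
represents `x` separately.

## Likert classes and calibration targets

A five-point willingness item maps to probability bands of width 0.2.
Class conventions, chosen so that class assignment and the retention
constraint are mutually consistent:

* bands are left-open/right-closed, `(0.2(j−1), 0.2j]`, with 0 included
  in class 1;
* classification snaps values within 1e-9 of a band edge onto it before
  applying the ceiling, so a steady state computed to sit exactly on an
  edge (which happens at the feasibility frontier) classifies stably
  under floating-point roundoff;
* the strict lower band bound of the retention constraint is closed by
  `ε = 1e-6` (numerical solvers need closed sets); class 1's lower bound
  is 0 and stays closed.

Class sizes come from the survey marginals by largest-remainder
rounding (`Σ c_j = n`, `|c_j − f_j n| < 1`, remainder ties resolved
toward the lower class index); labels are distributed by a seeded
uniform permutation, and each agent draws its target `p*_i` uniformly
in its class band. All randomness flows through
`numpy.random.default_rng` seeds, so identical seeds give bitwise
identical targets.

## The calibration program and its reduction

Calibration minimizes `‖p̄ − p*‖²` over `(λ, p(0))` subject to
`p(0) ∈ [0,1]ⁿ`, `λ ∈ [0,1]ⁿ` with `mean(λ) = ρ`, class retention for
every agent, and `p̄` being the steady state of the dynamics.

Rather than alternating between `λ`- and `p(0)`-steps, the solver uses
an exact elimination. Parameterize by the steady state `p̄` itself and
let `s = W p̄` be the neighborhood averages. Stationarity gives
`(1 − λ_i) p_i(0) = p̄_i − λ_i s_i`, so a consistent `p_i(0) ∈ [0,1]`
exists if and only if

    0 ≤ λ_i ≤ U_i(p̄) = min{ 1, (1 − p̄_i)/(1 − s_i), p̄_i/s_i },

with the ratio branches dropped where their denominators vanish. Every
constraint of the program therefore collapses to

    minimize ‖p̄ − p*‖²  over  p̄ in the (box) class bands
    subject to  Σ_i U_i(p̄) ≥ ρ n.

Consequences exploited by the implementation:

* **Fast path.** If the band-projected targets already satisfy the
  budget constraint — always the case for self-consistent targets,
  since the ground-truth `λ` is itself inside the caps — the projection
  is the identity and the objective is exactly zero.
* **Constrained projection.** Otherwise the single scalar constraint is
  handled by Lagrange-multiplier continuation: for a multiplier `μ` the
  subproblem `min ‖p̄ − p*‖² − μ Σ U_i(p̄)` over the band box is solved
  with L-BFGS-B (the cap gradient uses the active `min` branch as a
  subgradient); `μ` is doubled until the constraint holds and then
  refined by 30 bisection steps so the solution sits on the constraint
  surface. Several continuation paths are run (flat-profile start,
  caller-provided warm starts, seeded random band points — the
  `restarts` parameter) and the best feasible incumbent wins; the
  incumbent objective trace is recorded and is non-increasing by
  construction. Note `U_i = 1` exactly when `p̄_i = s_i`, so the
  susceptibility budget is maximized by profiles that are as flat as
  the bands allow — hence the flat start.
* **Recovery.** Given `p̄`, susceptibilities are chosen by water-filling
  `λ_i = min(U_i, θ)` with `θ` bisected so the mean is exactly `ρ`
  (a final affine correction on the uncapped entries makes it exact to
  machine precision), and `p(0)` follows in closed form. Water-filling
  makes the population as uniformly susceptible as the class structure
  allows; heterogeneity in `λ` then reflects network position rather
  than an arbitrary solver artifact. `U` is capped at `1 − 1e-6` to
  keep the `1/(1 − λ_i)` back-substitution well conditioned.

Feasibility is declared when every constraint residual (band after
ε-closure, `p(0)` box, mean susceptibility, steady-state consistency)
is below 1e-6; an infeasible `ρ` returns a flagged result with the
maximal violation, never an exception.

`find_max_rho` first estimates the feasibility frontier by directly
maximizing `Σ U_i(p̄)` over the bands (L-BFGS-B, multi-start), then
scans the `ρ` grid (default step 0.01, matching the two-decimal
precision such calibrations are usually reported at) downward from just
above the estimate; the returned grid value is re-verified by a full
calibration. Feasibility is monotone in `ρ` under the reduction, but
the scan does not rely on it.

## Campaigns

A campaign adds a virtual influencer with fixed probability `p_l` wired
to the targeted agents:

    p(k+1) = Λ( (I − αΔ) W p(k) + α δ p_l ) + (I − Λ) p(0),

with `δ` the 0/1 indicator, `Δ = diag(δ)`, and `α` the per-target
effort. The steady state solves the corresponding sparse linear system.
Target counts are `m = round(φn)` (half-up, deterministic) and ties in
every ranking break toward the lowest agent index, so selections are
reproducible and invariant under relabeling of the input file.

Strategy conventions:

* *degree* ranks by non-self-loop degree — self-loops are uniform
  across agents and carry no ranking information;
* *antivax-neighbors* calls an agent antivax when its baseline
  probability lies in the lowest band `[0, 0.2]`, ranks the remaining
  agents by their number of antivax neighbors, and never targets
  antivax agents themselves (if ever fewer non-antivax agents exist
  than targets required, the remainder is filled from the excluded pool
  to keep `Σδ = round(φn)`);
* *susceptibility* ranks by `λ_i`;
* *mass* wires everyone and requires `φ = 1`.

Effort sweeps use the only convention that makes `η = αφ` comparable
across campaign types: targeted strategies fix `α = 1` and vary
`φ = η`; the mass campaign fixes `φ = 1` and varies `α = η`. At
`η = 1` all four coincide exactly.

**The campaign anchor.** By campaign time the population's opinions are
taken as consolidated, so the innate anchor is reset to the calibrated
steady state, `p(0) := p̄`. A subtlety follows: under the reset anchor
the no-campaign (`α = 0`) fixed point is `(I − ΛW)⁻¹(I − Λ)p̄`, which
is not `p̄` itself (that would require `p̄` to be `W`-harmonic). The
sweep therefore measures every gain against the `α = 0` fixed point
under the anchor — the only baseline against which pro-vaccine gains
are elementwise nonnegative and anti-vaccine losses elementwise
nonpositive, by monotonicity of the campaign map in `α`. In practice
the re-anchored baseline mean differs from `mean(p̄)` by a few tenths
of a percentage point.

Reported summaries: `Δμ* = extremal_s μ_s(η) − μ_baseline` (max for
pro-vaccine, min for anti-vaccine, reported signed), `Δμ⁰` the same for
the mass campaign, and ratios `μ_s/μ_0`. The *targeted advantage*
`Δμ* − Δμ⁰` is the quantity with an interior maximum in `η` — `Δμ*`
itself is monotone in effort — and `summarize` reports its argmax.

## Outcome distributions

Vaccination decisions are independent Bernoullis, so the count is
Poisson-binomial. The pmf is computed by folding agents in one at a
time (`O(n²)` dynamic programming); all terms are nonnegative so there
is no cancellation, and the normalization and mean identity hold to
1e-12 at `n = 2000`. Exhaustive 2ⁿ enumeration (small `n`) and an
independently implemented library pmf serve as test oracles. The
variance of the vaccinated *fraction* is `Σ p_i(1 − p_i)/n² ≤ 1/(4n)`,
so the expected fraction is a reliable summary at population scale.

## Synthetic data

The generators emulate the statistical structure the analysis needs,
not any particular dataset:

* **Networks** — Erdős–Rényi (homogeneous degrees; largest connected
  component extracted and the draw retried if it covers less than 75%
  of the requested size), Barabási–Albert (heavy-tailed degrees, so
  degree targeting is genuinely different from mass targeting) and
  connected Watts–Strogatz (clustered, rewiring 0.1). Default analysis
  scale is n = 300 with mean degree 10 — large enough for a distinct
  hub structure, small enough that the full pipeline runs in seconds.
* **Survey profiles** — `hesitant-middle` `(0.06, 0.27, 0.30, 0.27,
  0.10)` is the default study condition: a mostly uncertain-to-favorable
  population with a small strongly-opposed minority, the qualitative
  shape COVID-era willingness items produced; `polarized` `(0.35, 0.12,
  0.06, 0.12, 0.35)` stresses the opposite regime; `uniform` is the
  neutral control.
* **Self-consistent fixtures** — ground-truth `λ` (mean exactly `ρ`,
  capped at 0.98) and `p(0)` (drawn in `[0.02, 0.98]`) imply a steady
  state that is nudged at least 1e-3 away from interior class edges;
  the nudge is realized by back-solving `p(0)` so the published targets
  are *exactly* a reachable steady state, guaranteeing a zero-objective
  feasible point for the calibration tests.

What synthetic data does not capture: the degree sequence, clustering
and community structure of real friendship networks, and any
correlation between opinion and network position (homophily). Passing
tests demonstrate the correctness of the machinery and the qualitative
strategy ranking on heavy-tailed graphs, not quantitative predictions
for a particular real population.

## Numerical conventions, in one place

| quantity | value |
|---|---|
| steady-state iteration tolerance (∞-norm) | 1e-12, cap 10⁶ steps |
| band ε-closure of the strict lower bound | 1e-6 |
| feasibility residual threshold | 1e-6 |
| susceptibility cap in recovery | 1 − 1e-6 |
| class-edge classification snap | 1e-9 |
| `find_max_rho` grid step | 0.01 |
| default effort grid | 0 to 1, step 0.05 |
| target count rounding | half-up; ties toward low index |

## Known limitations

* Calibration fixes only the steady state; transient (multi-snapshot)
  data, weighted or directed graphs, and time-varying campaigns are out
  of scope.
* The least-squares objective does not identify `λ` uniquely when the
  targets are exactly reachable; the water-filling rule is a declared
  convention, and other feasible `λ` profiles would change the
  susceptibility-targeting strategy's ranking.
* Bounded-confidence dynamics, private-vs-public opinions, and feedback
  from vaccination decisions onto willingness are not modeled.
* The influencer is a single static node; competing simultaneous
  campaigns are not represented.
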