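# Methods

## Model

A well-mixed population plays `n` public goods games in parallel. Each
individual is a pair `(s, i)`: a strategy `s ∈ {C, D}` and a preferred
resource `i ∈ 1..n`. Groups of `g` form uniformly at random; inside a
group, the members preferring resource `j` form that pool's subgroup. Each
cooperator in the subgroup contributes `c`; the pot is multiplied by `r_j`
and shared equally among the subgroup (cooperators and defectors alike), so
with `k_C` cooperators and `k_D` defectors a cooperator nets
`c·r_j·k_C/(k_C+k_D) − c + pi0` and a defector `c·r_j·k_C/(k_C+k_D) + pi0`,
`pi0` being a baseline income from outside the game. Reproduction is
payoff-proportional with synchronous generation replacement; offspring
mutate strategy and preference independently (rates `nu_s`, `nu_g`; a
preference mutation moves to a uniformly chosen one of the other `n−1`
resources, which for `n = 2` is the usual flip). We treat the resources as
unordered, so a cyclic "next resource" mutation scheme would impose
structure the model does not have; the uniform scheme is the only
permutation-symmetric choice.

The mechanism of interest: although `r_j < g` everywhere (a social dilemma
in every pool), the subgroup sizes fluctuate, and in subgroups smaller than
`r_j` cooperation is locally dominant. Averaged over groups this lets
per-resource cooperator payoffs exceed defector payoffs (a Simpson's-
paradox effect), producing cyclic dominance of the `2n` strategy
combinations rather than extinction of cooperators.

## Infinite-population map

The exact infinite-`N` dynamics is the discrete-time replicator-mutator
map; we implement it as the printed map (synchronous generations), not an
ODE discretization. Expected payoffs are exact double sums over the mate
composition `(n_C, n_D)` with `n_C + n_D ≤ g − 1`, with multinomial
coefficients computed through log-gamma so large `g` cannot overflow, and
`0^0 = 1` handling the degenerate (pure-state) multinomials. The
composition table is cached per `g`. After each step the state is
renormalized (the kernel is row-stochastic so drift is pure float error; a
drift above `1e-8` before renormalization raises instead of being silently
absorbed). The positivity guard `pi0 − c + c·min(r)/g > 0` is enforced at
`GameEnsemble` construction — with non-positive payoffs both the map's
denominator and fitness-proportional sampling are meaningless, so we reject
parameters rather than clip payoffs.

## Agent-based simulator

Per generation, in fixed RNG order: (1) a uniform permutation chunks the
population into `N/g` groups (so `N mod g = 0` is required and every agent
plays exactly once); (2) realized payoffs; (3) a whole new generation of
`N` parents drawn with replacement, probability proportional to payoff
(Wright-Fisher — the map above is its infinite-`N` limit, and "the new
generation replaces the old one" synchronously); (4) offspring mutations.
A single `numpy` `default_rng(seed)` drives all four stages, making runs
bit-reproducible for a fixed seed and numpy version.

## Attractor classification and phase diagrams

Trajectories settle on a defective fixed point, a cooperative fixed point,
or a periodic orbit. We classify by the amplitude (max − min) of the total
cooperator density over the final half of the trajectory: amplitude above
`osc_tol = 1e-3` means periodic orbit; otherwise the window mean above
`coop_threshold = 0.5` separates cooperative from defective fixed points.
Amplitude (rather than spectral) detection matches how the transition
behaves: approaching the cyclic-to-cooperative boundary the oscillation
amplitude shrinks continuously to zero, so "an orbit appears/disappears" is
exactly an amplitude threshold crossing. Both tolerances are exposed on the
classifier, the sweep API and the CLI. Near a bifurcation, transients decay
slowly; when a cell's amplitude lands within a factor 10 of `osc_tol` the
sweep re-runs it at twice the horizon before accepting the label.

Phase diagrams run the map from three initial-condition protocols:
*favorable* (everyone defects in resource 1 — one crowded pool plus empty
resources to escape into), *unfavorable* (defectors spread evenly), and
*homogeneous* (all `2n` densities equal). The orbit-onset boundaries
extracted per protocol are nested — favorable ≤ homogeneous ≤ unfavorable
in `r_1` at every `r_2` — with the bistable band between the favorable and
unfavorable onsets. Boundaries are reported as grid-edge midpoints, except
that an orbit already present at the left grid edge reports the edge value
itself (a midpoint does not exist there, and the nesting property needs a
total definition).

## Horizons and averaging windows

Defaults follow the study conditions the model is normally run under:
replicator horizon `T = 4000` with averages over `t = 2000..4000`;
agent-based horizon `T = 5000` with averages over the last 4000
generations; simulations at `N = 10000`. Sweeps in the test-suite and the
acceptance script use `T = 2000..3000` on 8×8 grids and a 0.5-step
diagonal — resolutions chosen so a full sweep stays desk-scale on one CPU;
at these sizes every regime (defective, bistable, cyclic, cooperative) is
resolved by multiple grid cells.

## A symmetry degeneracy worth knowing about

On the diagonal `r_1 = r_2` the homogeneous state is invariant under the
resource-swap symmetry, and the deterministic map preserves that symmetry
exactly, confining the dynamics to the symmetric subspace where the
resource-switching mechanism cannot operate. Inside the bistable band the
symmetric defective fixed point is locally stable, so the exactly
homogeneous start converges to it — e.g. at `r = (4.4, 4.4)` the map gives
a mean cooperator density of 0.008 from the homogeneous start but 0.907
from a generic (random simplex) start, which leaves the symmetric subspace
immediately. Any finite random assignment of strategies realizes the
homogeneous condition only up to `O(1/√N)` asymmetry, so finite simulations
do not show the degeneracy. Consequence: comparisons *across* the diagonal
(e.g. "cooperation is maximized when the resources have similar quality")
are made from a shared random initial state, not from the exactly symmetric
one; diagonal cells of homogeneous-start phase diagrams inherit this caveat.

## The gamma statistic

`gamma_i = ⟨rho_C^i/rho_C − rho_D^i/rho_D⟩_t` measures how much more likely
a cooperator is than a defector to prefer resource `i`; it lies in
`[−1, 1]` and is positive for lower-quality resources (the shelter effect).
Time points with `rho_C = 0` or `rho_D = 0` leave the fractions undefined
and are dropped from the average; with any positive mutation rate such
points do not occur in practice, and a fully degenerate window raises.

## What the tests do and do not show

All inputs are generated by the package itself (there is no external data),
so the test suite validates the mathematics and the implementation — exact
payoff sums against brute-force enumeration and against Monte-Carlo group
sampling, the map against a term-by-term hand computation, the simulator's
neutral-drift and mutation marginals against their binomial laws, and the
qualitative regime structure (cyclic dominance, bistability, nested
boundaries, the shelter effect, the finite-size and mutation-rate trends).
It does not, and cannot, say anything about how well the model describes
any empirical system. Known limitations: well-mixed populations only (no
spatial or network structure), synchronous generations only (no Moran-type
overlap), linear public goods payoffs, and no formal stability analysis of
the orbits — classification is purely trajectory-based.
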