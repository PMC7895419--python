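"""Finite-population agent-based simulator.

Each generation: the population of ``N`` agents is partitioned uniformly at
random into ``N/g`` groups of size ``g``; every agent's payoff is the
realized group payoff of its (strategy, resource) class within its group;
the next generation of exactly ``N`` agents is drawn by Wright-Fisher
sampling (independent fitness-proportional draws with replacement from the
whole population); finally each offspring independently mutates its strategy
with probability ``nu_s`` and its resource preference with probability
``nu_g`` (to a uniformly chosen other resource).

A single seeded generator drives everything, consumed in a fixed order per
generation — partition, parent draws, strategy mutation, game mutation — so
runs are reproducible bit-for-bit for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .model import GameEnsemble, MutationRates
from .replicator import Trajectory

__all__ = ["AgentPopulation", "abm_generation", "simulate"]


@dataclass
class AgentPopulation:
    """``N`` agents, each a (strategy, preferred-resource) pair.

    ``strategies`` holds 0 for cooperate and 1 for defect (matching the
    density-array row convention); ``games`` holds 0-based resource indices.
    ``N`` must be a multiple of the group size ``g`` so every agent plays
    exactly once per generation.
    """

    strategies: np.ndarray
    games: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.strategies = np.asarray(self.strategies, dtype=np.int64)
        self.games = np.asarray(self.games, dtype=np.int64)
        if self.strategies.shape != self.games.shape or self.strategies.ndim != 1:
            raise ValueError("strategies and games must be 1-d arrays of equal length")
        if not np.isin(self.strategies, (0, 1)).all():
            raise ValueError("strategies must be 0 (C) or 1 (D)")
        if ((self.games < 0) | (self.games >= self.n)).any():
            raise ValueError(f"game indices must lie in 0..{self.n - 1}")

    @property
    def N(self) -> int:
        return self.strategies.size

    def densities(self) -> np.ndarray:
        """Empirical (2, n) density array (counts / N)."""
        code = self.strategies * self.n + self.games
        counts = np.bincount(code, minlength=2 * self.n)
        return counts.reshape(2, self.n) / self.N

    @classmethod
    def from_densities(
        cls, rho: np.ndarray, N: int, rng: np.random.Generator, n: Optional[int] = None
    ) -> "AgentPopulation":
        """Draw ``N`` agents iid from a density spec (must sum to 1)."""
        rho = np.asarray(rho, dtype=float)
        if n is None:
            n = rho.shape[1]
        if abs(rho.sum() - 1.0) > 1e-8 or (rho < 0).any():
            raise ValueError("density spec must be non-negative and sum to 1")
        counts = rng.multinomial(N, rho.ravel() / rho.sum())
        code = np.repeat(np.arange(2 * n), counts)
        return cls(strategies=code // n, games=code % n, n=n)


def _check_sizes(N: int, g: int) -> None:
    if N < g or N % g != 0:
        raise ValueError(f"population size N={N} must be a positive multiple of g={g}")


def _payoffs(pop: AgentPopulation, ens: GameEnsemble, rng: np.random.Generator) -> np.ndarray:
    """Random partition into groups of g, then realized payoff per agent."""
    N, g, n = pop.N, ens.g, ens.n
    perm = rng.permutation(N)
    group = np.empty(N, dtype=np.int64)
    group[perm] = np.arange(N) // g  # agents perm[k*g:(k+1)*g] form group k
    n_groups = N // g
    code = pop.strategies * n + pop.games
    counts = np.bincount(group * (2 * n) + code, minlength=n_groups * 2 * n)
    counts = counts.reshape(n_groups, 2, n)
    kC = counts[group, 0, pop.games].astype(float)
    kD = counts[group, 1, pop.games].astype(float)
    share = ens.c * np.asarray(ens.r)[pop.games] * kC / (kC + kD)
    pay = share + ens.pi0 - ens.c * (pop.strategies == 0)
    if (pay <= 0).any():
        raise RuntimeError("non-positive payoff encountered")  # excluded by the guard
    return pay


def abm_generation(
    pop: AgentPopulation,
    ens: GameEnsemble,
    rates: MutationRates,
    rng: np.random.Generator,
) -> AgentPopulation:
    """One synchronous generation: group play, Wright-Fisher reproduction, mutation."""
    _check_sizes(pop.N, ens.g)
    if pop.n != ens.n:
        raise ValueError("population and ensemble disagree on the number of resources")
    pay = _payoffs(pop, ens, rng)
    parents = rng.choice(pop.N, size=pop.N, replace=True, p=pay / pay.sum())
    strategies = pop.strategies[parents]
    games = pop.games[parents]
    flip = rng.random(pop.N) < rates.nu_s
    strategies = np.where(flip, 1 - strategies, strategies)
    if ens.n > 1:
        move = rng.random(pop.N) < rates.nu_g
        pick = rng.integers(0, ens.n - 1, size=pop.N)
        new_games = pick + (pick >= games)  # uniform over the other n-1 resources
        games = np.where(move, new_games, games)
    return AgentPopulation(strategies=strategies, games=games, n=pop.n)


def simulate(
    init: Union[AgentPopulation, np.ndarray],
    ens: GameEnsemble,
    rates: MutationRates,
    T: int,
    seed: int,
    N: Optional[int] = None,
) -> Trajectory:
    """Run the simulator for ``T`` generations and record empirical densities.

    ``init`` is either an :class:`AgentPopulation` or a ``(2, n)`` density
    spec (then ``N`` is required and the initial population is drawn from
    it).  Returns a :class:`~pggchoice.replicator.Trajectory` with
    provenance ``{"engine": "abm", "N": N, "seed": seed}``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    rng = np.random.default_rng(seed)
    if not isinstance(init, AgentPopulation):
        if N is None:
            raise ValueError("N is required when initializing from a density spec")
        init = AgentPopulation.from_densities(np.asarray(init), N, rng, n=ens.n)
    _check_sizes(init.N, ens.g)
    states = np.empty((T + 1, 2, ens.n))
    states[0] = init.densities()
    pop = init
    for t in range(T):
        pop = abm_generation(pop, ens, rates, rng)
        states[t + 1] = pop.densities()
    return Trajectory(
        states, ens, rates, provenance={"engine": "abm", "N": pop.N, "seed": seed}
    )
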