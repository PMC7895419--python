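"""Core model primitives: parameters, mutation kernel, and payoffs.

The model is a public goods game (PGG) in which every individual carries a
strategy (cooperate ``C`` or defect ``D``) *and* a preferred public resource
``i`` in ``1..n``.  Groups of ``g`` players form at random; within a group,
only the members who prefer the same resource ``j`` share a pool.  Each
cooperator in that subgroup contributes ``c``, the pool is multiplied by the
resource's enhancement factor ``r_j`` and split equally among the subgroup's
members, and everyone additionally receives a base payoff ``pi0`` from
activities outside the game.

Internally, densities and payoffs over the ``2n`` strategy combinations are
stored as ``(2, n)`` arrays with row 0 = cooperators and row 1 = defectors;
flattened ordering is ``C^1 .. C^n, D^1 .. D^n``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GameEnsemble",
    "MutationRates",
    "StrategyGame",
    "GroupComposition",
    "mutation_kernel",
    "group_payoffs",
    "expected_payoff",
    "expected_payoffs",
]

#: row index of cooperators / defectors in (2, n) density and payoff arrays
COOPERATE, DEFECT = 0, 1


@dataclass(frozen=True)
class GameEnsemble:
    """The ``n`` public resources and the group game played on them.

    Parameters
    ----------
    n : int
        Number of public resources (>= 1).
    r : tuple of float
        Enhancement factors ``r_1 .. r_n`` (dimensionless, > 0).  A social
        dilemma exists in resource ``j`` when ``r_j`` is below the number of
        players sharing its pool.
    g : int
        Group size (>= 2).
    c : float
        Contribution cost, in payoff units (default 1).
    pi0 : float
        Base payoff every individual receives regardless of the game
        (default 1).

    Construction enforces the positivity guard ``pi0 - c + c*min(r)/g > 0``:
    the worst-case cooperator payoff (alone against ``g - 1`` defectors in
    the poorest resource) must be strictly positive, otherwise
    fitness-proportional reproduction and the replicator map's denominator
    are ill-defined.
    """

    n: int
    r: tuple[float, ...]
    g: int
    c: float = 1.0
    pi0: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", tuple(float(v) for v in np.atleast_1d(self.r)))
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if len(self.r) != self.n:
            raise ValueError(f"expected {self.n} enhancement factors, got {len(self.r)}")
        if self.g < 2:
            raise ValueError(f"group size g must be >= 2, got {self.g}")
        if self.c <= 0:
            raise ValueError(f"contribution cost c must be > 0, got {self.c}")
        if self.pi0 < 0:
            raise ValueError(f"base payoff pi0 must be >= 0, got {self.pi0}")
        if any(ri <= 0 for ri in self.r):
            raise ValueError(f"all enhancement factors must be > 0, got {self.r}")
        worst = self.pi0 - self.c + self.c * min(self.r) / self.g
        if worst <= 0:
            raise ValueError(
                "positivity guard violated: pi0 - c + c*min(r)/g = "
                f"{worst:g} must be > 0 so all payoffs stay positive"
            )

    @property
    def r_array(self) -> np.ndarray:
        return np.asarray(self.r, dtype=float)

    def to_dict(self) -> dict:
        """Flat mapping with keys n, r, g, c, pi0 (round-trips bit-exactly)."""
        return {"n": self.n, "r": list(self.r), "g": self.g, "c": self.c, "pi0": self.pi0}

    @classmethod
    def from_dict(cls, d: dict) -> "GameEnsemble":
        return cls(n=int(d["n"]), r=tuple(d["r"]), g=int(d["g"]),
                   c=float(d.get("c", 1.0)), pi0=float(d.get("pi0", 1.0)))


@dataclass(frozen=True)
class MutationRates:
    """Per-reproduction mutation probabilities.

    ``nu_s`` flips the offspring's strategy; ``nu_g`` moves its resource
    preference to a uniformly chosen one of the other ``n - 1`` resources.
    The two mutations are independent.
    """

    nu_s: float
    nu_g: float

    def __post_init__(self) -> None:
        for name, v in (("nu_s", self.nu_s), ("nu_g", self.nu_g)):
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    @classmethod
    def symmetric(cls, nu: float) -> "MutationRates":
        """The common setting nu_s = nu_g = nu."""
        return cls(nu_s=nu, nu_g=nu)

    def to_dict(self) -> dict:
        return {"nu_s": self.nu_s, "nu_g": self.nu_g}

    @classmethod
    def from_dict(cls, d: dict) -> "MutationRates":
        return cls(nu_s=float(d["nu_s"]), nu_g=float(d["nu_g"]))


@dataclass(frozen=True)
class StrategyGame:
    """A strategy combination: ``C`` or ``D`` plus a preferred resource in 1..n."""

    strategy: str
    game: int

    def __post_init__(self) -> None:
        if self.strategy not in ("C", "D"):
            raise ValueError(f"strategy must be 'C' or 'D', got {self.strategy!r}")
        if self.game < 1:
            raise ValueError(f"game index must be >= 1, got {self.game}")

    @property
    def strategy_index(self) -> int:
        return COOPERATE if self.strategy == "C" else DEFECT


@dataclass(frozen=True)
class GroupComposition:
    """Counts ``(k_C^j, k_D^j)`` of cooperators/defectors per resource in one group.

    ``counts`` is a ``(2, n)`` integer array (row 0 cooperators); the total
    must equal the group size it is evaluated against.
    """

    counts: np.ndarray = field()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != 2:
            raise ValueError(f"counts must have shape (2, n), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def size(self) -> int:
        return int(self.counts.sum())


def mutation_kernel(rates: MutationRates, n: int) -> np.ndarray:
    """Row-stochastic transition matrix over the ``2n`` strategy combinations.

    Entry ``[a, b]`` is the probability that the offspring of a parent with
    flattened combination ``a`` ends up with combination ``b``: the strategy
    flips with probability ``nu_s`` and, independently, the preference moves
    to a uniformly chosen one of the other ``n - 1`` resources with
    probability ``nu_g``.  For ``n = 1`` there is no other resource and game
    mutation is a no-op (a warning is logged if ``nu_g > 0``).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    strat = np.array(
        [[1.0 - rates.nu_s, rates.nu_s], [rates.nu_s, 1.0 - rates.nu_s]]
    )
    if n == 1:
        if rates.nu_g > 0:
            logger.warning(
                "n = 1: game-preference mutation rate nu_g=%g is ignored "
                "(no other resource exists)", rates.nu_g,
            )
        game = np.ones((1, 1))
    else:
        game = np.full((n, n), rates.nu_g / (n - 1))
        np.fill_diagonal(game, 1.0 - rates.nu_g)
    return np.kron(strat, game)


def group_payoffs(comp: GroupComposition, ens: GameEnsemble) -> np.ndarray:
    """Realized payoff of each (strategy, resource) member class in one group.

    Within the resource-``j`` subgroup of ``k_C`` cooperators and ``k_D``
    defectors, a cooperator earns ``c*r_j*k_C/(k_C + k_D) - c + pi0`` and a
    defector ``c*r_j*k_C/(k_C + k_D) + pi0``.  Returns a ``(2, n)`` array;
    entries for absent member classes are NaN ("no entries").
    """
    if comp.counts.shape[1] != ens.n:
        raise ValueError(f"composition has {comp.counts.shape[1]} resources, ensemble has {ens.n}")
    if comp.size != ens.g:
        raise ValueError(f"composition sums to {comp.size}, group size is {ens.g}")
    kC = comp.counts[COOPERATE].astype(float)
    kD = comp.counts[DEFECT].astype(float)
    size = kC + kD
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(size > 0, ens.c * ens.r_array * kC / np.maximum(size, 1), np.nan)
    out = np.empty((2, ens.n))
    out[COOPERATE] = share - ens.c + ens.pi0
    out[DEFECT] = share + ens.pi0
    out[comp.counts == 0] = np.nan
    return out


@lru_cache(maxsize=32)
def _composition_table(g: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All mate compositions ``(nC, nD)`` with ``nC + nD <= g - 1`` and the
    log multinomial coefficient ``log (g-1 choose nC, nD, rest)``."""
    nC, nD = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    mask = nC + nD <= g - 1
    nC, nD = nC[mask], nD[mask]
    rest = g - 1 - nC - nD
    logcoef = gammaln(g) - gammaln(nC + 1) - gammaln(nD + 1) - gammaln(rest + 1)
    return nC.astype(float), nD.astype(float), logcoef


def expected_payoffs(rho: np.ndarray, ens: GameEnsemble) -> np.ndarray:
    """Exact expected payoffs ``pi_x^j`` for all ``2n`` combinations.

    For a focal individual preferring resource ``j``, the ``g - 1`` group
    mates are iid draws from the population state, so the number of mates
    that cooperate in ``j`` (``nC``) and defect in ``j`` (``nD``) is
    multinomial.  The expectation is the exact double sum

    ``pi_C^j = sum_{nC,nD} c*r_j*(1+nC)/(1+nC+nD) * P(nC,nD) - c + pi0``
    ``pi_D^j = sum_{nC,nD} c*r_j*nC/(1+nC+nD) * P(nC,nD) + pi0``

    with ``P(nC, nD)`` the multinomial probability with cell probabilities
    ``(rho_C^j, rho_D^j, 1 - rho^j)``.  Multinomial coefficients are
    evaluated through log-gamma so large ``g`` cannot overflow.

    Parameters
    ----------
    rho : (2, n) array
        Population densities (must lie on the simplex; not re-validated
        here — hot path).

    Returns
    -------
    (2, n) array of payoffs, all > 0 under the ensemble's positivity guard.
    """
    rho = np.asarray(rho, dtype=float)
    nC, nD, logcoef = _composition_table(ens.g)
    rest = ens.g - 1 - nC - nD
    rhoC = rho[COOPERATE][:, None]  # (n, 1)
    rhoD = rho[DEFECT][:, None]
    other = np.clip(1.0 - rhoC - rhoD, 0.0, 1.0)
    # np.power gives 0**0 == 1, exactly the degenerate-multinomial convention
    probs = np.exp(logcoef) * rhoC**nC * rhoD**nD * other**rest  # (n, m)
    size = 1.0 + nC + nD
    base = ens.c * ens.r_array[:, None] * probs / size
    piC = (base * (1.0 + nC)).sum(axis=1) - ens.c + ens.pi0
    piD = (base * nC).sum(axis=1) + ens.pi0
    return np.stack([piC, piD])


def expected_payoff(state, who: StrategyGame, ens: GameEnsemble) -> float:
    """Expected payoff of one strategy combination at a population state.

    ``state`` may be a :class:`~pggchoice.replicator.PopulationState` or a
    ``(2, n)`` density array; it is validated against the simplex.
    """
    rho = np.asarray(getattr(state, "rho", state), dtype=float)
    if rho.shape != (2, ens.n):
        raise ValueError(f"state must have shape (2, {ens.n}), got {rho.shape}")
    if (rho < -1e-10).any() or abs(rho.sum() - 1.0) > 1e-8:
        raise ValueError("state is off the simplex")
    if not 1 <= who.game <= ens.n:
        raise ValueError(f"game index {who.game} outside 1..{ens.n}")
    return float(expected_payoffs(rho, ens)[who.strategy_index, who.game - 1])
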