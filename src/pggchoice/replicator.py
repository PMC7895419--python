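"""Infinite-population replicator-mutator map and trajectory container.

The exact dynamics in the infinite-population limit is a discrete-time map:
each strategy combination's density grows in proportion to its expected
payoff and is then redistributed by the mutation kernel,

    rho_x^i(t+1) = sum_{y,j} K[(y,j) -> (x,i)] rho_y^j(t) pi_y^j(t) / Z(t),

where ``Z(t)`` is the population's mean payoff.  The map is synchronous
(whole-generation replacement), matching the agent-based simulator's
Wright-Fisher reproduction of which it is the N -> infinity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import GameEnsemble, MutationRates, expected_payoffs, mutation_kernel

__all__ = ["PopulationState", "Trajectory", "replicator_step", "iterate"]

_SIMPLEX_TOL = 1e-10
_DRIFT_TOL = 1e-8


@dataclass(frozen=True)
class PopulationState:
    """A point on the ``2n``-simplex of strategy-combination densities.

    ``rho`` has shape ``(2, n)``: row 0 holds cooperator densities
    ``rho_C^i``, row 1 defector densities ``rho_D^i``.
    """

    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 2 or rho.shape[0] != 2:
            raise ValueError(f"rho must have shape (2, n), got {rho.shape}")
        if (rho < -_SIMPLEX_TOL).any() or (rho > 1 + _SIMPLEX_TOL).any():
            raise ValueError("densities must lie in [0, 1]")
        if abs(rho.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"densities must sum to 1, got {rho.sum()!r}")
        object.__setattr__(self, "rho", rho)

    @property
    def n(self) -> int:
        return self.rho.shape[1]

    @property
    def rho_C(self) -> float:
        """Total cooperator density ``sum_i rho_C^i``."""
        return float(self.rho[0].sum())

    @property
    def rho_D(self) -> float:
        return 1.0 - self.rho_C

    @property
    def resource_density(self) -> np.ndarray:
        """Per-resource occupancy ``rho^i = rho_C^i + rho_D^i``."""
        return self.rho.sum(axis=0)


@dataclass
class Trajectory:
    """A time series of population states plus the parameters that made it.

    ``states`` has shape ``(T + 1, 2, n)`` (state 0 is the initial
    condition).  ``provenance`` records the engine (``"replicator"`` or
    ``"abm"``, the latter with ``N`` and ``seed``).
    """

    states: np.ndarray
    ensemble: GameEnsemble
    rates: MutationRates
    provenance: dict = field(default_factory=lambda: {"engine": "replicator"})

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        if states.ndim != 3 or states.shape[1] != 2:
            raise ValueError(f"states must have shape (T+1, 2, n), got {states.shape}")
        if states.shape[2] != self.ensemble.n:
            raise ValueError("trajectory width does not match ensemble.n")
        sums = states.sum(axis=(1, 2))
        if (states < -1e-9).any() or np.abs(sums - 1.0).max() > 1e-8:
            raise ValueError("trajectory states must lie on the simplex")
        self.states = states

    @property
    def T(self) -> int:
        """Number of steps (length is ``T + 1`` states)."""
        return self.states.shape[0] - 1

    @property
    def n(self) -> int:
        return self.states.shape[2]

    @property
    def rho_C(self) -> np.ndarray:
        """Series of total cooperator density, length ``T + 1``."""
        return self.states[:, 0, :].sum(axis=1)

    @property
    def resource_density(self) -> np.ndarray:
        """Series of per-resource occupancy, shape ``(T + 1, n)``."""
        return self.states.sum(axis=1)

    def state(self, t: int) -> PopulationState:
        return PopulationState(self.states[t])


def replicator_step(
    state: PopulationState | np.ndarray,
    ens: GameEnsemble,
    kernel: np.ndarray,
) -> PopulationState:
    """One synchronous generation of the replicator-mutator map."""
    rho = np.asarray(getattr(state, "rho", state), dtype=float)
    new = _step_raw(rho, ens, kernel)
    return PopulationState(new)

def _step_raw(rho: np.ndarray, ens: GameEnsemble, kernel: np.ndarray) -> np.ndarray:
    pi = expected_payoffs(rho, ens)
    w = (rho * pi).ravel()
    z = w.sum()
    if z <= 0:
        raise ValueError("mean payoff is non-positive; replicator map undefined")
    new = (w @ kernel) / z
    total = new.sum()
    if abs(total - 1.0) > _DRIFT_TOL:
        raise FloatingPointError(f"simplex drift {total - 1.0:g} exceeds {_DRIFT_TOL:g}")
    return (new / total).reshape(rho.shape)


def iterate(
    state0: PopulationState | np.ndarray,
    T: int,
    ens: GameEnsemble,
    rates: MutationRates,
    kernel: Optional[np.ndarray] = None,
) -> Trajectory:
    """Iterate the map for ``T`` steps; deterministic given its inputs."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    rho = np.asarray(getattr(state0, "rho", state0), dtype=float)
    PopulationState(rho)  # validate once; the inner loop conserves the simplex
    if kernel is None:
        kernel = mutation_kernel(rates, ens.n)
    out = np.empty((T + 1,) + rho.shape)
    out[0] = rho
    for t in range(T):
        rho = _step_raw(rho, ens, kernel)
        out[t + 1] = rho
    return Trajectory(out, ens, rates, provenance={"engine": "replicator"})
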