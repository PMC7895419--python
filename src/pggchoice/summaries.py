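"""Time-averaged observables of a trajectory.

Covers the cooperation level (window mean of the total cooperator density),
the per-resource occupancy matrix, and the preference differential

    gamma_i = < rho_C^i / rho_C  -  rho_D^i / rho_D >_t,

the time-averaged difference between the fraction of cooperators and the
fraction of defectors preferring resource ``i``.  A positive gamma means
cooperators disproportionately occupy that resource — the signature of the
shelter effect, where defectors crowd the highest-quality resource and
cooperators assort into a lower-quality one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .replicator import Trajectory

__all__ = [
    "SummaryStats",
    "default_window",
    "cooperation_level",
    "gamma_statistic",
    "preference_occupancy",
    "summarize",
]


def default_window(traj: Trajectory) -> tuple[int, int]:
    """The standard averaging interval for each engine.

    Replicator runs average the last half of the trajectory (t = T/2..T);
    agent-based runs average the last four fifths (generations T/5..T).
    """
    if traj.provenance.get("engine") == "abm":
        return (traj.T - (traj.T * 4) // 5, traj.T)
    return (traj.T - traj.T // 2, traj.T)


def _resolve(traj: Trajectory, window) -> tuple[int, int]:
    t0, t1 = default_window(traj) if window is None else (int(window[0]), int(window[1]))
    if not (0 <= t0 < t1 <= traj.T):
        raise ValueError(f"window ({t0}, {t1}) not inside trajectory 0..{traj.T}")
    return t0, t1


def cooperation_level(traj: Trajectory, window=None) -> float:
    """Arithmetic mean of the total cooperator density over the window."""
    t0, t1 = _resolve(traj, window)
    return float(traj.rho_C[t0 : t1 + 1].mean())


def preference_occupancy(traj: Trajectory, window=None) -> np.ndarray:
    """Per-class time averages ``<rho_x^i>_t`` as a ``(2, n)`` matrix.

    The cooperator row sums to ``cooperation_level`` exactly.
    """
    t0, t1 = _resolve(traj, window)
    return traj.states[t0 : t1 + 1].mean(axis=0)


def gamma_statistic(traj: Trajectory, resource: int = 1, window=None) -> float:
    """Time-averaged preference differential for one resource (1-based index).

    Time points where the population holds no cooperators (or no defectors)
    leave the fractions undefined and are excluded from the average; with
    mutation switched on such points essentially never occur.
    """
    if not 1 <= resource <= traj.n:
        raise ValueError(f"resource {resource} outside 1..{traj.n}")
    t0, t1 = _resolve(traj, window)
    states = traj.states[t0 : t1 + 1]
    rhoC = states[:, 0, :].sum(axis=1)
    rhoD = states[:, 1, :].sum(axis=1)
    ok = (rhoC > 0) & (rhoD > 0)
    if not ok.any():
        raise ValueError("every time point in the window is degenerate (rho_C or rho_D = 0)")
    i = resource - 1
    diff = states[ok, 0, i] / rhoC[ok] - states[ok, 1, i] / rhoD[ok]
    return float(diff.mean())


@dataclass(frozen=True)
class SummaryStats:
    """Windowed averages of one run: cooperation level, occupancy, gamma."""

    mean_rhoC: float
    mean_rho_xi: np.ndarray  # (2, n) time-averaged densities
    gamma: float             # preference differential for `gamma_resource`
    gamma_resource: int
    window: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "mean_rhoC": self.mean_rhoC,
            "mean_rho_xi": np.asarray(self.mean_rho_xi).tolist(),
            "gamma": self.gamma,
            "gamma_resource": self.gamma_resource,
            "window": list(self.window),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize(traj: Trajectory, window=None, gamma_resource: int = 1) -> SummaryStats:
    """All windowed observables of a run in one object."""
    t0, t1 = _resolve(traj, window)
    occ = preference_occupancy(traj, (t0, t1))
    try:
        gamma = gamma_statistic(traj, gamma_resource, (t0, t1))
    except ValueError:
        gamma = float("nan")  # fully degenerate window (e.g. all-defector run)
    return SummaryStats(
        mean_rhoC=float(occ[0].sum()),
        mean_rho_xi=occ,
        gamma=gamma,
        gamma_resource=gamma_resource,
        window=(t0, t1),
    )
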