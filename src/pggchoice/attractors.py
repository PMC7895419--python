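"""Initial-condition protocols, attractor classification, phase diagrams.

The long-run behavior of the replicator-mutator map falls into three
regimes: a defective fixed point (defectors dominate), a cooperative fixed
point (cooperators dominate, reached when enhancement factors are large),
and a periodic orbit on which the strategy combinations cyclically dominate.
For intermediate enhancement factors the defective fixed point and the
periodic orbit coexist (bistability) and the initial condition selects
between them, which is why phase boundaries are traced from three distinct
initial-condition protocols.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GameEnsemble, MutationRates, mutation_kernel
from .replicator import PopulationState, Trajectory, iterate

logger = logging.getLogger(__name__)

__all__ = [
    "Attractor",
    "AttractorReport",
    "PhaseDiagram",
    "initial_condition",
    "classify_attractor",
    "phase_diagram",
    "PROTOCOLS",
]

#: default amplitude above which the analysis window is called oscillatory
OSC_TOL = 1e-3
#: default mean cooperator density separating cooperative from defective FPs
COOP_THRESHOLD = 0.5

PROTOCOLS = ("homogeneous", "favorable", "unfavorable", "random")


class Attractor(str, enum.Enum):
    DEFECTIVE_FP = "DEFECTIVE_FP"
    COOPERATIVE_FP = "COOPERATIVE_FP"
    PERIODIC_ORBIT = "PERIODIC_ORBIT"


@dataclass(frozen=True)
class AttractorReport:
    """Classification of a trajectory's tail plus its diagnostics."""

    label: Attractor
    amplitude: float       # max - min of rho_C over the window
    mean_rhoC: float
    window: tuple[int, int]


def initial_condition(
    protocol: str, n: int, seed: Optional[int] = None
) -> PopulationState:
    """Named starting states used to trace phase boundaries.

    - ``homogeneous``: all ``2n`` densities equal (the unbiased start).
    - ``favorable``: everyone defects in resource 1 (``rho_D^1 = 1``) — the
      start most favorable to cooperation, since the whole population shares
      one pool and cooperator mutants assort into the empty resources.
    - ``unfavorable``: all defectors, spread evenly over the resources
      (``rho_D^i = 1/n``) — the start least favorable to cooperation.
    - ``random``: a seeded uniform (flat Dirichlet) draw on the simplex.
    """
    rho = np.zeros((2, n))
    if protocol == "homogeneous":
        rho[:] = 1.0 / (2 * n)
    elif protocol == "favorable":
        rho[1, 0] = 1.0
    elif protocol == "unfavorable":
        rho[1, :] = 1.0 / n
    elif protocol == "random":
        rng = np.random.default_rng(seed)
        rho = rng.dirichlet(np.ones(2 * n)).reshape(2, n)
    else:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    return PopulationState(rho)


def classify_attractor(
    traj: Trajectory,
    window: float = 0.5,
    osc_tol: float = OSC_TOL,
    coop_threshold: float = COOP_THRESHOLD,
) -> AttractorReport:
    """Classify the trajectory's tail as a fixed point or a periodic orbit.

    Over the final ``window`` fraction of the trajectory the amplitude
    ``max - min`` of the total cooperator density is measured; an amplitude
    above ``osc_tol`` is a periodic orbit, otherwise a fixed point, called
    cooperative when the window-mean cooperator density exceeds
    ``coop_threshold`` and defective otherwise.  The window must contain at
    least 100 steps so one oscillation period cannot be missed.
    """
    if not 0 < window <= 1:
        raise ValueError(f"window must be a fraction in (0, 1], got {window}")
    t_start = int(np.ceil(traj.T * (1 - window)))
    t_end = traj.T
    if t_end - t_start < 100:
        raise ValueError(
            f"analysis window [{t_start}, {t_end}] has fewer than 100 steps"
        )
    tail = traj.rho_C[t_start : t_end + 1]
    amplitude = float(tail.max() - tail.min())
    mean = float(tail.mean())
    if amplitude > osc_tol:
        label = Attractor.PERIODIC_ORBIT
    elif mean > coop_threshold:
        label = Attractor.COOPERATIVE_FP
    else:
        label = Attractor.DEFECTIVE_FP
    return AttractorReport(label=label, amplitude=amplitude, mean_rhoC=mean,
                           window=(t_start, t_end))


@dataclass
class PhaseDiagram:
    """Attractor labels over an ``(r_1, r_2)`` grid, per initial-condition protocol.

    ``labels[p]`` etc. are ``(len(r2_grid), len(r1_grid))`` arrays indexed
    ``[i2, i1]``.
    """

    r1_grid: np.ndarray
    r2_grid: np.ndarray
    protocols: tuple[str, ...]
    labels: dict[str, np.ndarray]
    amplitude: dict[str, np.ndarray]
    mean_rhoC: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (r1, r2, protocol)."""
        rows = []
        for p in self.protocols:
            for i2, r2 in enumerate(self.r2_grid):
                for i1, r1 in enumerate(self.r1_grid):
                    rows.append(
                        {"r1": float(r1), "r2": float(r2), "protocol": p,
                         "label": str(self.labels[p][i2, i1]),
                         "amplitude": float(self.amplitude[p][i2, i1]),
                         "mean_rhoC": float(self.mean_rhoC[p][i2, i1])}
                    )
        return pd.DataFrame(rows)

    def po_onset(self, protocol: str) -> list[Optional[float]]:
        """Per ``r_2`` row, the ``r_1`` value where the periodic orbit first
        appears scanning ``r_1`` upward: the grid-edge midpoint before the
        first PO cell, the left grid edge if the orbit is already present
        there, or None if the row never oscillates."""
        out: list[Optional[float]] = []
        grid = self.labels[protocol]
        for i2 in range(len(self.r2_grid)):
            row = grid[i2]
            hits = np.nonzero(row == Attractor.PERIODIC_ORBIT.value)[0]
            if hits.size == 0:
                out.append(None)
            elif hits[0] == 0:
                out.append(float(self.r1_grid[0]))
            else:
                i1 = int(hits[0])
                out.append(float((self.r1_grid[i1 - 1] + self.r1_grid[i1]) / 2))
        return out

    def boundary_points(self, protocol: str) -> list[tuple[float, float]]:
        """Midpoints of grid edges separating cells with different labels."""
        grid = self.labels[protocol]
        pts = []
        for i2 in range(len(self.r2_grid)):
            for i1 in range(1, len(self.r1_grid)):
                if grid[i2, i1] != grid[i2, i1 - 1]:
                    pts.append((float((self.r1_grid[i1 - 1] + self.r1_grid[i1]) / 2),
                                float(self.r2_grid[i2])))
        for i1 in range(len(self.r1_grid)):
            for i2 in range(1, len(self.r2_grid)):
                if grid[i2, i1] != grid[i2 - 1, i1]:
                    pts.append((float(self.r1_grid[i1]),
                                float((self.r2_grid[i2 - 1] + self.r2_grid[i2]) / 2)))
        return pts

    def po_area(self, protocol: str) -> int:
        """Number of grid cells labeled periodic orbit (grid-cell area proxy)."""
        return int((self.labels[protocol] == Attractor.PERIODIC_ORBIT.value).sum())

    def boundaries(self) -> dict:
        """JSON-ready summary of the extracted transition curves."""
        return {
            "po_onset_r1_by_r2": {
                p: dict(zip(map(float, self.r2_grid), self.po_onset(p)))
                for p in self.protocols
            },
            "boundary_points": {p: self.boundary_points(p) for p in self.protocols},
        }


def phase_diagram(
    r1_grid: Sequence[float],
    r2_grid: Sequence[float],
    ens_template: GameEnsemble,
    rates: MutationRates,
    protocols: Sequence[str] = ("homogeneous", "favorable", "unfavorable"),
    T: int = 4000,
    window: float = 0.5,
    osc_tol: float = OSC_TOL,
    coop_threshold: float = COOP_THRESHOLD,
    refine: bool = True,
    seed: Optional[int] = None,
) -> PhaseDiagram:
    """Run the replicator map over an ``(r_1, r_2)`` grid and classify each cell.

    ``ens_template`` supplies ``g``, ``c``, ``pi0`` and, for ``n >= 3``, the
    fixed enhancement factors ``r_3..r_n``; only ``r_1`` and ``r_2`` vary.
    With ``refine=True``, a cell whose amplitude lands within a factor 10 of
    ``osc_tol`` (either side) is re-run at ``2 T`` so slow transients near a
    bifurcation do not misclassify it.
    """
    r1_grid = np.asarray(r1_grid, dtype=float)
    r2_grid = np.asarray(r2_grid, dtype=float)
    if r1_grid.size == 0 or r2_grid.size == 0:
        raise ValueError("grids must be non-empty")
    kernel = mutation_kernel(rates, ens_template.n)
    labels = {p: np.empty((r2_grid.size, r1_grid.size), dtype=object) for p in protocols}
    amplitude = {p: np.empty((r2_grid.size, r1_grid.size)) for p in protocols}
    mean_rhoC = {p: np.empty((r2_grid.size, r1_grid.size)) for p in protocols}
    for p in protocols:
        init = initial_condition(p, ens_template.n, seed=seed)
        for i2, r2 in enumerate(r2_grid):
            for i1, r1 in enumerate(r1_grid):
                r = (float(r1), float(r2)) + ens_template.r[2:]
                try:
                    ens = GameEnsemble(n=ens_template.n, r=r, g=ens_template.g,
                                       c=ens_template.c, pi0=ens_template.pi0)
                    traj = iterate(init, T, ens, rates, kernel=kernel)
                    rep = classify_attractor(traj, window, osc_tol, coop_threshold)
                    if refine and osc_tol / 10 < rep.amplitude < osc_tol * 10:
                        traj = iterate(init, 2 * T, ens, rates, kernel=kernel)
                        rep = classify_attractor(traj, window, osc_tol, coop_threshold)
                except (ValueError, FloatingPointError) as exc:
                    # record the failed cell and keep sweeping
                    logger.warning("cell (r1=%g, r2=%g, %s) failed: %s", r1, r2, p, exc)
                    labels[p][i2, i1] = "ERROR"
                    amplitude[p][i2, i1] = np.nan
                    mean_rhoC[p][i2, i1] = np.nan
                    continue
                labels[p][i2, i1] = rep.label.value
                amplitude[p][i2, i1] = rep.amplitude
                mean_rhoC[p][i2, i1] = rep.mean_rhoC
    return PhaseDiagram(r1_grid=r1_grid, r2_grid=r2_grid, protocols=tuple(protocols),
                        labels=labels, amplitude=amplitude, mean_rhoC=mean_rhoC)
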