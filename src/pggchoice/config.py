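"""Run configuration, single runs, and grid sweeps.

A :class:`RunConfig` fully specifies one computation: the game parameters,
the engine (exact replicator map or finite-population simulator), the
horizon, the initial condition and the analysis settings.  ``run`` executes
it and writes trajectory.csv, summary.json, report.json and manifest.json;
``sweep`` drives :func:`pggchoice.attractors.phase_diagram` over an
``(r_1, r_2)`` grid and writes a long-format CSV plus a boundary summary.
Outputs are written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .abm import simulate
from .attractors import (COOP_THRESHOLD, OSC_TOL, PROTOCOLS, classify_attractor,
                         initial_condition, phase_diagram)
from .io import write_phase_diagram, write_trajectory_csv
from .model import GameEnsemble, MutationRates
from .replicator import iterate
from .summaries import summarize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run", "sweep"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    # game
    n: int = 2
    r: tuple[float, ...] = (4.4, 2.8)
    g: int = 10
    c: float = 1.0
    pi0: float = 1.0
    nu_s: float = 1e-3
    nu_g: float = 1e-3
    # engine
    engine: str = "replicator"
    N: Optional[int] = None          # ABM only
    T: int = 4000
    init: str = "homogeneous"        # one of the named protocols
    seed: int = 0
    # analysis
    window: Optional[tuple[int, int]] = None
    osc_tol: float = OSC_TOL
    coop_threshold: float = COOP_THRESHOLD
    outdir: str = "."

    def validate(self) -> tuple[GameEnsemble, MutationRates]:
        try:
            ens = GameEnsemble(n=self.n, r=tuple(self.r), g=self.g, c=self.c, pi0=self.pi0)
        except ValueError as exc:
            raise ConfigError(f"game parameters: {exc}") from exc
        try:
            rates = MutationRates(nu_s=self.nu_s, nu_g=self.nu_g)
        except ValueError as exc:
            raise ConfigError(f"mutation rates: {exc}") from exc
        if self.engine not in ("replicator", "abm"):
            raise ConfigError(f"engine: must be 'replicator' or 'abm', got {self.engine!r}")
        if self.engine == "abm":
            if self.N is None:
                raise ConfigError("N: required when engine is 'abm'")
            if self.N < self.g or self.N % self.g != 0:
                raise ConfigError(f"N: {self.N} must be a positive multiple of g={self.g}")
        if self.T < 1:
            raise ConfigError(f"T: must be >= 1, got {self.T}")
        if self.init not in PROTOCOLS:
            raise ConfigError(f"init: unknown protocol {self.init!r}; expected one of {PROTOCOLS}")
        if self.osc_tol <= 0:
            raise ConfigError(f"osc_tol: must be > 0, got {self.osc_tol}")
        return ens, rates

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["r"] = list(self.r)
        if self.window is not None:
            d["window"] = list(self.window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "r" in d:
            d["r"] = tuple(d["r"])
        if d.get("window") is not None:
            d["window"] = tuple(d["window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _manifest(config: RunConfig, wall_time: float) -> dict:
    return {
        "config": config.to_dict(),
        "pggchoice_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "wall_time_s": wall_time,
    }


def run(config: RunConfig, outdir=None):
    """Execute one run and write its artifacts.

    Returns ``(trajectory, summary, report)``; writes trajectory.csv,
    summary.json, report.json and manifest.json under ``outdir``
    (default ``config.outdir``).
    """
    ens, rates = config.validate()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    init = initial_condition(config.init, config.n, seed=config.seed)
    if config.engine == "replicator":
        traj = iterate(init, config.T, ens, rates)
    else:
        traj = simulate(init.rho, ens, rates, config.T, seed=config.seed, N=config.N)
    stats = summarize(traj, window=config.window)
    report = classify_attractor(
        traj,
        osc_tol=config.osc_tol,
        coop_threshold=config.coop_threshold,
    )
    wall = time.perf_counter() - t0
    # trajectory.csv is written via a temp handle then renamed, like the rest
    tmp = outdir / "trajectory.csv.tmp"
    write_trajectory_csv(traj, tmp)
    os.replace(tmp, outdir / "trajectory.csv")
    _atomic_write(outdir / "summary.json", json.dumps(stats.to_dict(), indent=2))
    _atomic_write(
        outdir / "report.json",
        json.dumps(
            {"label": report.label.value, "amplitude": report.amplitude,
             "mean_rhoC": report.mean_rhoC, "window": list(report.window)},
            indent=2,
        ),
    )
    _atomic_write(outdir / "manifest.json", json.dumps(_manifest(config, wall), indent=2))
    logger.info(
        "run complete: engine=%s T=%d label=%s mean_rhoC=%.4f (%.2fs)",
        config.engine, config.T, report.label.value, report.mean_rhoC, wall,
    )
    return traj, stats, report


def sweep(
    config_template: RunConfig,
    r1_grid: Sequence[float],
    r2_grid: Sequence[float],
    protocols: Sequence[str] = ("homogeneous", "favorable", "unfavorable"),
    outdir=None,
    resume: bool = False,
):
    """Phase-diagram sweep over an (r1, r2) grid; writes phase_diagram.csv,
    boundaries.json and manifest.json.

    With ``resume=True`` and a complete phase_diagram.csv already present
    (matching grid and protocols), no recomputation is performed and the
    existing table is returned as a DataFrame.
    """
    ens, rates = config_template.validate()
    outdir = Path(outdir if outdir is not None else config_template.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "phase_diagram.csv"
    expected_rows = len(r1_grid) * len(r2_grid) * len(protocols)
    if resume and csv_path.exists():
        import pandas as pd

        existing = pd.read_csv(csv_path)
        if len(existing) == expected_rows:
            logger.info("sweep resume: %s already complete, skipping", csv_path)
            return existing
    t0 = time.perf_counter()
    diagram = phase_diagram(
        r1_grid, r2_grid, ens, rates, protocols=protocols,
        T=config_template.T, osc_tol=config_template.osc_tol,
        coop_threshold=config_template.coop_threshold, seed=config_template.seed,
    )
    tmp_csv = outdir / "phase_diagram.csv.tmp"
    tmp_json = outdir / "boundaries.json.tmp"
    write_phase_diagram(diagram, tmp_csv, tmp_json)
    os.replace(tmp_csv, csv_path)
    os.replace(tmp_json, outdir / "boundaries.json")
    _atomic_write(outdir / "manifest.json",
                  json.dumps(_manifest(config_template, time.perf_counter() - t0), indent=2))
    return diagram
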