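"""Serialization: trajectories to CSV/HDF5, parameters to YAML/JSON mappings."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import GameEnsemble, MutationRates
from .replicator import Trajectory

__all__ = [
    "trajectory_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_hdf5",
    "read_trajectory_hdf5",
    "params_to_yaml",
    "params_from_yaml",
    "write_phase_diagram",
]


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Columns t, rho_C1..rho_Cn, rho_D1..rho_Dn, rho_C, rho_1..rho_n."""
    n = traj.n
    data = {"t": np.arange(traj.T + 1)}
    for i in range(n):
        data[f"rho_C{i + 1}"] = traj.states[:, 0, i]
    for i in range(n):
        data[f"rho_D{i + 1}"] = traj.states[:, 1, i]
    data["rho_C"] = traj.rho_C
    for i in range(n):
        data[f"rho_{i + 1}"] = traj.resource_density[:, i]
    return pd.DataFrame(data)


def _params_mapping(traj: Trajectory) -> dict:
    return {**traj.ensemble.to_dict(), **traj.rates.to_dict(), **traj.provenance}


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """CSV with a single '# pggchoice ...' header comment carrying the params."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# pggchoice " + json.dumps(_params_mapping(traj)) + "\n")
        trajectory_frame(traj).to_csv(fh, index=False)


def read_trajectory_csv(path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# pggchoice "):
            raise ValueError(f"{path} is not a pggchoice trajectory CSV")
        meta = json.loads(first[len("# pggchoice "):])
        frame = pd.read_csv(fh)
    ens = GameEnsemble.from_dict(meta)
    rates = MutationRates.from_dict(meta)
    provenance = {k: meta[k] for k in ("engine", "N", "seed") if k in meta}
    n = ens.n
    states = np.stack(
        [
            np.column_stack([frame[f"rho_C{i + 1}"] for i in range(n)]),
            np.column_stack([frame[f"rho_D{i + 1}"] for i in range(n)]),
        ],
        axis=1,
    )
    return Trajectory(states, ens, rates, provenance=provenance)  # validates


def write_trajectory_hdf5(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("states", data=traj.states)
        grp = fh.create_group("params")
        for k, v in _params_mapping(traj).items():
            grp.attrs[k] = v


def read_trajectory_hdf5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        states = fh["states"][()]
        meta = dict(fh["params"].attrs)
    ens = GameEnsemble.from_dict(meta)
    rates = MutationRates.from_dict(meta)
    provenance = {k: (v.item() if hasattr(v, "item") else v)
                  for k, v in meta.items() if k in ("engine", "N", "seed")}
    if "engine" in provenance:
        provenance["engine"] = str(provenance["engine"])
    return Trajectory(states, ens, rates, provenance=provenance)


def params_to_yaml(ens: GameEnsemble, rates: MutationRates, path=None) -> str:
    """Flat mapping with keys n, r, g, c, pi0, nu_s, nu_g."""
    text = yaml.safe_dump({**ens.to_dict(), **rates.to_dict()}, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_yaml(source) -> tuple[GameEnsemble, MutationRates]:
    """Accepts a YAML string or a path to a YAML/JSON file."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    d = yaml.safe_load(text)
    return GameEnsemble.from_dict(d), MutationRates.from_dict(d)


def write_phase_diagram(pd_obj, csv_path, boundaries_json_path=None) -> None:
    """Long-format CSV plus an optional JSON file of extracted boundaries."""
    pd_obj.to_frame().to_csv(csv_path, index=False)
    if boundaries_json_path is not None:
        with open(boundaries_json_path, "w") as fh:
            json.dump(pd_obj.boundaries(), fh, indent=2)


def plot_phase_diagram(pd_obj, protocol: str, path) -> None:
    """Render one protocol's label grid as a heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = ["DEFECTIVE_FP", "PERIODIC_ORBIT", "COOPERATIVE_FP"]
    grid = np.vectorize(order.index)(pd_obj.labels[protocol])
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(pd_obj.r1_grid, pd_obj.r2_grid, grid, cmap="viridis",
                       vmin=0, vmax=2, shading="nearest")
    ax.set_xlabel("$r_1$")
    ax.set_ylabel("$r_2$")
    ax.set_title(f"attractor ({protocol} start)")
    cbar = fig.colorbar(im, ticks=[0, 1, 2])
    cbar.ax.set_yticklabels(["defective FP", "periodic orbit", "cooperative FP"])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
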