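"""Readers, writers and run configuration.

Tables go out as CSV with header rows, reports as JSON, trajectories
both as multi-model PDB (one MODEL per frame, readable in any molecular
viewer) and as a plain CSV dump that round-trips losslessly through
:func:`read_trajectory_csv`.  Excitation metadata rides along as
``# key=value`` comment lines (CSV) or REMARK records (PDB).
"""

from __future__ import annotations

import configparser
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elastic_network import CoarseGrainedStructure, ModalDecomposition
from .perturbation_response import Trajectory
from .trajectory_analysis import ScanResult

__all__ = [
    "RunConfig",
    "write_modes_csv",
    "write_bfactors_csv",
    "write_calibration_json",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_pdb",
    "write_scan",
    "write_overlap_csv",
]


@dataclass
class RunConfig:
    """Fully resolved parameters of one run; serialized next to results."""

    structure: str = ""
    target: str = ""
    chains: str = ""
    cutoff: float = 15.0
    gamma: float | None = None
    calibrate: bool = True
    temperature: float = 300.0
    frequencies_thz: list[float] = field(default_factory=list)
    damping_values: list[float] = field(default_factory=lambda: [0.01])
    seeds: list[int] = field(default_factory=lambda: [0])
    cycles: int = 10
    steps_per_cycle: int = 100
    include_transient_window: bool = True
    transient_cap_ps: float = 2000.0
    amplitude_bound_n: float = 1.0e-10
    preset: str = ""
    output_dir: str = "."

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["run"] = {}
        for key, value in asdict(self).items():
            if isinstance(value, list):
                cp["run"][key] = ",".join(str(v) for v in value)
            else:
                cp["run"][key] = "" if value is None else str(value)
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read(path)
        section = cp["run"]
        kwargs = {}
        for key, f in cls.__dataclass_fields__.items():
            if key not in section:
                continue
            raw = section[key]
            if key in ("frequencies_thz", "damping_values"):
                kwargs[key] = [float(v) for v in raw.split(",") if v]
            elif key == "seeds":
                kwargs[key] = [int(v) for v in raw.split(",") if v]
            elif f.type in ("float", "float | None"):
                kwargs[key] = None if raw == "" else float(raw)
            elif f.type == "int":
                kwargs[key] = int(raw)
            elif f.type == "bool":
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def write_modes_csv(modes: ModalDecomposition, path) -> None:
    """Mode table: index (1-based), rigid flag, f in THz, omega in rad/s."""
    df = pd.DataFrame(
        {
            "mode": np.arange(1, modes.omega.size + 1),
            "rigid": np.arange(modes.omega.size) < modes.rigid_mode_count,
            "frequency_thz": modes.frequencies_thz,
            "omega_rad_s": modes.omega,
        }
    )
    df.to_csv(path, index=False)


def write_bfactors_csv(
    structure: CoarseGrainedStructure, b_calc: np.ndarray, path
) -> None:
    df = pd.DataFrame(
        {
            "chain": structure.chain_ids,
            "resid": structure.residue_numbers,
            "resname": structure.residue_names,
            "b_exp": (
                structure.experimental_bfactors
                if structure.experimental_bfactors is not None
                else np.full(structure.n_nodes, np.nan)
            ),
            "b_calc": b_calc,
        }
    )
    df.to_csv(path, index=False)


def write_calibration_json(
    path,
    gamma: float,
    temperature: float,
    cutoff: float,
    mean_b_exp: float,
    mean_b_calc: float,
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "gamma_n_per_m": gamma,
                "temperature_k": temperature,
                "cutoff_a": cutoff,
                "mean_b_experimental_a2": mean_b_exp,
                "mean_b_calculated_a2": mean_b_calc,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """Frame table (frame, time_ps, u000x, u000y, ...) with ``# key=value``
    metadata comment lines before the header."""
    n = trajectory.n_nodes
    cols = [f"u{i:03d}{axis}" for i in range(n) for axis in "xyz"]
    df = pd.DataFrame(trajectory.displacements, columns=cols)
    df.insert(0, "time_ps", trajectory.times_ps)
    df.insert(0, "frame", np.arange(trajectory.n_frames))
    with open(path, "w") as fh:
        for key, value in trajectory.metadata.items():
            fh.write(f"# {key}={json.dumps(value)}\n")
        df.to_csv(fh, index=False)


def read_trajectory_csv(path) -> Trajectory:
    metadata = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, raw = line[1:].strip().partition("=")
                metadata[key.strip()] = json.loads(raw)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    disp = df.drop(columns=["frame", "time_ps"]).to_numpy()
    return Trajectory(
        times_ps=df["time_ps"].to_numpy(), displacements=disp, metadata=metadata
    )


def write_trajectory_pdb(
    trajectory: Trajectory, structure: CoarseGrainedStructure, path
) -> None:
    """Multi-model PDB: coordinates = reference + u(t), one MODEL per frame."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_nodes
    template = struc.AtomArray(n)
    template.chain_id = np.asarray([str(c) for c in structure.chain_ids])
    template.res_id = np.asarray(structure.residue_numbers, dtype=int)
    template.res_name = np.asarray([str(r) for r in structure.residue_names])
    template.atom_name = np.array(["CA"] * n)
    template.element = np.array(["C"] * n)
    template.hetero = np.zeros(n, dtype=bool)

    stack = struc.AtomArrayStack(trajectory.n_frames, n)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = (
        structure.coordinates[None, :, :]
        + trajectory.displacements.reshape(trajectory.n_frames, n, 3)
    )
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    remarks = [
        f"REMARK 250 {key.upper()}={json.dumps(value)}"
        for key, value in trajectory.metadata.items()
    ]
    pdb_file.lines = remarks + pdb_file.lines
    pdb_file.write(path)


def write_structure_pdb(structure: CoarseGrainedStructure, path) -> None:
    """Single-model Calpha PDB of a coarse-grained structure."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_nodes
    atoms = struc.AtomArray(n)
    atoms.chain_id = np.asarray([str(c) for c in structure.chain_ids])
    atoms.res_id = np.asarray(structure.residue_numbers, dtype=int)
    atoms.res_name = np.asarray([str(r) for r in structure.residue_names])
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.coord = np.asarray(structure.coordinates, dtype=np.float32)
    atoms.set_annotation(
        "b_factor",
        np.asarray(
            structure.experimental_bfactors
            if structure.experimental_bfactors is not None
            else np.zeros(n),
            dtype=float,
        ),
    )
    atoms.set_annotation("occupancy", np.ones(n))
    pdb_file = PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(path)


def write_overlap_csv(times_ps, values, path, extra: dict | None = None) -> None:
    df = pd.DataFrame({"time_ps": times_ps, "overlap": values})
    for key, col in (extra or {}).items():
        df[key] = col
    df.to_csv(path, index=False)


def write_scan(scan: ScanResult, csv_path, json_path=None) -> None:
    scan.table.to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "n_simulations": int(len(scan.table)),
            "best_overlap": float(scan.table["max_overlap"].max()),
            "optima": scan.optima.to_dict(orient="records"),
        }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
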