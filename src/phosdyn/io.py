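"""File formats: HDF5 trajectories, TSV event logs, key=value configs,
run manifests.

Trajectory container layout (chunked HDF5):

    /time        (nframe,)        float64, ns
    /positions   (nframe, n, 3)   float64, nm, wrapped to the box
    /chem        (nframe, nsite)  bool, True = pSer
    attrs: box (nm), seed

Event logs and tables are plain TSV so they stay diffable and greppable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .engine import Trajectory, EventLog, SimConfig


def write_trajectory(path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=traj.times, chunks=True)
        f.create_dataset("positions", data=traj.positions, chunks=True)
        f.create_dataset("chem", data=traj.chem, chunks=True)
        f.attrs["box"] = traj.box
        f.attrs["seed"] = traj.seed


def read_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(times=f["time"][:], positions=f["positions"][:],
                          chem=f["chem"][:].astype(bool),
                          box=float(f.attrs["box"]),
                          seed=int(f.attrs["seed"]))


def write_event_log(path, log: EventLog) -> None:
    log.to_frame().to_csv(path, sep="\t", index=False)


def read_event_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pdb_snapshot(path, positions: np.ndarray, codes: list[str],
                       chain_id: np.ndarray, resids: np.ndarray) -> None:
    """Minimal one-bead-per-residue PDB (CA records) for visualization."""
    three = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
             "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
             "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
             "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
             "p": "SEP", "X": "UNK", "Z": "UNK"}
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    with open(path, "w") as f:
        for i, (xyz, code) in enumerate(zip(positions, codes)):
            x, y, z = xyz * 10.0        # nm -> Angstrom
            f.write(f"ATOM  {i + 1:5d}  CA  {three.get(code, 'UNK'):>3s} "
                    f"{chains[int(chain_id[i]) % 26]}{int(resids[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
        f.write("END\n")


# ---------------------------------------------------------------------------
# config


_BOOL = {"true": True, "false": False, "yes": True, "no": False,
         "on": True, "off": False}


def parse_config(path) -> SimConfig:
    """Read a ``key = value`` config file into a SimConfig.

    Unknown keys raise (named in the error); '#' starts a comment.
    """
    values = {}
    valid = set(SimConfig.__dataclass_fields__)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = (s.strip() for s in line.partition("="))
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        val = val.strip()
        if val.lower() in _BOOL:
            values[key] = _BOOL[val.lower()]
        elif key in ("mc_interval", "n_steps", "traj_stride", "seed"):
            values[key] = int(val)
        else:
            values[key] = float(val)
    return SimConfig(**values)


def write_config(path, config: SimConfig) -> None:
    units = dict(dt="ps", temperature="K", friction="1/ps",
                 rotational_drag="1/ps", box_side="nm", mc_interval="MD steps",
                 contact_cutoff="nm", reservoir_distance="nm",
                 dmu_p="kJ/mol", reservoir_enabled="flag", n_steps="MD steps",
                 traj_stride="MD steps", seed="")
    with open(path, "w") as f:
        for key, val in asdict(config).items():
            unit = units.get(key, "")
            f.write(f"{key} = {val}" + (f"    # {unit}\n" if unit else "\n"))


# ---------------------------------------------------------------------------
# manifests


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: SimConfig, inputs: dict[str, str],
                   outputs: list[str], version: str = "") -> dict:
    """Record config, seed, input checksums and the output inventory."""
    if not version:
        from . import __version__
        version = __version__
    manifest = dict(
        version=version,
        seed=config.seed,
        config=asdict(config),
        input_checksums={name: file_checksum(p) for name, p in inputs.items()},
        outputs=[str(o) for o in outputs],
    )
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
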