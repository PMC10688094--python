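"""File formats: XYZ trajectories, PDB topology export, run configs,
result tables and run manifests.

Coordinates are Angstrom everywhere and energies kT; no unit conversion
happens at the I/O layer.  The XYZ element column encodes the bead role
(``DNA``, ``G2``, ``G2T``, ``PEP``, ``CI``) so any trajectory written by
the engine can be re-analysed without the originating composition.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import ROLE_CODES, ROLE_NAMES, ParticleSystem, Trajectory

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "write_bond_table",
    "read_config",
    "write_config",
    "RunManifest",
]

_COORD_FMT = "%.6f"


def write_xyz(path, traj: Trajectory, comment_extra: str = "") -> None:
    """Write a multi-frame XYZ file; the comment line carries the frame
    index and cell radius."""
    path = Path(path)
    roles = [ROLE_NAMES[int(c)] for c in traj.system.roles]
    with path.open("w") as fh:
        for fi, frame in enumerate(traj.frames):
            fh.write(f"{len(frame)}\n")
            fh.write(
                f"frame={fi} cell_radius={traj.cell_radius:g} {comment_extra}".rstrip()
                + "\n"
            )
            for role, (x, y, z) in zip(roles, frame):
                fh.write(
                    f"{role} {_COORD_FMT % x} {_COORD_FMT % y} {_COORD_FMT % z}\n"
                )


def read_xyz(path):
    """Read a role-encoded XYZ trajectory.

    Returns ``(frames, roles, cell_radius)`` where ``frames`` is an
    (F, N, 3) array, ``roles`` the per-particle role strings of the
    first frame, and ``cell_radius`` parsed from the comment line (nan
    when absent).  Raises ``ValueError`` naming the offending line on
    malformed input.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    roles: list[str] = []
    cell_radius = float("nan")
    lines = path.read_text().splitlines()
    i = 0
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        for tok in comment.split():
            if tok.startswith("cell_radius="):
                cell_radius = float(tok.split("=", 1)[1])
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{i + 1}: truncated frame (expected {n} atoms)")
        coords = np.empty((n, 3))
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + k}: malformed atom line {ln!r}")
            if first:
                roles.append(parts[0])
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{i + 3 + k}: bad coordinate in {ln!r}"
                ) from exc
        frames.append(coords)
        first = False
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.asarray(frames), roles, cell_radius


def write_pdb(path, system: ParticleSystem, coords: np.ndarray) -> None:
    """Export one configuration as PDB ATOM records plus CONECT bonds.

    Intended for visualisation only; bead roles map to pseudo-atom
    names.  Serial numbers are 1-based as PDB requires.
    """
    path = Path(path)
    names = {0: "DN", 1: "GC", 2: "GT", 3: "PE", 4: "CI"}
    with path.open("w") as fh:
        for i, (x, y, z) in enumerate(coords):
            role = int(system.roles[i])
            name = names[role]
            fh.write(
                f"ATOM  {i + 1:5d} {name:<4s} BEA A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        for a, b in system.bonds:
            fh.write(f"CONECT{a + 1:5d}{b + 1:5d}\n")
        fh.write("END\n")


def write_bond_table(path, system: ParticleSystem) -> None:
    """Bond list as CSV (bead_i, bead_j, rest_length)."""
    import pandas as pd

    pd.DataFrame(
        {
            "bead_i": system.bonds[:, 0],
            "bead_j": system.bonds[:, 1],
            "rest_length": system.bond_r0,
        }
    ).to_csv(path, index=False)


_KNOWN_CONFIG_KEYS = {
    "system",
    "scale",
    "r_charge",
    "n_vector",
    "seed",
    "equilibration_steps",
    "production_steps",
    "n_replicates",
    "sample_interval",
    "bjerrum_length",
    "screening_length",
    "bond_k",
    "cell_radius",
    "temperature",
}


def read_config(path) -> dict:
    """Read a YAML run configuration; warns on unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in cfg:
        if key not in _KNOWN_CONFIG_KEYS:
            warnings.warn(f"unknown config key {key!r} (kept, but unused)")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable hash of a config mapping (order-insensitive)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record for a batch of replicate runs."""

    scenario: str
    config: dict
    seeds: list[int]
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    wall_clock_s: float = 0.0

    def to_json(self) -> str:
        from . import __version__

        return json.dumps(
            {
                "scenario": self.scenario,
                "config_hash": config_hash(self.config),
                "config": self.config,
                "seeds": self.seeds,
                "outputs": self.outputs,
                "version": self.version or __version__,
                "wall_clock_s": round(self.wall_clock_s, 2),
            },
            indent=2,
            default=str,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def validate(self, base_dir=".") -> bool:
        """Every listed output exists."""
        return all((Path(base_dir) / p).exists() for p in self.outputs)
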