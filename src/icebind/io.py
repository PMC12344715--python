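"""File I/O: PDB/GRO (via MDAnalysis), extended XYZ, TSV/JSON, run config.

Internal units are nm; PDB files are converted from/to Angstrom at the
boundary.  Boxes must be orthorhombic — triclinic inputs are rejected, and a
missing box is an error rather than a silent vacuum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import Configuration, Trajectory

__all__ = [
    "RunConfig",
    "read_configuration",
    "read_trajectory_xyz",
    "write_configuration",
    "write_trajectory_xyz",
]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline in one auditable place.

    Defaults are the analysis constants used throughout: sparse-ice radius
    0.5 nm, absorption radius 0.35 nm, -CH2 attachment 6 ice molecules
    within 0.55 nm, hydrogen bonds at 0.35 nm / 30 degrees, coverage disks
    of radius 0.5 nm, and the closed PPII windows phi [-110, -30] /
    psi [120, 180].
    """

    r_sparse: float = 0.5
    min_ice_neighbors: int = 3
    r_absorb: float = 0.35
    r_attach: float = 0.55
    min_ice_attach: int = 6
    r_hbond: float = 0.35
    hbond_angle: float = 30.0
    atomic_radius: float = 0.5
    grid_res: float = 0.02
    surface_layer: float = 0.3
    surface_z_floor: float = 0.0
    engulf_fraction: float = 0.9
    coverage_resistance_threshold: float = 3.3
    ppii_phi: tuple[float, float] = (-110.0, -30.0)
    ppii_psi: tuple[float, float] = (120.0, 180.0)
    surface_method: str = "top_layer_mean"
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ppii_phi" in data:
            data["ppii_phi"] = tuple(data["ppii_phi"])
        if "ppii_psi" in data:
            data["ppii_psi"] = tuple(data["ppii_psi"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["ppii_phi"] = list(data["ppii_phi"])
        data["ppii_psi"] = list(data["ppii_psi"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# single-frame formats
# ---------------------------------------------------------------------------


def _check_box(dimensions, path) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise ValueError(f"{path}: no box information (refusing a silent vacuum)")
    dims = np.asarray(dimensions, dtype=float)
    if len(dims) >= 6 and not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise ValueError(f"{path}: triclinic box not supported (angles {dims[3:6]})")
    return dims[:3]


def read_configuration(path, fmt: str | None = None) -> Configuration:
    """Read a single frame from PDB, GRO, or extended XYZ.

    The format is taken from the extension unless ``fmt`` is given.
    Positions are returned in nm; the box must be orthorhombic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    ext = (fmt or path.suffix.lstrip(".")).lower()
    if ext in ("xyz", "extxyz"):
        frames = read_trajectory_xyz(path)
        if len(frames) != 1:
            raise ValueError(f"{path}: expected a single frame, found {len(frames)}")
        return frames[0]
    if ext not in ("pdb", "gro"):
        raise ValueError(f"unsupported format {ext!r}")
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    box = _check_box(u.dimensions, path) / 10.0  # A -> nm
    pos = u.atoms.positions.astype(float) / 10.0
    names = list(u.atoms.names) if hasattr(u.atoms, "names") else None
    try:
        resids = u.atoms.resids.astype(int) - 1
    except Exception:  # noqa: BLE001
        resids = None
    return Configuration(pos, box, names=names, resids=resids)


def write_configuration(config: Configuration, path, fmt: str | None = None) -> None:
    """Write a single frame as PDB, GRO, or extended XYZ."""
    path = Path(path)
    ext = (fmt or path.suffix.lstrip(".")).lower()
    if ext in ("xyz", "extxyz"):
        write_trajectory_xyz(Trajectory([config]), path)
        return
    if ext not in ("pdb", "gro"):
        raise ValueError(f"unsupported format {ext!r}")
    if config.box is None:
        raise ValueError("cannot write a configuration without a box")
    import MDAnalysis as mda

    n = config.n_atoms
    resids = config.resids if config.resids is not None else np.zeros(n, dtype=int)
    n_res = int(resids.max()) + 1 if n else 1
    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=resids, trajectory=True
    )
    names = config.names if config.names is not None else ["X"] * n
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("resnames", ["MOL"] * n_res)
    u.atoms.positions = config.positions * 10.0  # nm -> A
    u.dimensions = np.array([*(config.box * 10.0), 90.0, 90.0, 90.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# extended XYZ (single- and multi-frame), box carried on the comment line
# ---------------------------------------------------------------------------


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    """Write frames as extended XYZ with ``Lattice="..."`` box metadata (nm)."""
    with open(path, "w") as fh:
        for frame in traj:
            if frame.box is None:
                raise ValueError("cannot write a frame without a box")
            lx, ly, lz = frame.box
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{lx:.8f} 0 0 0 {ly:.8f} 0 0 0 {lz:.8f}" '
                f"Properties=species:S:1:pos:R:3\n"
            )
            names = frame.names or ["X"] * frame.n_atoms
            for name, (x, y, z) in zip(names, frame.positions):
                fh.write(f"{name} {x:.8f} {y:.8f} {z:.8f}\n")


def _parse_lattice(comment: str, path) -> np.ndarray:
    if "Lattice=" not in comment:
        raise ValueError(f"{path}: XYZ comment line lacks Lattice= box metadata")
    raw = comment.split("Lattice=")[1]
    quote = raw[0]
    if quote in "\"'":
        raw = raw[1:].split(quote)[0]
    else:
        raw = raw.split()[0]
    vals = np.array([float(v) for v in raw.split()])
    if len(vals) != 9:
        raise ValueError(f"{path}: Lattice= must hold 9 numbers")
    mat = vals.reshape(3, 3)
    if not np.allclose(mat, np.diag(np.diag(mat)), atol=1e-10):
        raise ValueError(f"{path}: triclinic box not supported")
    return np.diag(mat).copy()


def read_trajectory_xyz(path) -> Trajectory:
    """Read a (multi-frame) extended XYZ file written by this package."""
    path = Path(path)
    frames: list[Configuration] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: expected atom count") from err
            comment = fh.readline()
            lineno += 1
            box = _parse_lattice(comment, path)
            names = []
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                lineno += 1
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed atom record")
                names.append(parts[0])
                pos[i] = [float(p) for p in parts[1:4]]
            frames.append(Configuration(pos, box, names=names))
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(frames)


def write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(data: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
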