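"""Core containers: configurations, trajectories, phase labels, PBC helpers.

All coordinates are in nanometres.  Boxes are orthorhombic (three edge
lengths); ``box=None`` means open (non-periodic) boundaries, which is the
natural setting for an isolated polymer chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Configuration",
    "Trajectory",
    "Phase",
    "PhaseLabels",
    "minimum_image",
    "pair_distance",
    "wrap_positions",
    "molar_concentration_in_water",
]

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23
#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.015


@dataclass
class Configuration:
    """A single frame: particle positions plus an orthorhombic box.

    Parameters
    ----------
    positions
        ``(N, 3)`` array of positions in nm.
    box
        Edge lengths ``(Lx, Ly, Lz)`` in nm, or ``None`` for open boundaries.
    names
        Optional per-atom names (e.g. ``"O"``, ``"CA"``).
    resids
        Optional per-atom residue indices (0-based).
    """

    positions: np.ndarray
    box: np.ndarray | None = None
    names: list[str] | None = None
    resids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError(f"box edges must be positive, got {self.box}")
        if self.resids is not None:
            self.resids = np.asarray(self.resids, dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def wrapped(self) -> "Configuration":
        """Return a copy with positions wrapped into the primary box."""
        if self.box is None:
            return self
        return Configuration(
            wrap_positions(self.positions, self.box),
            self.box.copy(),
            self.names,
            self.resids,
        )

    def translated(self, shift) -> "Configuration":
        return Configuration(
            self.positions + np.asarray(shift, dtype=float),
            None if self.box is None else self.box.copy(),
            self.names,
            self.resids,
        )


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing a box and atom identity."""

    frames: list[Configuration] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Configuration:
        return self.frames[i]


class Phase(IntEnum):
    """Per-molecule phase assignment.

    ``ABSORBED`` marks liquid molecules pulled into the ice phase by the
    interfacial-water proximity rule; it counts as ice everywhere.
    """

    LIQUID = 0
    HEX_ICE = 1
    CUBIC_ICE = 2
    INTERFACIAL_ICE = 3
    ABSORBED = 4


ICE_PHASES = (Phase.HEX_ICE, Phase.CUBIC_ICE, Phase.INTERFACIAL_ICE, Phase.ABSORBED)


@dataclass
class PhaseLabels:
    """Per-molecule phase labels for one frame."""

    labels: np.ndarray  # (N,) int array of Phase values

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_molecules(self) -> int:
        return len(self.labels)

    def count(self, phase: Phase) -> int:
        return int(np.sum(self.labels == int(phase)))

    @property
    def is_ice(self) -> np.ndarray:
        """Boolean mask of molecules in any ice phase (incl. absorbed)."""
        return self.labels != int(Phase.LIQUID)

    @property
    def n_ice_total(self) -> int:
        return int(np.sum(self.is_ice))

    def counts(self) -> dict[str, int]:
        c = {
            "n_hex": self.count(Phase.HEX_ICE),
            "n_cubic": self.count(Phase.CUBIC_ICE),
            "n_interfacial": self.count(Phase.INTERFACIAL_ICE),
            "n_absorbed": self.count(Phase.ABSORBED),
            "n_liquid": self.count(Phase.LIQUID),
        }
        c["n_ice_total"] = c["n_hex"] + c["n_cubic"] + c["n_interfacial"] + c["n_absorbed"]
        assert c["n_ice_total"] + c["n_liquid"] == self.n_molecules
        return c


def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement vectors."""
    v = np.asarray(vectors, dtype=float)
    if box is None:
        return v
    return v - box * np.round(v / box)


def pair_distance(a, b, box=None) -> float:
    """Minimum-image distance between two points."""
    d = minimum_image(np.asarray(b, float) - np.asarray(a, float), box)
    return float(np.linalg.norm(d))


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap positions into ``[0, L)`` along each axis."""
    return np.mod(np.asarray(positions, dtype=float), box)


def molar_concentration_in_water(n_solute: int, n_waters: float) -> float:
    """Molar concentration (mol/L) of ``n_solute`` molecules dissolved in
    ``n_waters`` water molecules, taking the solution volume as that of
    liquid water at 1 g/cm^3.
    """
    if n_waters <= 0:
        raise ValueError("n_waters must be positive")
    volume_l = n_waters * WATER_MOLAR_MASS / N_AVOGADRO / 1000.0  # g / (g/L)
    return n_solute / N_AVOGADRO / volume_l
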