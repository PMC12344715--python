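"""Polymer topology: which atoms play which role in the binding metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PolymerTopology"]


@dataclass
class PolymerTopology:
    """Roles of a polymer chain's atoms within a configuration.

    All indices are 0-based indices into the parent configuration.

    Attributes
    ----------
    chain_id
        Identifier of the chain.
    heavy_atoms
        Indices of all heavy (non-hydrogen) atoms of the chain.
    ch2_carbons
        Indices of the methylene (-CH2) carbons probed for ice attachment
        (for proline: the three ring carbons CB, CG, CD of each residue).
    donors
        Mapping donor-atom index -> list of attached hydrogen indices.
    acceptors
        Indices of hydrogen-bond acceptor atoms (carbonyl oxygens).
    phi_quads, psi_quads
        Mapping residue index -> 4-tuple of atom indices defining the
        backbone phi (C'_{i-1}, N_i, CA_i, C'_i) and
        psi (N_i, CA_i, C'_i, N_{i+1}) torsions.
    n_residues
        Number of residues in the chain.
    masses
        Optional per-atom masses (amu) aligned with the parent configuration
        (entries for atoms outside the chain may be zero).
    """

    chain_id: str
    heavy_atoms: np.ndarray
    ch2_carbons: np.ndarray
    donors: dict[int, list[int]] = field(default_factory=dict)
    acceptors: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    phi_quads: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    psi_quads: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    n_residues: int = 0
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heavy_atoms = np.asarray(self.heavy_atoms, dtype=int)
        self.ch2_carbons = np.asarray(self.ch2_carbons, dtype=int)
        self.acceptors = np.asarray(self.acceptors, dtype=int)
        for d, hs in self.donors.items():
            if len(hs) == 0:
                raise ValueError(f"donor atom {d} has no attached hydrogen")

    def shifted(self, offset: int) -> "PolymerTopology":
        """Return a copy with all atom indices shifted by ``offset`` (used
        when the chain is appended to a larger configuration)."""
        return PolymerTopology(
            chain_id=self.chain_id,
            heavy_atoms=self.heavy_atoms + offset,
            ch2_carbons=self.ch2_carbons + offset,
            donors={d + offset: [h + offset for h in hs] for d, hs in self.donors.items()},
            acceptors=self.acceptors + offset,
            phi_quads={r: tuple(i + offset for i in q) for r, q in self.phi_quads.items()},
            psi_quads={r: tuple(i + offset for i in q) for r, q in self.psi_quads.items()},
            n_residues=self.n_residues,
            masses=self.masses,
        )
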