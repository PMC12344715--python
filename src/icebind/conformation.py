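"""Backbone conformation metrics: torsions, PPII content, Rg, populations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Configuration
from .topology import PolymerTopology

__all__ = [
    "KB",
    "PPII_PHI_WINDOW",
    "PPII_PSI_WINDOW",
    "DihedralRecord",
    "dihedral",
    "ppii_fraction",
    "radius_of_gyration",
    "population_ratio",
]

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083145

#: Closed dihedral windows (degrees) defining the polyproline-II helix.
PPII_PHI_WINDOW = (-110.0, -30.0)
PPII_PSI_WINDOW = (120.0, 180.0)


@dataclass
class DihedralRecord:
    residue: int
    phi: float
    psi: float
    is_ppii: bool


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Standard right-hand convention: looking down the p2->p3 bond, a positive
    angle rotates the p1 side clockwise onto the p4 side.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate (collinear) points in dihedral")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / nb2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def is_ppii(phi: float, psi: float) -> bool:
    """Closed-interval PPII test: phi in [-110, -30] and psi in [120, 180]."""
    return (
        PPII_PHI_WINDOW[0] <= phi <= PPII_PHI_WINDOW[1]
        and PPII_PSI_WINDOW[0] <= psi <= PPII_PSI_WINDOW[1]
    )


def ppii_fraction(
    config: Configuration, topology: PolymerTopology
) -> tuple[float, list[DihedralRecord]]:
    """Fraction of evaluable residues in the PPII window, plus per-residue records.

    A residue is evaluable when both its phi and psi quadruplets exist;
    terminal residues lacking one are excluded from the denominator.
    """
    pos = config.positions
    records: list[DihedralRecord] = []
    for res in sorted(set(topology.phi_quads) & set(topology.psi_quads)):
        phi = dihedral(*(pos[i] for i in topology.phi_quads[res]))
        psi = dihedral(*(pos[i] for i in topology.psi_quads[res]))
        records.append(DihedralRecord(res, phi, psi, is_ppii(phi, psi)))
    if not records:
        raise ValueError("no residue has both phi and psi defined")
    frac = sum(r.is_ppii for r in records) / len(records)
    return frac, records


def dihedral_table(config: Configuration, topology: PolymerTopology) -> pd.DataFrame:
    _, records = ppii_fraction(config, topology)
    return pd.DataFrame(
        [{"residue": r.residue, "phi": r.phi, "psi": r.psi, "is_ppii": r.is_ppii} for r in records]
    )


def radius_of_gyration(
    config: Configuration, atom_set=None, weights=None
) -> float:
    """Mass-weighted radius of gyration about the weighted centroid (nm)."""
    idx = np.arange(config.n_atoms) if atom_set is None else np.asarray(atom_set, dtype=int)
    if len(idx) < 1:
        raise ValueError("empty atom selection")
    pos = config.positions[idx]
    w = np.ones(len(idx)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(idx):
        raise ValueError("weights must match the atom selection")
    w = w / w.sum()
    centroid = w @ pos
    return float(np.sqrt(np.sum(w * np.sum((pos - centroid) ** 2, axis=1))))


def population_ratio(delta_g_cl: float, temperature: float) -> float:
    """Boltzmann population ratio p(L)/p(C) = exp(dG_CL / kB T).

    ``delta_g_cl`` is G_C - G_L in kJ/mol: a positive value favours the
    extended linear (L) conformer over the compact coil (C).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(delta_g_cl / (KB * temperature)))
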