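"""Synthetic ice/water/polymer systems for exercising the analysis pipeline.

Everything the classification and binding metrics consume can be generated
here without a molecular-dynamics engine:

* ideal hexagonal (Ih) and cubic (Ic) ice **oxygen** lattices in orthorhombic
  boxes,
* excluded-volume "liquid" boxes (random insertion with a minimum distance),
* oligoproline-like chains built from internal coordinates, in ideal
  polyproline-II (PPII) or perturbed-coil conformations, with three ring
  carbons per residue acting as the -CH2 ice-attachment probes,
* advancing ice-front trajectories with exact per-frame ground-truth phase
  labels, optionally containing a chain placed above, inside, or below the
  initial front.

Water is represented by its oxygen position only: the phase classification
and every binding metric operate on molecular (oxygen) neighbour geometry.
Explicit hydrogens are generated only where hydrogen-bond geometry is being
tested (:func:`make_water`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Configuration, Trajectory, minimum_image, wrap_positions
from .topology import PolymerTopology

__all__ = [
    "LatticeSpec",
    "ChainSpec",
    "FrontTrajectorySpec",
    "FrontTrajectory",
    "build_ice_lattice",
    "build_liquid",
    "build_chain",
    "build_front_trajectory",
    "make_water",
    "PPII_PHI",
    "PPII_PSI",
]

# Canonical PPII backbone torsions (degrees).  These sit centrally inside the
# PPII classification window phi in [-110, -30], psi in [120, 180].
PPII_PHI = -75.0
PPII_PSI = 145.0
OMEGA_TRANS = 180.0

# Backbone internal coordinates (nm / degrees), standard peptide values.
_B_N_CA = 0.146
_B_CA_C = 0.152
_B_C_N = 0.133
_B_C_O = 0.123
_A_N_CA_C = 111.0
_A_CA_C_N = 116.6
_A_C_N_CA = 121.9
_A_CA_C_O = 121.0

_MASS = {"N": 14.007, "C": 12.011, "O": 15.999, "H": 1.008}

# Atom order within one residue; CB/CG/CD are the ring -CH2 pseudo-carbons.
_RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB", "CG", "CD")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class LatticeSpec:
    """Ideal ice oxygen lattice: polymorph, cell counts, O-O bond length."""

    phase: str  # "Ih" or "Ic"
    n_cells: tuple[int, int, int] = (2, 2, 2)
    oo_distance: float = 0.276  # nm, nearest-neighbour O-O
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.phase not in ("Ih", "Ic"):
            raise ValueError(f"phase must be 'Ih' or 'Ic', got {self.phase!r}")
        if any(int(n) < 1 for n in self.n_cells):
            raise ValueError(f"n_cells must be >= 1 in each direction: {self.n_cells}")
        if self.oo_distance <= 0:
            raise ValueError("oo_distance must be positive")
        self.n_cells = tuple(int(n) for n in self.n_cells)


@dataclass
class ChainSpec:
    """Oligoproline-like chain: length, conformation family, torsion noise."""

    n_residues: int
    conformation: str = "linear_PPII"  # or "coil"
    dihedral_noise_deg: float = 0.0
    seed: int = 0
    cis_probability: float = 0.25  # coil only: chance of a cis omega flip
    phi: float = PPII_PHI  # base backbone torsions (degrees); override to
    psi: float = PPII_PSI  # build non-PPII reference chains

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.conformation not in ("linear_PPII", "coil"):
            raise ValueError(f"unknown conformation {self.conformation!r}")
        if self.dihedral_noise_deg < 0:
            raise ValueError("dihedral_noise_deg must be >= 0")


@dataclass
class FrontTrajectorySpec:
    """An ice slab whose front advances frame by frame into liquid water."""

    slab_spec: LatticeSpec
    n_liquid: int = 200
    n_frames: int = 5
    front_velocity: float = 0.0  # nm per frame, upward along +z
    thermal_jitter: float = 0.0  # Gaussian sigma per coordinate, nm
    chain: ChainSpec | None = None
    chain_placement: str | tuple[str, float] = "above_surface"
    seed: int = 0
    liquid_density: float = 20.0  # particles/nm^3 in the liquid region
    liquid_min_dist: float = 0.26  # nm between liquid oxygens
    # liquid is kept outside the second lattice shell (1.633 d ~ 0.45 nm for
    # d = 0.276), so surface bond patterns are deterministic at zero jitter
    ice_clearance: float = 0.48  # nm kept between liquid and ice sites
    chain_clearance: float = 0.30  # nm above the front for "above_surface"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.thermal_jitter < 0:
            raise ValueError("thermal_jitter must be >= 0")
        placement = self.chain_placement
        if isinstance(placement, str):
            if placement not in ("above_surface", "engulfed"):
                raise ValueError(f"unknown chain placement {placement!r}")
        else:
            kind, depth = placement
            if kind != "embedded" or depth < 0:
                raise ValueError(f"unknown chain placement {placement!r}")


# ---------------------------------------------------------------------------
# ice lattices
# ---------------------------------------------------------------------------

# Fractional coordinates of the 8-molecule orthorhombic cells.  Both are
# bipartite 4-regular networks with every bond of length oo_distance.
#
# Ic: diamond-cubic oxygen sublattice, conventional cubic cell, a = 4 d/sqrt(3).
_IC_FRAC = np.array(
    [
        [0.00, 0.00, 0.00],
        [0.00, 0.50, 0.50],
        [0.50, 0.00, 0.50],
        [0.50, 0.50, 0.00],
        [0.25, 0.25, 0.25],
        [0.25, 0.75, 0.75],
        [0.75, 0.25, 0.75],
        [0.75, 0.75, 0.25],
    ]
)

# Ih: hexagonal-diamond (lonsdaleite) oxygen sublattice in the orthohexagonal
# setting (a, a*sqrt(3), c) with ideal c/a; two interpenetrating hcp
# sublattices offset by 3/8 c (= one bond) along z.  The crystallographic
# hexagonal cell holds 4 molecules but cannot tile an orthorhombic box; this
# doubled cell holds 8.
_HCP_FRAC = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.5, 0.5, 0.0],
        [0.5, 1.0 / 6.0, 0.5],
        [0.0, 2.0 / 3.0, 0.5],
    ]
)
_IH_FRAC = np.vstack([_HCP_FRAC, _HCP_FRAC + [0.0, 0.0, 3.0 / 8.0]])


def _cell_dimensions(phase: str, d: float) -> np.ndarray:
    if phase == "Ic":
        a = 4.0 * d / math.sqrt(3.0)
        return np.array([a, a, a])
    a = d * math.sqrt(8.0 / 3.0)  # hexagonal a
    c = 8.0 * d / 3.0  # ideal lonsdaleite c
    return np.array([a, a * math.sqrt(3.0), c])


def build_ice_lattice(spec: LatticeSpec) -> Configuration:
    """Build an ideal oxygen-only ice lattice in an orthorhombic box.

    Every molecule is 4-coordinated at ``spec.oo_distance`` under periodic
    boundaries.  The box is ``n_cells * cell`` with the cell dimensions fixed
    by the polymorph and the O-O distance.
    """
    frac = _IC_FRAC if spec.phase == "Ic" else _IH_FRAC
    cell = _cell_dimensions(spec.phase, spec.oo_distance)
    nx, ny, nz = spec.n_cells
    shifts = np.array(
        [[i, j, k] for i in range(nx) for j in range(ny) for k in range(nz)], dtype=float
    )
    pos = (frac[None, :, :] + shifts[:, None, :]).reshape(-1, 3) * cell
    box = cell * np.array([nx, ny, nz], dtype=float)
    pos = wrap_positions(pos + np.asarray(spec.origin, dtype=float), box)
    names = ["O"] * len(pos)
    return Configuration(pos, box, names=names)


# ---------------------------------------------------------------------------
# liquid packing
# ---------------------------------------------------------------------------


class _CellList:
    """Minimal periodic cell list for minimum-distance insertion checks."""

    def __init__(self, box: np.ndarray, min_dist: float):
        self.box = box
        self.n = np.maximum(np.floor(box / min_dist).astype(int), 1)
        self.min_dist = min_dist
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> np.ndarray:
        return np.floor(p / self.box * self.n).astype(int) % self.n

    def ok(self, p: np.ndarray) -> bool:
        k = self._key(p)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    key = tuple((k + [di, dj, dk]) % self.n)
                    for q in self.cells.get(key, ()):
                        d = minimum_image(p - q, self.box)
                        if d @ d < self.min_dist**2:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        self.cells.setdefault(tuple(self._key(p)), []).append(p)


def _pack(
    box: np.ndarray,
    n: int,
    min_dist: float,
    rng: np.random.Generator,
    z_range: tuple[float, float] | None = None,
    exclude: np.ndarray | None = None,
    exclude_dist: float = 0.0,
    max_tries_per_particle: int = 2000,
) -> np.ndarray:
    """Random sequential insertion of ``n`` points with PBC minimum distance.

    Optionally restricted to a z-slab and kept ``exclude_dist`` away from a
    fixed set of points.
    """
    if n == 0:
        return np.empty((0, 3))
    cells = _CellList(box, min_dist)
    tree = None
    if exclude is not None and len(exclude):
        tree = cKDTree(wrap_positions(exclude, box), boxsize=box)
    lo = 0.0 if z_range is None else z_range[0]
    hi = box[2] if z_range is None else z_range[1]
    if hi <= lo:
        raise ValueError(f"empty z-range [{lo}, {hi}] for liquid insertion")
    out = []
    budget = max_tries_per_particle * n
    while len(out) < n:
        if budget <= 0:
            raise RuntimeError(
                f"could not insert particle {len(out) + 1}/{n} at min_dist={min_dist}"
            )
        budget -= 1
        p = rng.random(3) * box
        p[2] = lo + rng.random() * (hi - lo)
        if not cells.ok(p):
            continue
        if tree is not None and tree.query(p, k=1)[0] < exclude_dist:
            continue
        cells.add(p)
        out.append(p)
    return np.array(out)


def build_liquid(n: int, density: float = 20.0, min_dist: float = 0.25, seed: int = 0) -> Configuration:
    """Random excluded-volume 'liquid' in a cubic box of the given density.

    Reproducible for a fixed seed; positions have all minimum-image pair
    distances >= ``min_dist``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if density <= 0:
        raise ValueError("density must be positive")
    L = max((n / density) ** (1.0 / 3.0), 1.0) if n else 1.0
    box = np.array([L, L, L])
    rng = np.random.default_rng(seed)
    pos = _pack(box, n, min_dist, rng)
    return Configuration(pos, box, names=["O"] * n)


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position of D bonded to C with angle B-C-D and
    torsion A-B-C-D."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate (collinear) reference atoms in chain build")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(spec: ChainSpec) -> tuple[Configuration, PolymerTopology]:
    """Build a proline-like chain from internal coordinates.

    The backbone (N, CA, C' per residue) is generated with
    phi = -75, psi = +145, omega = 180 degrees for ``linear_PPII``; ``coil``
    adds seeded Gaussian torsion noise and random cis-omega flips.  Three
    ring-carbon pseudo-atoms (CB, CG, CD) per residue stand in for the
    proline -CH2 groups, and each carbonyl oxygen is listed as a hydrogen-bond
    acceptor.  Proline has no backbone amide hydrogen, so the donor list is
    empty.

    Returns the chain as an open-boundary :class:`Configuration` together
    with its :class:`PolymerTopology`.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues

    def noisy(base: float) -> float:
        if spec.dihedral_noise_deg > 0:
            return base + float(rng.normal(0.0, spec.dihedral_noise_deg))
        return base

    phis = [None] + [noisy(spec.phi) for _ in range(1, n)]  # phi_0 undefined
    psis = [noisy(spec.psi) for _ in range(n)]
    omegas = [OMEGA_TRANS] * n
    if spec.conformation == "coil":
        for i in range(n - 1):
            if rng.random() < spec.cis_probability:
                omegas[i] = 0.0

    pos: list[np.ndarray] = []
    names: list[str] = []
    resids: list[int] = []

    def add(name: str, p: np.ndarray, res: int) -> int:
        pos.append(np.asarray(p, dtype=float))
        names.append(name)
        resids.append(res)
        return len(pos) - 1

    idx: dict[tuple[int, str], int] = {}

    # residue 0 bootstrap: N at origin, CA along +x, C' in the xy-plane
    idx[(0, "N")] = add("N", np.zeros(3), 0)
    idx[(0, "CA")] = add("CA", np.array([_B_N_CA, 0.0, 0.0]), 0)
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = pos[idx[(0, "CA")]] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    idx[(0, "C")] = add("C", c0, 0)

    for i in range(n):
        N, CA, C = (pos[idx[(i, a)]] for a in ("N", "CA", "C"))
        # carbonyl oxygen, trans to the (next) amide nitrogen
        idx[(i, "O")] = add("O", _place_atom(N, CA, C, _B_C_O, _A_CA_C_O, psis[i] + 180.0), i)
        # ring pseudo-carbons, fixed internal coordinates
        cb = _place_atom(C, N, CA, 0.153, 103.0, -120.0)
        idx[(i, "CB")] = add("CB", cb, i)
        cg = _place_atom(N, CA, cb, 0.152, 104.0, 30.0)
        idx[(i, "CG")] = add("CG", cg, i)
        idx[(i, "CD")] = add("CD", _place_atom(C, CA, N, 0.147, 112.0, 170.0), i)
        if i == n - 1:
            break
        # next residue backbone: psi_i, omega_i, phi_{i+1}
        n_next = _place_atom(N, CA, C, _B_C_N, _A_CA_C_N, psis[i])
        idx[(i + 1, "N")] = add("N", n_next, i + 1)
        ca_next = _place_atom(CA, C, n_next, _B_N_CA, _A_C_N_CA, omegas[i])
        idx[(i + 1, "CA")] = add("CA", ca_next, i + 1)
        c_next = _place_atom(C, n_next, ca_next, _B_CA_C, _A_N_CA_C, phis[i + 1])
        idx[(i + 1, "C")] = add("C", c_next, i + 1)

    positions = np.array(pos)
    config = Configuration(positions, box=None, names=names, resids=np.array(resids))

    heavy = np.arange(len(positions))
    ch2 = np.array(
        sorted(idx[(i, a)] for i in range(n) for a in ("CB", "CG", "CD")), dtype=int
    )
    acceptors = np.array(sorted(idx[(i, "O")] for i in range(n)), dtype=int)
    phi_quads = {
        i: (idx[(i - 1, "C")], idx[(i, "N")], idx[(i, "CA")], idx[(i, "C")])
        for i in range(1, n)
    }
    psi_quads = {
        i: (idx[(i, "N")], idx[(i, "CA")], idx[(i, "C")], idx[(i + 1, "N")])
        for i in range(n - 1)
    }
    masses = np.array([_MASS[nm[0]] for nm in names])
    topo = PolymerTopology(
        chain_id="P",
        heavy_atoms=heavy,
        ch2_carbons=ch2,
        donors={},
        acceptors=acceptors,
        phi_quads=phi_quads,
        psi_quads=psi_quads,
        n_residues=n,
        masses=masses,
    )
    return config, topo


def make_water(origin, direction=(1.0, 0.0, 0.0)) -> tuple[np.ndarray, list[str]]:
    """One explicit water (O, H1, H2) for hydrogen-bond geometry fixtures.

    The first O-H bond points along ``direction``; H-O-H angle 104.5 degrees,
    O-H length 0.0957 nm.  Returns positions (3, 3) and names.
    """
    o = np.asarray(origin, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    # any vector orthogonal to u
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    ang = math.radians(104.5)
    h1 = o + 0.0957 * u
    h2 = o + 0.0957 * (math.cos(ang) * u + math.sin(ang) * v)
    return np.array([o, h1, h2]), ["O", "H", "H"]


# ---------------------------------------------------------------------------
# advancing front
# ---------------------------------------------------------------------------


@dataclass
class FrontTrajectory:
    """Synthetic advancing-front trajectory plus its exact ground truth.

    ``truth_ice`` holds, per frame, a boolean mask over the water molecules
    (the first ``n_waters`` atoms of each frame); ``front_heights`` is the
    front z-position per frame.  If a chain is present its atoms follow the
    waters and ``topology`` indexes into the full configuration.

    ``truth_core_ice`` marks the subset of ice molecules whose four lattice
    bonds all connect to ice molecules present in the frame.  Molecules in
    the one-or-two outermost sublayers of a slab have incomplete neighbour
    shells, and no neighbour-geometry classifier can label them from the ice
    side alone; the core mask is therefore the sharpest label set a
    classifier can be held to exactly.
    """

    trajectory: Trajectory
    truth_ice: list[np.ndarray]
    truth_core_ice: list[np.ndarray]
    front_heights: list[float]
    n_waters: int
    topology: PolymerTopology | None = None
    spec: FrontTrajectorySpec | None = None

    def truth_ice_counts(self) -> np.ndarray:
        return np.array([int(m.sum()) for m in self.truth_ice])

    def truth_core_counts(self) -> np.ndarray:
        return np.array([int(m.sum()) for m in self.truth_core_ice])

    def truth_surface_z(self) -> np.ndarray:
        """Per-frame ground-truth surface height: the top of the core-ice
        region (falls back to the top ice site when no core exists)."""
        out = []
        for frame, core, ice in zip(self.trajectory, self.truth_core_ice, self.truth_ice):
            mask = core if core.any() else ice
            zs = frame.positions[: self.n_waters, 2][mask[: self.n_waters]]
            out.append(float(zs.max()) if len(zs) else float("nan"))
        return np.array(out)


def build_front_trajectory(spec: FrontTrajectorySpec) -> FrontTrajectory:
    """Generate frames of an ice slab growing upward into liquid.

    The ice occupies the bottom of the box; the front height rises by
    ``front_velocity`` each frame, converting lattice sites below it to ice
    (lattice position + fresh thermal jitter) while everything above is
    re-drawn as excluded-volume liquid kept ``ice_clearance`` away from the
    ice.  Water identity is conserved: site *j* of the extended lattice is
    always atom *j*; while still liquid its position is random.
    """
    rng = np.random.default_rng(spec.seed)
    slab = build_ice_lattice(spec.slab_spec)
    cell = _cell_dimensions(spec.slab_spec.phase, spec.slab_spec.oo_distance)
    nx, ny, nz = spec.slab_spec.n_cells
    h0 = nz * cell[2]
    h_final = h0 + spec.front_velocity * (spec.n_frames - 1)

    # extend the lattice upward far enough to host all future ice
    nz_ext = nz + int(math.ceil(max(h_final - h0, 0.0) / cell[2] + 1e-9))
    ext = build_ice_lattice(
        LatticeSpec(spec.slab_spec.phase, (nx, ny, nz_ext), spec.slab_spec.oo_distance)
    )
    site_pos = ext.positions
    eps = 1e-9
    site_pos = site_pos[site_pos[:, 2] < h_final - eps]

    liquid_depth = spec.n_liquid / (spec.liquid_density * cell[0] * nx * cell[1] * ny)
    box = np.array(
        [cell[0] * nx, cell[1] * ny, h_final + liquid_depth + 2.5 * spec.ice_clearance]
    )
    if h_final + spec.ice_clearance >= box[2]:
        raise ValueError("front leaves the box before the trajectory ends")

    # optional chain, laterally centred, placed relative to the initial front
    chain_pos = None
    topo = None
    if spec.chain is not None:
        chain_cfg, topo = build_chain(spec.chain)
        p = chain_cfg.positions.copy()
        p -= p.mean(axis=0)
        p[:, 0] += box[0] / 2.0
        p[:, 1] += box[1] / 2.0
        placement = spec.chain_placement
        if placement == "above_surface":
            p[:, 2] += h0 + spec.chain_clearance - p[:, 2].min()
        elif placement == "engulfed":
            # fully below the surface layer (not just below the front height)
            p[:, 2] += h0 - 0.5 - p[:, 2].max()
        else:
            _, depth = placement
            p[:, 2] += h0 - depth - p[:, 2].min()
        if p[:, 2].min() < 0 or p[:, 2].max() > box[2]:
            raise ValueError("chain does not fit inside the box at this placement")
        chain_pos = p
        # carve out lattice sites overlapping the chain
        tree = cKDTree(wrap_positions(chain_pos, box), boxsize=box)
        d, _ = tree.query(site_pos, k=1)
        site_pos = site_pos[d >= 0.25]

    n_sites = len(site_pos)
    n_waters = n_sites + spec.n_liquid

    # lattice bond adjacency among the kept sites (cutoff 1.2 d)
    site_tree = cKDTree(wrap_positions(site_pos, box), boxsize=box)
    bond_pairs = site_tree.query_pairs(1.2 * spec.slab_spec.oo_distance, output_type="ndarray")
    adjacency: list[list[int]] = [[] for _ in range(n_sites)]
    for a, b in bond_pairs:
        adjacency[a].append(b)
        adjacency[b].append(a)

    frames: list[Configuration] = []
    truth: list[np.ndarray] = []
    truth_core: list[np.ndarray] = []
    heights: list[float] = []

    for t in range(spec.n_frames):
        h = h0 + spec.front_velocity * t
        heights.append(h)
        ice_mask_sites = site_pos[:, 2] < h - eps
        positions = np.empty((n_waters, 3))
        positions[:n_sites] = site_pos
        if spec.thermal_jitter > 0:
            positions[:n_sites][ice_mask_sites] += rng.normal(
                0.0, spec.thermal_jitter, (int(ice_mask_sites.sum()), 3)
            )
        # liquid: pending (not yet frozen) sites + the extra liquid budget
        liquid_idx = np.concatenate(
            [np.flatnonzero(~ice_mask_sites), np.arange(n_sites, n_waters)]
        )
        exclude = positions[:n_sites][ice_mask_sites]
        if chain_pos is not None:
            exclude = np.vstack([exclude, chain_pos])
        liq = _pack(
            box,
            len(liquid_idx),
            spec.liquid_min_dist,
            rng,
            z_range=(h + spec.ice_clearance, box[2] - spec.ice_clearance),
            exclude=exclude,
            exclude_dist=spec.ice_clearance,
        )
        positions[liquid_idx] = liq

        mask = np.zeros(n_waters, dtype=bool)
        mask[:n_sites] = ice_mask_sites
        truth.append(mask)
        core = np.zeros(n_waters, dtype=bool)
        for j in np.flatnonzero(ice_mask_sites):
            nbrs = adjacency[j]
            if len(nbrs) == 4 and all(ice_mask_sites[nb] for nb in nbrs):
                core[j] = True
        truth_core.append(core)

        all_pos = positions
        frame_names = ["O"] * n_waters
        resids = np.zeros(n_waters, dtype=int)
        if chain_pos is not None:
            all_pos = np.vstack([positions, chain_pos])
            frame_names = frame_names + list(
                np.asarray(_chain_names(spec.chain.n_residues))
            )
            resids = np.concatenate([resids, _chain_resids(spec.chain.n_residues) + 1])
        frames.append(
            Configuration(wrap_positions(all_pos, box), box, names=frame_names, resids=resids)
        )

    shifted_topo = topo.shifted(n_waters) if topo is not None else None
    return FrontTrajectory(
        trajectory=Trajectory(frames),
        truth_ice=truth,
        truth_core_ice=truth_core,
        front_heights=heights,
        n_waters=n_waters,
        topology=shifted_topo,
        spec=spec,
    )


def _chain_names(n_residues: int) -> list[str]:
    return [a for _ in range(n_residues) for a in _RESIDUE_ATOMS]


def _chain_resids(n_residues: int) -> np.ndarray:
    return np.array([i for i in range(n_residues) for _ in _RESIDUE_ATOMS], dtype=int)
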