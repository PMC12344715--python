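"""Ice-binding metrics for polymer chains at an advancing ice front.

Everything here operates on a classified frame: a :class:`Configuration`,
its :class:`PhaseLabels` (after both interface corrections), and the chain's
:class:`PolymerTopology`.

* a -CH2 carbon is *attached* when at least six ice-phase molecules — one
  hexatomic surface ring — lie within 0.55 nm (the first solvation shell);
* the *ice surface height* z_ice is the mean z of the topmost ice layer;
* the *embedded depth* is z_chain_min - z_ice (negative = dips into ice);
* a chain is *bound* when it has an attached -CH2 and is not engulfed,
  *engulfed* when >= 90% of its heavy atoms lie below z_ice;
* the *coverage area* rasterizes the bound chain's heavy atoms onto the
  lateral plane as periodic disks of radius 0.5 nm;
* hydrogen bonds use the geometric donor-acceptor < 0.35 nm,
  hydrogen-donor-acceptor angle < 30 degrees criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Configuration, PhaseLabels, Phase, minimum_image, wrap_positions
from .topology import PolymerTopology

__all__ = [
    "BindingParams",
    "SurfaceModel",
    "BindingRecord",
    "ch2_attachment",
    "ice_surface_z",
    "embedded_depth",
    "binding_state",
    "coverage_area",
    "hydrogen_bonds",
    "binding_record",
]


@dataclass
class BindingParams:
    """Thresholds of the binding metrics (defaults as used throughout)."""

    r_attach: float = 0.55  # nm, first solvation shell of a -CH2 carbon
    min_ice_attach: int = 6  # a hexatomic ring
    surface_layer: float = 0.3  # nm window below the top ice z
    surface_z_floor: float = 0.0  # exclude restraint-side ice below this z
    engulf_fraction: float = 0.9  # heavy atoms below z_ice
    atomic_radius: float = 0.5  # nm, coverage disks
    grid_res: float = 0.02  # nm, coverage raster
    r_hbond: float = 0.35  # nm donor-acceptor
    hbond_angle: float = 30.0  # degrees, H-D-A
    coverage_resistance_threshold: float = 3.3  # nm^2, reporting threshold


@dataclass
class SurfaceModel:
    """Per-frame ice-surface height along z."""

    z_ice: float
    method: str = "top_layer_mean"
    grid: np.ndarray | None = None  # optional lateral per-cell maxima


@dataclass
class BindingRecord:
    frame: int
    chain: str
    n_ch2_attached: int
    embedded_depth: float
    state: str  # unbound | bound | engulfed
    coverage_area: float
    hbond_water: int = 0
    hbond_ice: int = 0


def ch2_attachment(
    config: Configuration,
    labels: PhaseLabels,
    topology: PolymerTopology,
    params: BindingParams | None = None,
) -> tuple[int, np.ndarray]:
    """Count attached -CH2 carbons (N_CH2) for one chain.

    Returns the count and a boolean mask over ``topology.ch2_carbons``.
    """
    params = params or BindingParams()
    if len(topology.ch2_carbons) == 0:
        raise ValueError("topology lists no -CH2 carbons")
    ice_idx = np.flatnonzero(labels.is_ice)
    if len(ice_idx) == 0:
        return 0, np.zeros(len(topology.ch2_carbons), dtype=bool)
    pos = config.positions
    if config.box is not None:
        pos = wrap_positions(pos, config.box)
    tree = cKDTree(pos[ice_idx], boxsize=config.box)
    counts = np.array(
        [
            np.sum(np.asarray(tree.query(pos[c], k=min(params.min_ice_attach, len(ice_idx)))[0]) < params.r_attach)
            for c in topology.ch2_carbons
        ]
    )
    attached = counts >= params.min_ice_attach
    return int(attached.sum()), attached


def ice_surface_z(
    labels: PhaseLabels,
    config: Configuration,
    params: BindingParams | None = None,
    method: str = "top_layer_mean",
    grid_cells: tuple[int, int] = (8, 8),
) -> SurfaceModel:
    """Locate the ice surface along z.

    ``top_layer_mean`` (default): mean z over ice molecules within
    ``surface_layer`` of the per-frame maximum ice z, ignoring ice below
    ``surface_z_floor`` (the restrained bottom of the slab).  ``grid``
    additionally records per-lateral-cell maxima.
    """
    params = params or BindingParams()
    ice = labels.is_ice
    if not np.any(ice):
        raise ValueError("no ice present; surface undefined")
    pos = config.positions
    if config.box is not None:
        pos = wrap_positions(pos, config.box)
    z = pos[ice, 2]
    zsel = z[z >= params.surface_z_floor]
    if len(zsel) == 0:
        raise ValueError("no ice above surface_z_floor")
    ztop = zsel.max()
    layer = zsel[zsel >= ztop - params.surface_layer]
    z_ice = float(layer.mean())
    grid = None
    if method == "grid":
        if config.box is None:
            raise ValueError("grid surface method requires a box")
        xy = pos[ice][z >= params.surface_z_floor][:, :2]
        gx, gy = grid_cells
        ix = np.floor(xy[:, 0] / config.box[0] * gx).astype(int) % gx
        iy = np.floor(xy[:, 1] / config.box[1] * gy).astype(int) % gy
        grid = np.full((gx, gy), -np.inf)
        np.maximum.at(grid, (ix, iy), zsel)
    return SurfaceModel(z_ice=z_ice, method=method, grid=grid)


def embedded_depth(
    config: Configuration, topology: PolymerTopology, surface: SurfaceModel
) -> float:
    """z_chain - z_ice with z_chain the minimum z over the chain's atoms;
    negative values mean the chain dips below the ice surface."""
    if len(topology.heavy_atoms) == 0:
        raise ValueError("empty chain")
    z_min = float(config.positions[topology.heavy_atoms, 2].min())
    return z_min - surface.z_ice


def binding_state(
    config: Configuration,
    labels: PhaseLabels,
    topology: PolymerTopology,
    surface: SurfaceModel,
    params: BindingParams | None = None,
    n_ch2: int | None = None,
) -> str:
    """Classify the chain as unbound, bound, or engulfed.

    Engulfed: >= ``engulf_fraction`` of heavy atoms below z_ice.
    Bound: at least one attached -CH2 carbon and not engulfed.
    """
    params = params or BindingParams()
    if n_ch2 is None:
        n_ch2, _ = ch2_attachment(config, labels, topology, params)
    z = config.positions[topology.heavy_atoms, 2]
    below = float(np.mean(z < surface.z_ice))
    if below >= params.engulf_fraction:
        return "engulfed"
    if n_ch2 >= 1:
        return "bound"
    return "unbound"


def coverage_area(
    config: Configuration,
    topology: PolymerTopology,
    params: BindingParams | None = None,
    atom_indices=None,
) -> float:
    """Lateral coverage area (nm^2) of the chain's heavy atoms.

    Heavy-atom positions are projected onto the xy-plane and rasterized as
    disks of ``atomic_radius`` on a periodic grid of spacing ``grid_res``;
    the area is the number of occupied cells times the cell area.  Callers
    are expected to pass only chains currently bound to the ice (an unbound
    chain covers nothing); ``atom_indices`` overrides the default heavy-atom
    selection.
    """
    params = params or BindingParams()
    if config.box is None:
        raise ValueError("coverage area requires a periodic box")
    if params.grid_res <= 0:
        raise ValueError("grid_res must be positive")
    if params.grid_res > params.atomic_radius:
        raise ValueError("grid_res larger than the atomic radius")
    idx = topology.heavy_atoms if atom_indices is None else np.asarray(atom_indices, int)
    if len(idx) == 0:
        return 0.0
    lx, ly = float(config.box[0]), float(config.box[1])
    nx = max(int(round(lx / params.grid_res)), 1)
    ny = max(int(round(ly / params.grid_res)), 1)
    hx, hy = lx / nx, ly / ny
    xy = wrap_positions(config.positions[idx], config.box)[:, :2]
    occupied = np.zeros((nx, ny), dtype=bool)
    r = params.atomic_radius
    # rasterize each disk over its bounding cell window (periodic wrap)
    kx = int(np.ceil(r / hx)) + 1
    ky = int(np.ceil(r / hy)) + 1
    for x, y in xy:
        cx = int(np.floor(x / hx))
        cy = int(np.floor(y / hy))
        ix = (np.arange(cx - kx, cx + kx + 1)) % nx
        iy = (np.arange(cy - ky, cy + ky + 1)) % ny
        # cell-centre coordinates relative to the atom, minimum image
        xc = (np.arange(cx - kx, cx + kx + 1) + 0.5) * hx - x
        yc = (np.arange(cy - ky, cy + ky + 1) + 0.5) * hy - y
        xc -= lx * np.round(xc / lx)
        yc -= ly * np.round(yc / ly)
        mask = (xc[:, None] ** 2 + yc[None, :] ** 2) <= r * r
        occupied[np.ix_(ix, iy)] |= mask
    return float(occupied.sum()) * hx * hy


def hydrogen_bonds(
    config: Configuration,
    donors: dict[int, list[int]],
    acceptors: np.ndarray,
    params: BindingParams | None = None,
    labels: PhaseLabels | None = None,
    acceptor_molecule: np.ndarray | None = None,
) -> tuple[int, list[tuple[int, int, int]], dict[str, int]]:
    """Geometric hydrogen bonds: D-A distance < 0.35 nm, H-D-A angle < 30 deg.

    ``donors`` maps donor atom index -> attached hydrogen indices.  Returns
    the total count, the (donor, hydrogen, acceptor) triples, and a partition
    of the count by acceptor phase (``water`` vs ``ice``) when ``labels`` and
    ``acceptor_molecule`` (acceptor atom -> water molecule index) are given.
    """
    params = params or BindingParams()
    acceptors = np.asarray(acceptors, dtype=int)
    pairs: list[tuple[int, int, int]] = []
    partition = {"water": 0, "ice": 0, "other": 0}
    if len(acceptors) == 0 or not donors:
        return 0, pairs, partition
    pos = config.positions
    box = config.box
    acc_pos = pos[acceptors]
    tree = cKDTree(wrap_positions(acc_pos, box) if box is not None else acc_pos, boxsize=box)
    cos_cut = np.cos(np.radians(params.hbond_angle))
    for d_idx, h_list in donors.items():
        if not h_list:
            raise ValueError(f"donor {d_idx} has no hydrogen")
        d = pos[d_idx]
        near = tree.query_ball_point(
            wrap_positions(d[None, :], box)[0] if box is not None else d, params.r_hbond
        )
        for a_local in near:
            a_idx = int(acceptors[a_local])
            if a_idx == d_idx:
                continue
            da = minimum_image(pos[a_idx] - d, box)
            r_da = np.linalg.norm(da)
            if not (0 < r_da < params.r_hbond):
                continue
            for h_idx in h_list:
                dh = minimum_image(pos[h_idx] - d, box)
                ndh = np.linalg.norm(dh)
                if ndh == 0:
                    continue
                cosang = (dh @ da) / (ndh * r_da)
                if cosang > cos_cut:  # angle strictly below the cutoff
                    pairs.append((d_idx, h_idx, a_idx))
                    key = "other"
                    if labels is not None and acceptor_molecule is not None:
                        mol = int(acceptor_molecule[a_local])
                        if 0 <= mol < labels.n_molecules:
                            key = "ice" if labels.is_ice[mol] else "water"
                    partition[key] += 1
                    break  # one bond per donor-acceptor pair
    return len(pairs), pairs, partition


def binding_record(
    frame: int,
    config: Configuration,
    labels: PhaseLabels,
    topology: PolymerTopology,
    params: BindingParams | None = None,
) -> BindingRecord:
    """Full per-frame binding summary for one chain."""
    params = params or BindingParams()
    surface = ice_surface_z(labels, config, params)
    n_ch2, _ = ch2_attachment(config, labels, topology, params)
    state = binding_state(config, labels, topology, surface, params, n_ch2=n_ch2)
    depth = embedded_depth(config, topology, surface)
    area = coverage_area(config, topology, params) if state == "bound" else 0.0
    return BindingRecord(
        frame=frame,
        chain=topology.chain_id,
        n_ch2_attached=n_ch2,
        embedded_depth=depth,
        state=state,
        coverage_area=area,
    )


def binding_table(records: list[BindingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": r.frame,
                "chain": r.chain,
                "n_ch2": r.n_ch2_attached,
                "depth_nm": r.embedded_depth,
                "state": r.state,
                "coverage_nm2": r.coverage_area,
                "hbond_water": r.hbond_water,
                "hbond_ice": r.hbond_ice,
            }
            for r in records
        ]
    )
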