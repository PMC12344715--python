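"""Shared fixtures: small lattices, chains, and an independent brute-force
phase-classification oracle (closed-form spherical harmonics, O(N^2)
neighbour search, explicit loops) used to cross-check the production path."""

from __future__ import annotations

import math

import numpy as np
import pytest

from icebind import (
    ChainSpec,
    LatticeSpec,
    Phase,
    build_chain,
    build_ice_lattice,
)
from icebind.metad import (
    DoubleWell,
    WTMetaDParams,
    replicate_average,
    tiwary_reweight,
    wtmetad_run,
)


@pytest.fixture(scope="session")
def ih_222():
    return build_ice_lattice(LatticeSpec("Ih", (2, 2, 2)))


@pytest.fixture(scope="session")
def ic_222():
    return build_ice_lattice(LatticeSpec("Ic", (2, 2, 2)))


@pytest.fixture(scope="session")
def ppii_chain_8():
    return build_chain(ChainSpec(8))


# ---------------------------------------------------------------------------
# brute-force oracle (independent of icebind.chillplus)
# ---------------------------------------------------------------------------


def _y3m(m: int, v: np.ndarray) -> complex:
    """Closed-form Y_3^m (Condon-Shortley) for a unit vector."""
    x, y, z = v
    ct = z
    st = math.sqrt(max(0.0, 1.0 - z * z))
    phi = math.atan2(y, x)
    e = lambda k: complex(math.cos(k * phi), math.sin(k * phi))  # noqa: E731
    if m == 0:
        return math.sqrt(7.0 / (16.0 * math.pi)) * (5 * ct**3 - 3 * ct)
    if m == 1:
        return -0.125 * math.sqrt(21.0 / math.pi) * st * (5 * ct * ct - 1) * e(1)
    if m == -1:
        return 0.125 * math.sqrt(21.0 / math.pi) * st * (5 * ct * ct - 1) * e(-1)
    if m == 2:
        return 0.25 * math.sqrt(105.0 / (2.0 * math.pi)) * st * st * ct * e(2)
    if m == -2:
        return 0.25 * math.sqrt(105.0 / (2.0 * math.pi)) * st * st * ct * e(-2)
    if m == 3:
        return -0.125 * math.sqrt(35.0 / math.pi) * st**3 * e(3)
    if m == -3:
        return 0.125 * math.sqrt(35.0 / math.pi) * st**3 * e(-3)
    raise ValueError(m)


def _min_image(d: np.ndarray, box) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def oracle_labels(config) -> np.ndarray:
    """Naive raw CHILL+ labels: full O(N^2) distances, explicit loops."""
    pos = config.positions
    box = config.box
    n = len(pos)
    neigh = []
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i:
                continue
            d = _min_image(pos[j] - pos[i], box)
            cand.append((round(float(np.linalg.norm(d)), 12), j, d))
        cand.sort(key=lambda t: (t[0], t[1]))
        neigh.append(cand[:4])
    q = np.zeros((n, 7), dtype=complex)
    for i in range(n):
        for _, _, d in neigh[i]:
            u = d / np.linalg.norm(d)
            for k, m in enumerate(range(-3, 4)):
                q[i, k] += _y3m(m, u)
    labels = np.full(n, int(Phase.LIQUID))
    for i in range(n):
        ns = ne = 0
        for _, j, _ in neigh[i]:
            c = float(
                np.real(np.sum(q[i] * np.conj(q[j])))
                / (np.linalg.norm(q[i]) * np.linalg.norm(q[j]))
            )
            if c <= -0.8:
                ns += 1
            elif -0.35 <= c <= 0.25:
                ne += 1
        if ns == 4:
            labels[i] = int(Phase.CUBIC_ICE)
        elif ns == 3 and ne == 1:
            labels[i] = int(Phase.HEX_ICE)
        elif ns == 2 or (ns == 3 and ne == 0):
            labels[i] = int(Phase.INTERFACIAL_ICE)
    return labels


# ---------------------------------------------------------------------------
# double-well replicas shared by the metadynamics acceptance checks
# ---------------------------------------------------------------------------

T5_PARAMS = WTMetaDParams(W=1.0, sigma=0.1, gamma=20.0, stride=500, T=300.0)
T5_GRID = np.linspace(-1.6, 1.6, 65)
T5_STEPS = 4_000_000


def run_double_well_replicas(seed: int, n_steps: int = T5_STEPS):
    """Three independently seeded WTMetaD replicas on the 10 kJ/mol double
    well, reweighted on the common reporting grid."""
    well = DoubleWell(barrier=10.0)
    profiles = []
    for k in (1, 2, 3):
        trace, bias = wtmetad_run(
            well, T5_PARAMS, n_steps=n_steps, seed=seed * 1000 + k, sample_stride=2
        )
        profiles.append(tiwary_reweight(trace, bias, T5_PARAMS, T5_GRID))
    return profiles, replicate_average(profiles)


@pytest.fixture(scope="session")
def double_well_replicas():
    return run_double_well_replicas(seed=1)
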