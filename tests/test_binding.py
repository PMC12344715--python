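"""Binding metrics: attachment, surface, depth, state, coverage, H-bonds."""

import math

import numpy as np
import pytest

from icebind import (
    BindingParams,
    ChainSpec,
    Configuration,
    LatticeSpec,
    Phase,
    PhaseLabels,
    SurfaceModel,
    binding_record,
    binding_state,
    build_front_trajectory,
    build_ice_lattice,
    ch2_attachment,
    classify,
    coverage_area,
    embedded_depth,
    hydrogen_bonds,
    ice_surface_z,
    minimum_image,
)
from icebind.systems import FrontTrajectorySpec, make_water
from icebind.topology import PolymerTopology


def hex_labels(n, ice_idx):
    arr = np.full(n, int(Phase.LIQUID))
    arr[list(ice_idx)] = int(Phase.HEX_ICE)
    return PhaseLabels(arr)


def carbon_topology(idx, n_extra=0):
    return PolymerTopology(
        chain_id="P",
        heavy_atoms=np.array([idx] + list(range(idx + 1, idx + 1 + n_extra))),
        ch2_carbons=np.array([idx]),
    )


class TestAttachment:
    def _ring_config(self, n_ring):
        # n_ring 'ice' oxygens on a 0.45 nm-radius ring, carbon 0.2 nm above
        box = np.ones(3) * 4.0
        ang = np.linspace(0, 2 * math.pi, n_ring, endpoint=False)
        ring = np.stack([2 + 0.45 * np.cos(ang), 2 + 0.45 * np.sin(ang), np.full(n_ring, 2.0)], axis=1)
        carbon = np.array([[2.0, 2.0, 2.2]])
        cfg = Configuration(np.vstack([ring, carbon]), box)
        labels = hex_labels(cfg.n_atoms, range(n_ring))
        topo = carbon_topology(n_ring)
        return cfg, labels, topo

    def test_hexatomic_ring_attaches(self):
        cfg, labels, topo = self._ring_config(6)
        n, mask = ch2_attachment(cfg, labels, topo)
        assert n == 1 and mask[0]

    def test_five_ice_not_attached(self):
        cfg, labels, topo = self._ring_config(5)
        n, _ = ch2_attachment(cfg, labels, topo)
        assert n == 0

    def test_chain_far_in_liquid_zero(self, front):
        frame = front.trajectory[0]
        labels = classify(frame)
        # a probe carbon high above the front, pure liquid around
        pos = np.vstack([frame.positions, [[1.0, 1.0, frame.box[2] - 0.2]]])
        cfg = Configuration(pos, frame.box)
        full = PhaseLabels(np.append(labels.labels, int(Phase.LIQUID)))
        topo = carbon_topology(frame.n_atoms)
        n, _ = ch2_attachment(cfg, full, topo)
        assert n == 0

    def test_matches_bruteforce_pairwise_oracle(self, front):
        frame = front.trajectory[1]
        labels = classify(frame)
        rng = np.random.default_rng(3)
        probes = rng.random((12, 3)) * frame.box
        pos = np.vstack([frame.positions, probes])
        cfg = Configuration(pos, frame.box)
        full = PhaseLabels(
            np.append(labels.labels, np.full(12, int(Phase.LIQUID)))
        )
        topo = PolymerTopology(
            chain_id="P",
            heavy_atoms=np.arange(frame.n_atoms, frame.n_atoms + 12),
            ch2_carbons=np.arange(frame.n_atoms, frame.n_atoms + 12),
        )
        _, mask = ch2_attachment(cfg, full, topo)
        ice_pos = frame.positions[labels.is_ice]
        for probe, attached in zip(probes, mask):
            d = np.linalg.norm(minimum_image(ice_pos - probe, frame.box), axis=1)
            assert attached == (np.sum(d < 0.55) >= 6)


@pytest.fixture(scope="module")
def front():
    spec = FrontTrajectorySpec(
        LatticeSpec("Ih", (3, 3, 2)), n_liquid=120, n_frames=3, front_velocity=0.15, seed=8
    )
    return build_front_trajectory(spec)


class TestSurface:
    def test_flat_slab_top_layer_mean_exact(self):
        slab = build_ice_lattice(LatticeSpec("Ih", (2, 2, 2)))
        box = slab.box.copy()
        box[2] += 2.0
        cfg = Configuration(slab.positions, box)
        labels = hex_labels(cfg.n_atoms, range(cfg.n_atoms))
        z = slab.positions[:, 2]
        expect = z[z >= z.max() - 0.3].mean()
        model = ice_surface_z(labels, cfg)
        assert model.z_ice == pytest.approx(expect, abs=1e-12)

    def test_translation_equivariance(self):
        slab = build_ice_lattice(LatticeSpec("Ih", (2, 2, 1)))
        box = slab.box.copy()
        box[2] += 3.0
        cfg = Configuration(slab.positions, box)
        labels = hex_labels(cfg.n_atoms, range(cfg.n_atoms))
        z0 = ice_surface_z(labels, cfg).z_ice
        shifted = Configuration(slab.positions + [0, 0, 0.7], box)
        z1 = ice_surface_z(labels, shifted).z_ice
        assert z1 - z0 == pytest.approx(0.7, abs=1e-9)

    def test_tracks_synthetic_front(self, front):
        truth = front.truth_surface_z()
        for t, frame in enumerate(front.trajectory):
            labels = classify(frame)
            z = ice_surface_z(labels, frame).z_ice
            assert abs(z - truth[t]) <= 0.15

    def test_no_ice_raises(self):
        cfg = Configuration(np.random.default_rng(0).random((10, 3)), np.ones(3) * 3)
        labels = PhaseLabels(np.full(10, int(Phase.LIQUID)))
        with pytest.raises(ValueError):
            ice_surface_z(labels, cfg)


class TestDepthAndState:
    def test_depth_arithmetic(self):
        cfg = Configuration(np.array([[1.0, 1.0, 2.3], [1.0, 1.0, 2.8]]), np.ones(3) * 5)
        topo = PolymerTopology("P", heavy_atoms=np.array([0, 1]), ch2_carbons=np.array([0]))
        assert embedded_depth(cfg, topo, SurfaceModel(2.0)) == pytest.approx(0.3)
        assert embedded_depth(cfg, topo, SurfaceModel(2.5)) == pytest.approx(-0.2)

    def test_generator_embedded_depth(self):
        spec = FrontTrajectorySpec(
            LatticeSpec("Ih", (4, 3, 2)),
            n_liquid=120,
            n_frames=1,
            chain=ChainSpec(4),
            chain_placement=("embedded", 0.4),
            seed=6,
        )
        ft = build_front_trajectory(spec)
        frame = ft.trajectory[0]
        # against the generator's nominal front height the placement is exact
        depth = embedded_depth(frame, ft.topology, SurfaceModel(ft.front_heights[0]))
        assert depth == pytest.approx(-0.4, abs=1e-9)

    def test_unbound_bound_engulfed(self):
        slab = build_ice_lattice(LatticeSpec("Ih", (2, 2, 1)))
        box = slab.box.copy()
        box[2] += 3.0
        labels = hex_labels(slab.n_atoms + 1, range(slab.n_atoms))
        top = slab.positions[:, 2].max()
        surface = SurfaceModel(top)
        # far liquid probe: unbound
        cfg = Configuration(np.vstack([slab.positions, [[0.5, 0.5, top + 2.0]]]), box)
        topo = carbon_topology(slab.n_atoms)
        assert binding_state(cfg, labels, topo, surface) == "unbound"
        # probe resting on the surface ring: bound
        ring_atom = slab.positions[np.argmax(slab.positions[:, 2])]
        cfg2 = Configuration(np.vstack([slab.positions, [ring_atom + [0, 0, 0.3]]]), box)
        assert binding_state(cfg2, labels, topo, surface) == "bound"
        # probe deep inside the slab: engulfed
        cfg3 = Configuration(np.vstack([slab.positions, [[0.4, 0.4, 0.2]]]), box)
        assert binding_state(cfg3, labels, topo, surface) == "engulfed"

    def test_generator_engulfed_placement(self):
        spec = FrontTrajectorySpec(
            LatticeSpec("Ih", (4, 3, 3)),
            n_liquid=120,
            n_frames=1,
            chain=ChainSpec(4),
            chain_placement="engulfed",
            seed=6,
        )
        ft = build_front_trajectory(spec)
        frame = ft.trajectory[0]
        water = np.arange(ft.n_waters)
        labels_w = classify(Configuration(frame.positions[water], frame.box))
        full = np.full(frame.n_atoms, int(Phase.LIQUID))
        full[water] = labels_w.labels
        rec = binding_record(0, frame, PhaseLabels(full), ft.topology)
        assert rec.state == "engulfed"

    def test_engulfment_transition_at_predicted_frame(self):
        spec = FrontTrajectorySpec(
            LatticeSpec("Ih", (4, 3, 2)),
            n_liquid=150,
            n_frames=10,
            front_velocity=0.15,
            chain=ChainSpec(4),
            chain_placement="above_surface",
            seed=7,
        )
        ft = build_front_trajectory(spec)
        chain_z = ft.trajectory[0].positions[ft.topology.heavy_atoms, 2]
        z90 = np.quantile(chain_z, 0.9)
        truth_surface = ft.truth_surface_z()
        predicted = next(
            (t for t, zs in enumerate(truth_surface) if zs > z90), None
        )
        observed = None
        for t, frame in enumerate(ft.trajectory):
            water = np.arange(ft.n_waters)
            lw = classify(Configuration(frame.positions[water], frame.box))
            full = np.full(frame.n_atoms, int(Phase.LIQUID))
            full[water] = lw.labels
            rec = binding_record(t, frame, PhaseLabels(full), ft.topology)
            if rec.state == "engulfed":
                observed = t
                break
        assert predicted is not None and observed is not None
        assert abs(observed - predicted) <= 1


class TestCoverage:
    def _single_atom(self, box=3.0):
        cfg = Configuration(np.array([[1.5, 1.5, 1.0]]), np.ones(3) * box)
        topo = PolymerTopology("P", heavy_atoms=np.array([0]), ch2_carbons=np.array([0]))
        return cfg, topo

    def test_single_disk_area(self):
        cfg, topo = self._single_atom()
        area = coverage_area(cfg, topo)
        assert area == pytest.approx(math.pi * 0.5**2, rel=0.02)

    def test_disjoint_disks_additive(self):
        cfg = Configuration(np.array([[1.0, 1.5, 1.0], [2.2, 1.5, 1.0]]), np.ones(3) * 4.0)
        topo = PolymerTopology("P", heavy_atoms=np.array([0, 1]), ch2_carbons=np.array([0]))
        area = coverage_area(cfg, topo)
        assert area == pytest.approx(2 * math.pi * 0.25, rel=0.02)

    def test_no_atoms_zero(self):
        cfg, _ = self._single_atom()
        topo = PolymerTopology("P", heavy_atoms=np.empty(0, int), ch2_carbons=np.array([0]))
        assert coverage_area(cfg, topo) == 0.0

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        box = np.ones(3) * 2.0
        pts = rng.random((30, 3)) * box
        areas = []
        for k in (5, 15, 30):
            cfg = Configuration(pts[:k], box)
            topo = PolymerTopology("P", heavy_atoms=np.arange(k), ch2_carbons=np.array([0]))
            areas.append(coverage_area(cfg, topo))
        assert areas[0] <= areas[1] <= areas[2]
        assert areas[2] <= box[0] * box[1] + 1e-9

    def test_xy_translation_invariance(self):
        cfg, topo = self._single_atom()
        a0 = coverage_area(cfg, topo)
        shifted = Configuration(cfg.positions + [0.71, -0.33, 0.0], cfg.box)
        a1 = coverage_area(shifted, topo)
        assert a1 == pytest.approx(a0, rel=0.01)

    def test_grid_coarser_than_radius_rejected(self):
        cfg, topo = self._single_atom()
        with pytest.raises(ValueError):
            coverage_area(cfg, topo, BindingParams(grid_res=0.6))


class TestHydrogenBonds:
    def _dha(self, r_da, angle_deg):
        # donor at origin with one H; acceptor at distance r_da; the H is
        # placed so the H-D-A angle equals angle_deg
        d = np.array([1.0, 1.0, 1.0])
        a = d + np.array([r_da, 0.0, 0.0])
        ang = math.radians(angle_deg)
        h = d + 0.1 * np.array([math.cos(ang), math.sin(ang), 0.0])
        cfg = Configuration(np.array([d, h, a]), np.ones(3) * 5.0)
        return cfg

    def test_collinear_bond_counts(self):
        cfg = self._dha(0.29, 0.0)
        n, pairs, _ = hydrogen_bonds(cfg, {0: [1]}, np.array([2]))
        assert n == 1 and pairs == [(0, 1, 2)]

    def test_long_distance_rejected(self):
        cfg = self._dha(0.36, 0.0)
        n, _, _ = hydrogen_bonds(cfg, {0: [1]}, np.array([2]))
        assert n == 0

    def test_wide_angle_rejected(self):
        cfg = self._dha(0.29, 35.0)
        n, _, _ = hydrogen_bonds(cfg, {0: [1]}, np.array([2]))
        assert n == 0

    def test_donor_without_hydrogen_rejected(self):
        cfg = self._dha(0.29, 0.0)
        with pytest.raises(ValueError):
            hydrogen_bonds(cfg, {0: []}, np.array([2]))

    def test_partition_by_acceptor_phase(self):
        w, _ = make_water((1.0, 1.0, 1.0))
        # two acceptor oxygens, one along each O-H direction: one
        # ice-labelled, one liquid
        oh2 = (w[2] - w[0]) / np.linalg.norm(w[2] - w[0])
        acc = np.array([[1.3, 1.0, 1.0], w[0] + 0.3 * oh2])
        pos = np.vstack([w, acc])
        cfg = Configuration(pos, np.ones(3) * 4.0)
        labels = PhaseLabels(
            np.array([int(Phase.LIQUID)] * 3 + [int(Phase.HEX_ICE), int(Phase.LIQUID)])
        )
        n, _, part = hydrogen_bonds(
            cfg,
            {0: [1, 2]},
            np.array([3, 4]),
            labels=labels,
            acceptor_molecule=np.array([3, 4]),
        )
        assert n == 2
        assert part["ice"] == 1 and part["water"] == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        box = np.ones(3) * 2.5
        n_w = 40
        pos_list, donors, acceptors = [], {}, []
        for i in range(n_w):
            p, _ = make_water(rng.random(3) * box, rng.normal(size=3))
            base = 3 * i
            pos_list.append(p)
            donors[base] = [base + 1, base + 2]
            acceptors.append(base)
        cfg = Configuration(np.vstack(pos_list), box)
        n, pairs, _ = hydrogen_bonds(cfg, donors, np.array(acceptors))
        # naive O(N^2): every donor-acceptor pair, every hydrogen
        expect = 0
        cos_cut = math.cos(math.radians(30.0))
        for d_idx, hs in donors.items():
            for a_idx in acceptors:
                if a_idx == d_idx:
                    continue
                da = minimum_image(cfg.positions[a_idx] - cfg.positions[d_idx], box)
                r = np.linalg.norm(da)
                if not 0 < r < 0.35:
                    continue
                for h_idx in hs:
                    dh = minimum_image(cfg.positions[h_idx] - cfg.positions[d_idx], box)
                    if dh @ da / (np.linalg.norm(dh) * r) > cos_cut:
                        expect += 1
                        break
        assert n == expect


class TestRigidMotionInvariance:
    def test_metrics_invariant_under_xy_translation_and_z_shift(self, front):
        frame = front.trajectory[1]
        labels = classify(frame)
        probe = frame.positions[np.argmax(frame.positions[:, 2] * labels.is_ice)] + [0, 0, 0.3]
        pos = np.vstack([frame.positions, probe[None, :]])
        cfg = Configuration(pos, frame.box)
        full = PhaseLabels(np.append(labels.labels, int(Phase.LIQUID)))
        topo = carbon_topology(frame.n_atoms)
        rec0 = binding_record(0, cfg, full, topo)

        shift = np.array([0.37, -0.61, 0.5])
        box2 = cfg.box.copy()
        box2[2] += 0.5  # keep the shifted system inside the box
        moved = Configuration(cfg.positions + shift, box2)
        # classify the moved waters from scratch: labels must be preserved
        lab2 = classify(Configuration(moved.positions[: frame.n_atoms], box2))
        full2 = PhaseLabels(np.append(lab2.labels, int(Phase.LIQUID)))
        rec1 = binding_record(0, moved, full2, topo)
        assert rec1.n_ch2_attached == rec0.n_ch2_attached
        assert rec1.embedded_depth == pytest.approx(rec0.embedded_depth, abs=1e-6)
        assert rec1.state == rec0.state
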