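"""Tunnel detection: free-radius field, cheapest-path search, metrics."""
import math

import numpy as np
import pytest

from sugarport.structure import Structure
from sugarport.synthetic import ChannelSpec, make_branching_channel, make_channel_structure
from sugarport.tunnels import (
    StartPointError,
    Tunnel,
    TunnelConfig,
    bottleneck_residues,
    find_tunnels,
    free_radius_field,
    throughput_from_cost,
    tunnel_metrics,
    tunnel_residue_set,
)


def _single_atom_structure():
    return Structure(
        atom_name=np.array(["CA", "CA"]),
        element=np.array(["S", "S"]),  # wider bbox for the hull
        res_seq=np.array([1, 4]),
        res_name=np.array(["GLY", "GLY"]),
        chain=np.array(["A", "A"]),
        coords=np.array([[0.0, 0.0, 0.0], [8.0, 8.0, 8.0]]),
        hetero=np.array([False, False]),
    )


class TestFreeRadiusField:
    def test_free_radius_arithmetic(self):
        s = _single_atom_structure()  # S atoms, vdW 1.8
        cfg = TunnelConfig(start_point=(4.0, 0.0, 0.0))
        field = free_radius_field(s, cfg)
        # node nearest (4, 0, 0): distance 4 from atom 1 -> free radius 2.2
        idx = field.start_index
        node = field.node_coords(idx)
        d = min(np.linalg.norm(node - s.coords[0]), np.linalg.norm(node - s.coords[1]))
        assert field.free_radius[idx] == pytest.approx(d - 1.8, abs=1e-9)

    def test_node_inside_atom_blocked(self):
        s = _single_atom_structure()
        cfg = TunnelConfig(start_point=(0.0, 0.0, 0.0))
        with pytest.raises(StartPointError, match="cavity"):
            free_radius_field(s, cfg)

    def test_cylinder_axis_matches_analytic_geometry(self, channel):
        structure, truth = channel
        cfg = TunnelConfig(start_point=truth["start_xyz"])
        field = free_radius_field(structure, cfg)
        h = field.spacing
        for z, expected in truth["axial_free_radius"][2:6]:
            # nearest on-axis grid node to (0, 0, z)
            idx = tuple(
                int(round((c - o) / h)) for c, o in zip((0.0, 0.0, z), field.origin)
            )
            assert field.free_radius[idx] == pytest.approx(expected, abs=h)


def _solid_slab():
    xs = np.arange(-6.0, 6.1, 1.5)
    pts = np.array([[x, y, z] for x in xs for y in xs for z in (0.0, 1.5, 3.0)])
    n = len(pts)
    return Structure(
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        res_seq=np.arange(1, n + 1),
        res_name=np.array(["GLY"] * n),
        chain=np.array(["A"] * n),
        coords=pts,
        hetero=np.zeros(n, dtype=bool),
    )


class TestFindTunnels:
    def test_straight_channel_single_cluster(self, channel, channel_tunnels):
        _, truth = channel
        assert len(channel_tunnels) == 1
        tunnel = channel_tunnels[0]
        assert tunnel.bottleneck_radius == pytest.approx(
            truth["bottleneck_radius"], abs=0.8
        )
        assert tunnel.curvature == pytest.approx(1.0, abs=1e-6)

    def test_solid_slab_no_tunnels(self):
        assert find_tunnels(_solid_slab(), TunnelConfig(start_point=(0, 0, 1.5))) == []

    def test_y_channel_two_clusters_shared_prefix(self):
        structure, truth = make_branching_channel(seed=3)
        tunnels = find_tunnels(structure, TunnelConfig(start_point=truth["start_xyz"]))
        assert len(tunnels) == truth["n_exits"] == 2
        a, b = tunnels[0].centers, tunnels[1].centers
        shared = 0
        for pa, pb in zip(a, b):
            if np.allclose(pa, pb):
                shared += 1
            else:
                break
        assert shared >= 5  # identical sphere prefix up to the branch point

    def test_sub_probe_branch_not_recovered(self):
        structure, truth = make_branching_channel(
            branch_angles_deg=(-55.0, 0.0, 55.0),
            branch_pinch_radii=(None, 2.3, None),
            seed=4,
        )
        tunnels = find_tunnels(structure, TunnelConfig(start_point=truth["start_xyz"]))
        assert len(tunnels) == truth["n_recoverable_exits"] == 2

    def test_cluster_count_stable_under_grid_spacing(self, channel):
        structure, truth = channel
        counts = []
        for h in (0.6, 0.8, 1.0):
            cfg = TunnelConfig(start_point=truth["start_xyz"], grid_spacing=h)
            counts.append(len(find_tunnels(structure, cfg)))
        assert counts == [1, 1, 1]

    def test_shrinking_probe_never_loses_exits(self, channel):
        structure, truth = channel
        wide = find_tunnels(
            structure, TunnelConfig(start_point=truth["start_xyz"], probe_radius=0.8)
        )
        narrow = find_tunnels(
            structure, TunnelConfig(start_point=truth["start_xyz"], probe_radius=0.5)
        )
        assert sum(t.cluster_size for t in narrow) >= sum(t.cluster_size for t in wide)

    def test_widening_pinch_increases_bottleneck(self):
        radii = []
        for pinch in (2.6, 3.0, 3.4):
            s, truth = make_channel_structure(ChannelSpec(seed=5, pinch_radius=pinch))
            tunnels = find_tunnels(s, TunnelConfig(start_point=truth["start_xyz"]))
            radii.append(tunnels[0].bottleneck_radius)
        assert radii[0] < radii[1] < radii[2]


class TestTunnelMetrics:
    def _line_spheres(self, n=5, r=1.0):
        return [(np.array([0.0, 0.0, float(i)]), r) for i in range(n)]

    def test_throughput_of_printed_cost(self):
        assert round(throughput_from_cost(3.227465), 6) == 0.039658

    def test_zero_cost_unit_throughput(self):
        throughput, r_b, length, curv = tunnel_metrics(self._line_spheres(), 0.0)
        assert throughput == 1.0
        assert r_b == 1.0
        assert length == pytest.approx(4.0)
        assert curv == pytest.approx(1.0)

    def test_semicircle_curvature(self):
        theta = np.linspace(0, math.pi, 200)
        radius = 10.0
        spheres = [
            (np.array([radius * math.cos(t), radius * math.sin(t), 0.0]), 1.0)
            for t in theta
        ]
        _, _, _, curv = tunnel_metrics(spheres, 1.0)
        assert curv == pytest.approx(math.pi / 2, abs=1e-3)

    def test_coincident_endpoints_error(self):
        spheres = [(np.zeros(3), 1.0), (np.zeros(3), 1.0)]
        with pytest.raises(ValueError, match="curvature"):
            tunnel_metrics(spheres, 0.5)

    def test_log_throughput_identity(self):
        rng = np.random.default_rng(0)
        for cost in rng.uniform(0, 10, size=20):
            assert math.log(throughput_from_cost(cost)) == pytest.approx(
                -cost, abs=1e-12
            )


class TestBottleneckResidues:
    def test_pinch_ring_recovered(self, channel, channel_tunnels):
        _, truth = channel
        labels = {r.label for r in channel_tunnels[0].bottleneck_residues}
        assert set(truth["pinch_residues"]) <= labels

    def test_zero_cutoff_far_sphere_empty(self, channel):
        structure, _ = channel
        tunnel = Tunnel(
            spheres=[(np.array([0.0, 0.0, 200.0]), 0.5),
                     (np.array([0.0, 0.0, 205.0]), 0.5)],
            cost=1.0, throughput=math.exp(-1), bottleneck_radius=0.5,
            length=5.0, curvature=1.0,
        )
        assert bottleneck_residues(tunnel, structure, cutoff=1e-9) == []

    def test_cutoff_monotone(self, channel, channel_tunnels):
        structure, _ = channel
        tunnel = channel_tunnels[0]
        small = set(bottleneck_residues(tunnel, structure, cutoff=1.0))
        large = set(bottleneck_residues(tunnel, structure, cutoff=4.0))
        assert small <= large


class TestTunnelResidueSet:
    def test_single_sphere_consistency(self, channel, channel_tunnels):
        structure, _ = channel
        full = channel_tunnels[0]
        k = int(np.argmin(full.radii))
        single = Tunnel(
            spheres=[full.spheres[k]], cost=full.cost, throughput=full.throughput,
            bottleneck_radius=full.spheres[k][1], length=full.length,
            curvature=full.curvature,
        )
        assert tunnel_residue_set([single], structure, cutoff=3.0) == set(
            bottleneck_residues(full, structure, cutoff=3.0)
        )

    def test_matches_brute_force_scan(self, channel, channel_tunnels):
        structure, _ = channel
        atoms = structure.polymer().heavy()
        res = atoms.atom_residues()
        expected = set()
        for center, radius in channel_tunnels[0].spheres:
            d = np.linalg.norm(atoms.coords - center, axis=1)
            for i in np.flatnonzero(d - atoms.vdw - radius <= 3.0):
                expected.add(res[i])
        assert tunnel_residue_set(channel_tunnels, structure, cutoff=3.0) == expected


class TestTunnelConfig:
    def test_grid_spacing_bound(self):
        with pytest.raises(ValueError, match="grid_spacing"):
            TunnelConfig(probe_radius=0.3, grid_spacing=0.8)

    def test_positive_lengths(self):
        with pytest.raises(ValueError):
            TunnelConfig(probe_radius=-1.0)
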