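"""Structure reading, RIN construction and betweenness centrality."""
import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from sugarport.rin import (
    CentralityProfile,
    betweenness,
    build_rin,
    centrality_peaks,
    subnetwork,
)
from sugarport.structure import Residue, Structure, read_structure
from tests.conftest import make_random_structure


def _pdb_line(serial, name, res, seq, x, y, z, element, altloc=" ", occ=1.0,
              record="ATOM"):
    return (
        f"{record:<6}{serial:5d} {name:^4}{altloc}{res:<3} A{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}"
    )


class TestReadStructure:
    def test_minimal_two_atom_pdb(self):
        text = "\n".join(
            [
                _pdb_line(1, "N", "GLY", 1, 1.0, 2.0, 3.0, "N"),
                _pdb_line(2, "CA", "GLY", 1, 2.5, 2.0, 3.0, "C"),
                "END",
            ]
        )
        s = read_structure(text)
        assert s.n_atoms == 2
        assert np.allclose(s.coords[0], [1.0, 2.0, 3.0])
        assert s.vdw[0] == pytest.approx(1.55)

    def test_altloc_highest_occupancy_kept(self):
        text = "\n".join(
            [
                _pdb_line(1, "CA", "SER", 1, 0.0, 0.0, 0.0, "C", altloc="A", occ=0.6),
                _pdb_line(2, "CA", "SER", 1, 5.0, 0.0, 0.0, "C", altloc="B", occ=0.4),
                "END",
            ]
        )
        s = read_structure(text)
        assert s.n_atoms == 1
        assert np.allclose(s.coords[0], [0.0, 0.0, 0.0])

    def test_ligand_separated_from_polymer(self):
        text = "\n".join(
            [
                _pdb_line(1, "CA", "GLY", 1, 0.0, 0.0, 0.0, "C"),
                _pdb_line(2, "CA", "GLY", 2, 3.0, 0.0, 0.0, "C"),
                _pdb_line(3, "C1", "XYL", 9, 9.0, 0.0, 0.0, "C", record="HETATM"),
                "END",
            ]
        )
        s = read_structure(text)
        assert s.polymer().n_atoms == 2
        assert s.ligands().n_atoms == 1


def _two_residue_structure(d, names=("O", "N"), elements=("O", "N"), seqs=(1, 10)):
    return Structure(
        atom_name=np.array(names),
        element=np.array(elements),
        res_seq=np.array(seqs),
        res_name=np.array(["GLY", "GLY"]),
        chain=np.array(["A", "A"]),
        coords=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        hetero=np.array([False, False]),
    )


def brute_force_rin(structure, slack=0.5, hbond=3.5, min_sep=2):
    """Independent O(n^2) oracle over all heavy-atom pairs."""
    poly = structure.polymer().heavy()
    res = poly.atom_residues()
    edges = {}
    backbone = {"N", "CA", "C", "O"}
    for i in range(poly.n_atoms):
        for j in range(i + 1, poly.n_atoms):
            ri, rj = res[i], res[j]
            if ri == rj:
                continue
            if ri.chain == rj.chain and abs(ri.seq - rj.seq) < min_sep:
                continue
            d = np.linalg.norm(poly.coords[i] - poly.coords[j])
            pi = "mc" if poly.atom_name[i] in backbone else "sc"
            pj = "mc" if poly.atom_name[j] in backbone else "sc"
            part = "-".join(sorted((pi, pj)))
            u, v = sorted((ri, rj), key=lambda r: (r.chain, r.seq, r.name))
            rsum = poly.vdw[i] + poly.vdw[j]
            if d <= rsum + slack:
                edges[(u, v, "contact", part)] = edges.get((u, v, "contact", part), 0) + 1
            if d < rsum:
                edges[(u, v, "overlap", part)] = edges.get((u, v, "overlap", part), 0) + 1
            if d <= hbond and str(poly.element[i]).upper() in "NO" \
                    and str(poly.element[j]).upper() in "NO":
                edges[(u, v, "hbond", part)] = edges.get((u, v, "hbond", part), 0) + 1
    return edges


def _edge_multiset(graph):
    out = {}
    for u, v, d in graph.edges(data=True):
        a, b = sorted((u, v), key=lambda r: (r.chain, r.seq, r.name))
        out[(a, b, d["interaction"], d["chain_part"])] = d["count"]
    return out


class TestBuildRin:
    def test_distant_residues_no_edges(self):
        s = _two_residue_structure(20.0, names=("CA", "CA"), elements=("C", "C"))
        assert build_rin(s).number_of_edges() == 0

    def test_backbone_hbond_and_contact(self):
        s = _two_residue_structure(2.9)
        graph = build_rin(s)
        edges = _edge_multiset(graph)
        u = Residue("A", 1, "GLY")
        v = Residue("A", 10, "GLY")
        assert edges[(u, v, "hbond", "mc-mc")] == 1
        assert edges[(u, v, "contact", "mc-mc")] == 1
        assert (u, v, "overlap", "mc-mc") in edges  # 2.9 < 1.52 + 1.55

    def test_min_seq_separation_excludes_neighbors(self):
        s = _two_residue_structure(2.9, seqs=(1, 2))
        assert build_rin(s).number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            s = make_random_structure(rng, n_residues=4, atoms_per_residue=3)
            assert _edge_multiset(build_rin(s)) == brute_force_rin(s)

    def test_invariant_under_atom_reordering(self):
        rng = np.random.default_rng(99)
        s = make_random_structure(rng, n_residues=5)
        perm = rng.permutation(s.n_atoms)
        shuffled = s.subset(perm)
        assert _edge_multiset(build_rin(s)) == _edge_multiset(build_rin(shuffled))


def _graph(edges, n_nodes=None):
    g = nx.MultiGraph()
    nodes = sorted({x for e in edges for x in e})
    if n_nodes is not None:
        nodes = list(range(n_nodes))
    for n in nodes:
        g.add_node(Residue("A", n, "ALA"))
    for u, v in edges:
        g.add_edge(Residue("A", u, "ALA"), Residue("A", v, "ALA"),
                   interaction="contact", chain_part="sc-sc", count=1)
    return g


def bfs_enumeration_betweenness(graph):
    """Oracle: explicitly enumerate every shortest path between every pair."""
    nodes = sorted(graph.nodes, key=lambda r: r.seq)
    adj = {n: set() for n in nodes}
    for u, v in graph.edges():
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    through = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS layering from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            x = queue.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    queue.append(y)
        if t not in dist:
            continue
        # enumerate all shortest s-t paths by walking the BFS DAG backwards
        paths = []

        def back(node, acc):
            if node == s:
                paths.append(acc)
                return
            for p in adj[node]:
                if p in dist and dist[p] == dist[node] - 1:
                    back(p, acc + [p])

        back(t, [t])
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through[v] += sum(v in path for path in paths) / sigma
    norm = (n - 1) * (n - 2) / 2
    return {v: through[v] / norm for v in nodes}


class TestBetweenness:
    def test_path_graph_middle_node(self):
        prof = betweenness(_graph([(0, 1), (1, 2)]))
        values = {r.seq: b for r, b in prof.betweenness.items()}
        assert values == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_star_center_normalization(self):
        prof = betweenness(_graph([(0, 1), (0, 2), (0, 3)]))
        values = {r.seq: b for r, b in prof.betweenness.items()}
        assert values[0] == pytest.approx(1.0)
        assert values[1] == values[2] == values[3] == 0.0

    def test_path_graph_closed_form(self):
        n = 9
        prof = betweenness(_graph([(i, i + 1) for i in range(n - 1)]))
        for r, b in prof.betweenness.items():
            i = r.seq + 1  # 1-based position
            expected = 2 * (i - 1) * (n - i) / ((n - 1) * (n - 2))
            assert b == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_and_networkx(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.35
            ]
            g = _graph(edges, n_nodes=n)
            prof = betweenness(g)
            oracle = bfs_enumeration_betweenness(g)
            nxval = nx.betweenness_centrality(nx.Graph(g), normalized=True)
            for r in prof.residues:
                assert prof.betweenness[r] == pytest.approx(oracle[r], abs=1e-12)
                assert prof.betweenness[r] == pytest.approx(nxval[r], abs=1e-12)

    def test_relabeling_invariance(self):
        edges = [(0, 1), (1, 2), (2, 3), (1, 3)]
        base = betweenness(_graph(edges))
        shifted = betweenness(_graph([(u + 10, v + 10) for u, v in edges]))
        for r, b in base.betweenness.items():
            assert shifted.betweenness[Residue("A", r.seq + 10, "ALA")] == pytest.approx(b)

    def test_too_small_graph_errors(self):
        g = nx.MultiGraph()
        g.add_node(Residue("A", 1, "ALA"))
        with pytest.raises(ValueError):
            betweenness(g)


def _profile(values):
    residues = [Residue("A", i + 1, "ALA") for i in range(len(values))]
    return CentralityProfile(
        residues=residues,
        betweenness=dict(zip(residues, values)),
        degree={r: 1 for r in residues},
    )


class TestCentralityPeaks:
    def test_single_strict_maximum(self):
        prof = _profile([0.1, 0.2, 0.9, 0.2, 0.1])
        assert {r.seq for r in centrality_peaks(prof, 0.5)} == {3}

    def test_constant_profile_empty(self):
        assert centrality_peaks(_profile([0.3] * 10), 0.5) == set()

    def test_two_planted_spikes(self):
        values = [0.01] * 20
        values[4], values[14] = 0.8, 0.9
        peaks = centrality_peaks(_profile(values), 0.9)
        assert {r.seq for r in peaks} == {5, 15}


class TestSubnetwork:
    def test_isolated_node(self):
        g = _graph([(1, 2)])
        g.add_node(Residue("A", 9, "ALA"))
        sub = subnetwork(g, Residue("A", 9, "ALA"), radius=1)
        assert sub.number_of_nodes() == 1 and sub.number_of_edges() == 0

    def test_star_center_radius_one(self):
        g = _graph([(0, 1), (0, 2), (0, 3)])
        sub = subnetwork(g, Residue("A", 0, "ALA"), radius=1)
        assert sub.number_of_nodes() == 4 and sub.number_of_edges() == 3

    def test_matches_bfs_ball(self):
        rng = np.random.default_rng(8)
        n = 15
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.2
        ]
        g = _graph(edges, n_nodes=n)
        center = Residue("A", 3, "ALA")
        for radius in (1, 2):
            expected = {
                node
                for node, d in nx.single_source_shortest_path_length(
                    nx.Graph(g), center
                ).items()
                if d <= radius
            }
            assert set(subnetwork(g, center, radius).nodes) == expected

    def test_absent_residue_errors(self):
        with pytest.raises(KeyError):
            subnetwork(_graph([(1, 2)]), Residue("A", 99, "ALA"))
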