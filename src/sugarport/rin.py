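"""Residue interaction networks (RIN) and betweenness centrality.

Residues are nodes; typed multi-edges record non-covalent interactions
(van der Waals contact, vdW-overlap, hydrogen bond) split by the chain
part of the contributing atoms (main chain mc / side chain sc).  The
betweenness of a node is the number of shortest paths between every
other node pair that pass through it, as a fraction of all pair paths,
normalized by the number of unordered pairs (N-1)(N-2)/2, so values lie
in [0, 1].  Path counting uses the unweighted simple projection of the
multigraph.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import BACKBONE_ATOMS, Residue, Structure

DEFAULT_CONTACT_SLACK = 0.5  # Å added to r_i + r_j for a vdW contact
DEFAULT_HBOND_MAX = 3.5  # Å donor-acceptor distance, no explicit hydrogens
DEFAULT_MIN_SEQ_SEP = 2  # minimum |i - j| for same-chain residue pairs

INTERACTIONS = ("contact", "hbond", "overlap")


def _chain_part(atom_name: str) -> str:
    return "mc" if atom_name in BACKBONE_ATOMS else "sc"


def build_rin(
    structure: Structure,
    contact_slack: float = DEFAULT_CONTACT_SLACK,
    hbond_dist_max: float = DEFAULT_HBOND_MAX,
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEP,
) -> nx.MultiGraph:
    """Build the typed residue interaction multigraph of a structure.

    For residue pairs with sequence separation >= ``min_seq_separation``
    (same chain; any pair across chains), each qualifying heavy-atom pair
    contributes to a (interaction, chain-part) edge whose ``count``
    attribute is the number of qualifying atom pairs:

    - contact: d <= r_i + r_j + contact_slack
    - overlap: d <  r_i + r_j
    - hbond:   d <= hbond_dist_max and both atoms are N or O
    """
    poly = structure.polymer().heavy()
    residues = poly.residues
    if len(residues) < 2:
        raise ValueError("structure must contain at least 2 polymer residues")

    atom_res = poly.atom_residues()
    elements = np.char.upper(poly.element.astype(str))
    is_no = np.isin(elements, ["N", "O"])
    parts = np.array([_chain_part(a) for a in poly.atom_name])

    r_max = 2 * float(poly.vdw.max()) + contact_slack
    search = max(r_max, hbond_dist_max)
    tree = cKDTree(poly.coords)
    pairs = tree.query_pairs(r=search, output_type="ndarray")

    counts: dict[tuple[Residue, Residue, str, str], int] = {}
    for i, j in pairs:
        ri, rj = atom_res[i], atom_res[j]
        if ri == rj:
            continue
        if ri.chain == rj.chain and abs(ri.seq - rj.seq) < min_seq_separation:
            continue
        d = float(np.linalg.norm(poly.coords[i] - poly.coords[j]))
        part = "-".join(sorted((parts[i], parts[j])))
        u, v = sorted((ri, rj), key=lambda r: (r.chain, r.seq, r.name))
        rsum = float(poly.vdw[i] + poly.vdw[j])
        if d <= rsum + contact_slack:
            counts[(u, v, "contact", part)] = counts.get((u, v, "contact", part), 0) + 1
        if d < rsum:
            counts[(u, v, "overlap", part)] = counts.get((u, v, "overlap", part), 0) + 1
        if d <= hbond_dist_max and is_no[i] and is_no[j]:
            counts[(u, v, "hbond", part)] = counts.get((u, v, "hbond", part), 0) + 1

    graph = nx.MultiGraph()
    graph.add_nodes_from(residues)
    for (u, v, interaction, part), count in sorted(
        counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
    ):
        graph.add_edge(
            u,
            v,
            key=f"{interaction}:{part}",
            interaction=interaction,
            chain_part=part,
            count=count,
        )
    return graph


@dataclass
class CentralityProfile:
    """Per-residue pair-normalized betweenness and multi-edge degree."""

    residues: list[Residue]  # ordered by (chain, seq)
    betweenness: dict[Residue, float]
    degree: dict[Residue, int]

    def values(self) -> np.ndarray:
        return np.asarray([self.betweenness[r] for r in self.residues])


def _simple_adjacency(graph: nx.MultiGraph) -> dict:
    adj: dict = {n: set() for n in graph.nodes}
    for u, v in graph.edges():
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def betweenness(graph: nx.MultiGraph) -> CentralityProfile:
    """Pair-normalized betweenness centrality of every residue.

    Brandes accumulation over the unweighted simple projection; each
    unordered pair (s, t) with s != k != t contributes
    sigma_st(k)/sigma_st, and the sum is divided by (N-1)(N-2)/2.
    Disconnected pairs contribute 0.  Degree is taken on the multigraph
    (each typed edge counts once).
    """
    nodes = sorted(graph.nodes, key=lambda r: (r.chain, r.seq, r.name))
    n = len(nodes)
    if n < 2:
        raise ValueError("betweenness requires at least 2 residues")
    adj = _simple_adjacency(graph)
    raw = {v: 0.0 for v in nodes}
    for s in nodes:
        # single-source shortest paths (BFS) with path counts
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = {v: 0.0 for v in nodes}
        dist = {v: -1 for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w is not s:
                raw[w] += delta[w]
    # raw counts ordered (s, t) pairs twice for undirected graphs
    norm = (n - 1) * (n - 2) / 2.0
    bc = {v: (raw[v] / 2.0) / norm if norm > 0 else 0.0 for v in nodes}
    degree = {v: graph.degree(v) for v in nodes}
    return CentralityProfile(residues=nodes, betweenness=bc, degree=degree)


def centrality_peaks(
    profile: CentralityProfile, quantile: float = 0.95
) -> set[Residue]:
    """Residues that are strict local betweenness maxima (sequence window
    +-2 within their chain) and lie at or above the given quantile of all
    betweenness values."""
    if not profile.residues:
        raise ValueError("profile is empty")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    cut = float(np.quantile(profile.values(), quantile))
    peaks: set[Residue] = set()
    by_chain: dict[str, list[Residue]] = {}
    for r in profile.residues:
        by_chain.setdefault(r.chain, []).append(r)
    for chain_res in by_chain.values():
        for i, r in enumerate(chain_res):
            b = profile.betweenness[r]
            if b < cut:
                continue
            lo, hi = max(0, i - 2), min(len(chain_res), i + 3)
            neighbors = [chain_res[j] for j in range(lo, hi) if j != i]
            if all(b > profile.betweenness[x] for x in neighbors):
                peaks.add(r)
    return peaks


def subnetwork(
    graph: nx.MultiGraph, residue: Residue, radius: int = 1
) -> nx.MultiGraph:
    """Induced subgraph on nodes within graph distance <= radius."""
    if residue not in graph:
        raise KeyError(f"residue {residue} not in graph")
    lengths = nx.single_source_shortest_path_length(graph, residue, cutoff=radius)
    return graph.subgraph(lengths.keys()).copy()


# ------------------------------------------------------------------ export
def _node_label(r: Residue) -> str:
    return f"{r.chain}:{r.name}{r.seq}"


def edges_table(graph: nx.MultiGraph):
    """Edge list as a pandas DataFrame (u, v, interaction, chain_part, count)."""
    import pandas as pd

    rows = [
        {
            "u": _node_label(u),
            "v": _node_label(v),
            "interaction": data["interaction"],
            "chain_part": data["chain_part"],
            "count": data["count"],
        }
        for u, v, data in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["u", "v", "interaction", "chain_part", "count"])


def centrality_table(profile: CentralityProfile):
    """Per-residue centrality as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "residue": [_node_label(r) for r in profile.residues],
            "chain": [r.chain for r in profile.residues],
            "res_seq": [r.seq for r in profile.residues],
            "res_name": [r.name for r in profile.residues],
            "betweenness": [profile.betweenness[r] for r in profile.residues],
            "degree": [profile.degree[r] for r in profile.residues],
        }
    )


def write_graphml(graph: nx.MultiGraph, path) -> None:
    """GraphML export with string node labels."""
    relabeled = nx.relabel_nodes(graph, {n: _node_label(n) for n in graph.nodes})
    nx.write_graphml(relabeled, str(path))
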