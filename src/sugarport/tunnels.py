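"""Transport tunnel detection by probe-based cheapest-path search.

The structure is discretized on a regular grid; every grid node carries a
free radius (distance to the nearest atom surface).  Nodes that cannot
host the probe are blocked.  A Dijkstra search from an interior start
point finds, for every reachable surface exit, the cheapest path under
the cost density length x (probe / free_radius)^2, which makes wide
passages cost roughly their length-scaled minimum while narrow ones are
penalized quadratically.  Candidate paths are greedily clustered by
centerline proximity; each cluster's representative is its cheapest
member.  Tunnel usability is summarized by throughput = exp(-cost),
bottleneck radius (narrowest sphere), length (centerline polyline) and
curvature (length over straight-line end-to-end distance, >= 1).
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.distance import cdist

from .structure import Residue, Structure

logger = logging.getLogger(__name__)


class StartPointError(ValueError):
    """Raised when the requested start point cannot host the probe."""


@dataclass
class TunnelConfig:
    """Parameters of the tunnel search.

    Defaults follow CAVER-style conventions for a pentose-sized probe:
    probe radius 0.8 Å, clustering threshold 4.5 Å, shell depth 4 Å and
    shell radius 3 Å.
    """

    probe_radius: float = 0.8
    clustering_threshold: float = 4.5
    shell_depth: float = 4.0
    shell_radius: float = 3.0
    grid_spacing: float = 0.8
    start_point: tuple[float, float, float] | None = None
    start_residue: Residue | None = None
    bottleneck_cutoff: float = 3.0  # Å, bottleneck-residue assignment

    def __post_init__(self) -> None:
        for name in (
            "probe_radius",
            "clustering_threshold",
            "shell_depth",
            "shell_radius",
            "grid_spacing",
            "bottleneck_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.grid_spacing > 2 * self.probe_radius:
            raise ValueError("grid_spacing must be <= 2 * probe_radius")


@dataclass
class Tunnel:
    """An ordered sphere path with its transport metrics."""

    spheres: list[tuple[np.ndarray, float]]  # (center xyz, free radius)
    cost: float
    throughput: float
    bottleneck_radius: float
    length: float
    curvature: float
    exit_label: str = ""
    bottleneck_residues: list[Residue] = field(default_factory=list)
    cluster_size: int = 1

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([c for c, _ in self.spheres])

    @property
    def radii(self) -> np.ndarray:
        return np.asarray([r for _, r in self.spheres])


@dataclass
class FreeRadiusField:
    """Free-radius grid around a structure."""

    origin: np.ndarray  # (3,) grid origin, multiples of spacing
    spacing: float
    shape: tuple[int, int, int]
    free_radius: np.ndarray  # 3D array of free radii
    blocked: np.ndarray  # 3D bool, free_radius < probe_radius
    exit: np.ndarray  # 3D bool, bulk-solvent (terminal) nodes
    start_index: tuple[int, int, int]

    def node_coords(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing


def _resolve_start(structure: Structure, config: TunnelConfig) -> np.ndarray:
    if config.start_point is not None:
        return np.asarray(config.start_point, dtype=float)
    if config.start_residue is not None:
        return structure.residue_centroid(config.start_residue, side_chain=True)
    raise ValueError("config must define start_point or start_residue")


def free_radius_field(structure: Structure, config: TunnelConfig) -> FreeRadiusField:
    """Free-radius grid, blocked mask and bulk-solvent exit mask.

    free_radius(node) = min over atoms of (|node - atom| - vdW radius);
    nodes with free radius below the probe radius are blocked.  A node is
    a bulk-solvent exit when it lies outside the convex envelope of the
    atom centers, or when it is within ``shell_depth`` of the envelope
    boundary with free radius >= ``shell_radius``.  Paths terminate at
    exit nodes, which marks the protein surface.
    """
    atoms = structure.heavy()
    coords = atoms.coords
    vdw = atoms.vdw
    h = config.grid_spacing
    pad = max(config.shell_radius, 2 * h) + h
    lo = np.floor((coords.min(axis=0) - pad) / h) * h
    hi = coords.max(axis=0) + pad
    shape = tuple(int(math.floor((hi[k] - lo[k]) / h)) + 1 for k in range(3))
    axes = [lo[k] + h * np.arange(shape[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    nodes = grid.reshape(-1, 3)

    fr = np.full(len(nodes), np.inf)
    chunk = max(1, 4_000_000 // max(len(coords), 1))
    for i in range(0, len(nodes), chunk):
        d = cdist(nodes[i : i + chunk], coords)
        fr[i : i + chunk] = np.min(d - vdw[None, :], axis=1)
    fr = fr.reshape(shape)
    blocked = fr < config.probe_radius

    hull = None
    if len(coords) >= 4:
        try:
            # QJ joggles coplanar/degenerate inputs
            hull = ConvexHull(coords, qhull_options="QJ")
        except Exception:  # pragma: no cover - pathological geometry
            hull = None
    if hull is not None:
        # signed facet evaluation: > 0 outside the hull
        eq = hull.equations  # (n_facets, 4): n . x + d <= 0 inside
        signed = nodes @ eq[:, :3].T + eq[:, 3][None, :]
        max_signed = signed.max(axis=1).reshape(shape)
        outside = max_signed > 0
        near_surface = (-max_signed <= config.shell_depth) & (
            fr >= config.shell_radius
        )
        exit_mask = ~blocked & (outside | near_surface)
    else:
        exit_mask = ~blocked & (fr >= config.shell_radius)

    start = _resolve_start(structure, config)
    start_index = tuple(
        int(np.clip(round((start[k] - lo[k]) / h), 0, shape[k] - 1))
        for k in range(3)
    )
    if blocked[start_index]:
        raise StartPointError(
            "start point not in a cavity (free radius "
            f"{fr[start_index]:.2f} Å < probe {config.probe_radius} Å)"
        )
    return FreeRadiusField(
        origin=lo,
        spacing=h,
        shape=shape,
        free_radius=fr,
        blocked=blocked,
        exit=exit_mask,
        start_index=start_index,
    )


_OFFSETS = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0)
]


def _grid_graph(field: FreeRadiusField, probe: float):
    """Directed sparse graph over unblocked nodes; exit nodes absorb."""
    shape = field.shape
    flat_id = np.full(shape, -1, dtype=np.int64)
    open_mask = ~field.blocked
    n_open = int(open_mask.sum())
    flat_id[open_mask] = np.arange(n_open)
    interior = open_mask & ~field.exit
    fr = field.free_radius
    h = field.spacing

    rows, cols, costs = [], [], []
    for off in _OFFSETS:
        src = [slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)]
        dst = [slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)]
        src, dst = tuple(src), tuple(dst)
        ok = interior[src] & open_mask[dst]
        if not ok.any():
            continue
        u = flat_id[src][ok]
        v = flat_id[dst][ok]
        rmin = np.minimum(fr[src][ok], fr[dst][ok])
        seglen = h * math.sqrt(sum(o * o for o in off))
        w = seglen * (probe / rmin) ** 2
        rows.append(u)
        cols.append(v)
        costs.append(w)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        costs = np.concatenate(costs)
    graph = sparse.csr_matrix(
        (costs, (rows, cols)), shape=(n_open, n_open)
    )
    return graph, flat_id, open_mask


def _resample_polyline(points: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arclength steps."""
    if len(points) < 2:
        return points
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0:
        return points[:1]
    n = max(2, int(math.ceil(total / step)) + 1)
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arclen, points[:, k])
    return out


def centerline_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean nearest-point distance between two resampled
    centerlines (the clustering metric)."""
    d = cdist(a, b)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def tunnel_metrics(
    spheres: list[tuple[np.ndarray, float]], cost: float
) -> tuple[float, float, float, float]:
    """(throughput, bottleneck_radius, length, curvature) of a sphere path."""
    if len(spheres) < 2:
        raise ValueError("a tunnel needs at least 2 spheres")
    if cost < 0:
        raise ValueError("cost must be non-negative")
    centers = np.asarray([c for c, _ in spheres], dtype=float)
    radii = np.asarray([r for _, r in spheres], dtype=float)
    length = float(np.linalg.norm(np.diff(centers, axis=0), axis=1).sum())
    straight = float(np.linalg.norm(centers[-1] - centers[0]))
    if straight < 1e-9:
        raise ValueError("curvature undefined: coincident start and end")
    return (
        float(math.exp(-cost)),
        float(radii.min()),
        length,
        length / straight,
    )


def throughput_from_cost(cost: float) -> float:
    """Tunnel throughput (transport-usability probability) from the
    accumulated path cost: exp(-cost)."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    return math.exp(-cost)


def bottleneck_residues(
    tunnel: Tunnel, structure: Structure, cutoff: float = 3.0
) -> list[Residue]:
    """Residues lining the tunnel's narrowest sphere.

    A residue qualifies when at least one heavy atom's surface
    (center distance - vdW radius) lies within ``cutoff`` of the
    bottleneck sphere surface; sorted by residue number.
    """
    if not tunnel.spheres:
        raise ValueError("tunnel has no spheres")
    radii = tunnel.radii
    k = int(np.argmin(radii))
    center, r_b = tunnel.centers[k], float(radii[k])
    return _residues_near_sphere(structure, center, r_b, cutoff)


def _residues_near_sphere(
    structure: Structure, center: np.ndarray, radius: float, cutoff: float
) -> list[Residue]:
    atoms = structure.polymer().heavy()
    d = np.linalg.norm(atoms.coords - center[None, :], axis=1)
    near = (d - atoms.vdw - radius) <= cutoff
    res = {r for r, hit in zip(atoms.atom_residues(), near) if hit}
    return sorted(res, key=lambda r: (r.chain, r.seq, r.name))


def tunnel_residue_set(
    tunnels: list[Tunnel], structure: Structure, cutoff: float = 3.0
) -> set[Residue]:
    """Union of residues lining any sphere of any tunnel."""
    if not tunnels:
        raise ValueError("at least one tunnel is required")
    atoms = structure.polymer().heavy()
    tree = cKDTree(atoms.coords)
    max_vdw = float(atoms.vdw.max())
    atom_res = atoms.atom_residues()
    lining: set[Residue] = set()
    for tunnel in tunnels:
        for center, radius in tunnel.spheres:
            cand = tree.query_ball_point(center, r=radius + cutoff + max_vdw)
            if not cand:
                continue
            cand = np.asarray(cand)
            d = np.linalg.norm(atoms.coords[cand] - center[None, :], axis=1)
            ok = (d - atoms.vdw[cand] - radius) <= cutoff
            lining.update(atom_res[i] for i in cand[ok])
    return lining


def find_tunnels(structure: Structure, config: TunnelConfig) -> list[Tunnel]:
    """Detect, cluster and rank transport tunnels from the start point.

    One candidate path per reachable surface exit node (cheapest path);
    candidates join an existing cluster when the symmetric mean
    nearest-point distance between their 1 Å-resampled centerlines and
    the cluster representative is <= ``clustering_threshold``; each
    cluster is reported through its cheapest member, sorted by cost.
    """
    try:
        field_ = free_radius_field(structure, config)
    except StartPointError as exc:
        logger.warning("no tunnels: %s", exc)
        return []
    graph, flat_id, open_mask = _grid_graph(field_, config.probe_radius)
    start_id = int(flat_id[field_.start_index])
    if start_id < 0:
        return []
    if field_.exit[field_.start_index]:
        logger.warning("start point lies in bulk solvent; no tunnels")
        return []
    dist, pred = _csgraph_dijkstra(
        graph, directed=True, indices=start_id, return_predecessors=True
    )
    open_idx = np.argwhere(open_mask)
    is_exit_open = field_.exit[open_mask.nonzero()]
    reached = np.flatnonzero(np.isfinite(dist) & is_exit_open)
    reached = reached[reached != start_id]
    if reached.size == 0:
        logger.warning("no surface exit reachable from the start point")
        return []

    order = np.argsort(dist[reached], kind="stable")
    fr_flat = field_.free_radius[open_mask.nonzero()]

    def path_of(node: int) -> np.ndarray:
        chain = [node]
        while pred[chain[-1]] >= 0:
            chain.append(int(pred[chain[-1]]))
        return np.asarray(chain[::-1], dtype=int)

    clusters: list[dict] = []
    for node in reached[order]:
        ids = path_of(int(node))
        centers = field_.origin + open_idx[ids] * field_.spacing
        resampled = _resample_polyline(centers, step=1.0)
        placed = False
        for cl in clusters:
            if (
                centerline_distance(resampled, cl["resampled"])
                <= config.clustering_threshold
            ):
                cl["size"] += 1
                placed = True
                break
        if not placed:
            clusters.append(
                {
                    "ids": ids,
                    "centers": centers,
                    "resampled": resampled,
                    "cost": float(dist[node]),
                    "size": 1,
                }
            )

    tunnels: list[Tunnel] = []
    for rank, cl in enumerate(sorted(clusters, key=lambda c: c["cost"]), start=1):
        spheres = [
            (cl["centers"][i], float(fr_flat[cl["ids"][i]]))
            for i in range(len(cl["ids"]))
        ]
        throughput, r_b, length, curvature = tunnel_metrics(spheres, cl["cost"])
        tunnel = Tunnel(
            spheres=spheres,
            cost=cl["cost"],
            throughput=throughput,
            bottleneck_radius=r_b,
            length=length,
            curvature=curvature,
            exit_label=f"T{rank}",
            cluster_size=cl["size"],
        )
        tunnel.bottleneck_residues = bottleneck_residues(
            tunnel, structure, cutoff=config.bottleneck_cutoff
        )
        tunnels.append(tunnel)
    return tunnels


def tunnels_report(tunnels: list[Tunnel]) -> list[dict]:
    """JSON-ready per-tunnel metric records."""
    return [
        {
            "rank": i + 1,
            "exit_label": t.exit_label,
            "throughput": t.throughput,
            "cost": t.cost,
            "bottleneck_radius": t.bottleneck_radius,
            "length": t.length,
            "curvature": t.curvature,
            "cluster_size": t.cluster_size,
            "bottleneck_residues": [r.label for r in t.bottleneck_residues],
        }
        for i, t in enumerate(tunnels)
    ]


def centerline_pdb(tunnels: list[Tunnel], path) -> None:
    """Write tunnel centerlines as PDB pseudo-atom (HETATM) records."""
    lines = []
    serial = 1
    for i, tunnel in enumerate(tunnels, start=1):
        for center, radius in tunnel.spheres:
            x, y, z = center
            lines.append(
                f"HETATM{serial:5d}  C   TUN {chr(64 + i)}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{radius:6.2f}"
                f"           C"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
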