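"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate, at desk scale, the data the pipeline consumes:
channel-bearing atom clouds with engineered pore geometry, annotation
evidence tables with a planted transporter set, FPKM replicate tables
with a planted condition-specific up-regulated subfamily, and
per-residue energy component tables with exact sums.  Every generator is
deterministic under a fixed seed and returns a truth record sufficient
to score the downstream stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .structure import Structure

WALL_VDW = 1.70  # carbon wall atoms
_CHANNEL_ELEMENT_BY_VDW = {1.70: "C", 1.55: "N", 1.52: "O", 1.80: "S"}


@dataclass
class ChannelSpec:
    """A single-pore channel: stacked atom rings around the z-axis.

    The wall radius profile defaults to a 35 Å tube of radius 4 Å with a
    pinch ring narrowed to ``pinch_radius``; the pinch ring is built from
    ``pinch_atoms`` atoms at slightly staggered radii so the planted
    bottleneck residues have distinct, strictly ordered geometry.  One
    end is capped, leaving a single engineered exit.
    """

    wall_radius_profile: list[tuple[float, float]] | None = None
    atom_vdw: float = WALL_VDW
    atoms_per_ring: int = 16
    ring_spacing: float = 2.5
    pinch_radius: float = 2.6
    pinch_atoms: int = 6
    pinch_ring_index: int = 7
    n_rings: int = 15
    ring_radius: float = 4.0
    capped: bool = True
    probe_radius: float = 0.8  # used only for the "closed" truth flag
    seed: int = 0

    def profile(self) -> list[tuple[float, float]]:
        if self.wall_radius_profile is not None:
            return list(self.wall_radius_profile)
        prof = [
            (i * self.ring_spacing, self.ring_radius) for i in range(self.n_rings)
        ]
        prof[self.pinch_ring_index] = (
            self.pinch_ring_index * self.ring_spacing,
            self.pinch_radius,
        )
        return prof

    def __post_init__(self) -> None:
        if self.atom_vdw <= 0 or self.ring_spacing <= 0:
            raise ValueError("lengths must be positive")
        prof = self.profile()
        zs = [z for z, _ in prof]
        if any(z2 <= z1 for z1, z2 in zip(zs, zs[1:])):
            raise ValueError("wall_radius_profile z values must be increasing")
        if any(r <= self.atom_vdw for _, r in prof):
            raise ValueError("wall radii must exceed the atom vdW radius")


def _ring(center_z, radius, n_atoms, phase, jitter, rng, basis=None, origin=None):
    angles = phase + np.arange(n_atoms) * (2 * math.pi / n_atoms)
    if jitter > 0:
        angles = angles + rng.uniform(-jitter, jitter, size=n_atoms)
    if basis is None:
        return np.stack(
            [radius * np.cos(angles), radius * np.sin(angles),
             np.full(n_atoms, float(center_z))],
            axis=1,
        )
    e1, e2, u = basis
    pts = (
        origin[None, :]
        + center_z * u[None, :]
        + radius * (np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2)
    )
    return pts


def _cap_coords(z0: float, rng, jitter: float) -> np.ndarray:
    """A closed cap just below z0 (rings of shrinking radius + apex atom)."""
    parts = [
        _ring(z0 - 1.6, 2.6, 10, 0.15, jitter, rng),
        _ring(z0 - 2.4, 1.2, 6, 0.45, jitter, rng),
        np.array([[0.0, 0.0, z0 - 2.7]]),
    ]
    return np.concatenate(parts, axis=0)


def _element_for_vdw(vdw: float) -> str:
    best = min(_CHANNEL_ELEMENT_BY_VDW, key=lambda r: abs(r - vdw))
    return _CHANNEL_ELEMENT_BY_VDW[best]


def make_channel_structure(spec: ChannelSpec) -> tuple[Structure, dict]:
    """Generate a channel structure and its geometric ground truth.

    Each wall atom is its own single-atom residue (CA of GLY); the pinch
    ring atoms are TRP residues interleaved into the numbering away from
    their spatial neighbors, so they form isolated sequence-local
    features.  Truth records the axial free-radius profile, the pinch
    location and value, the pinch residue labels and the suggested
    tunnel start point.
    """
    rng = np.random.default_rng(spec.seed)
    jitter = math.radians(2.0)
    profile = spec.profile()
    r_min = min(r for _, r in profile)
    z_pinch = next(z for z, r in profile if r == r_min)
    element = _element_for_vdw(spec.atom_vdw)

    wall_coords: list[np.ndarray] = []
    pinch_coords: list[np.ndarray] = []
    for i, (z, r) in enumerate(profile):
        phase = (i % 2) * (math.pi / spec.atoms_per_ring)
        if z == z_pinch and r == r_min:
            # staggered pinch ring: distinct radii, strictly ordered
            angles = phase + np.arange(spec.pinch_atoms) * (
                2 * math.pi / spec.pinch_atoms
            ) + rng.uniform(-jitter, jitter, size=spec.pinch_atoms)
            radii = r + 0.08 * np.arange(spec.pinch_atoms)
            pts = np.stack(
                [radii * np.cos(angles), radii * np.sin(angles),
                 np.full(spec.pinch_atoms, z)],
                axis=1,
            )
            pinch_coords.append(pts)
        else:
            wall_coords.append(
                _ring(z, r, spec.atoms_per_ring, phase, jitter, rng)
            )
    z0 = profile[0][0]
    if spec.capped:
        wall_coords.append(_cap_coords(z0, rng, jitter))
    wall = np.concatenate(wall_coords, axis=0)
    pinch = np.concatenate(pinch_coords, axis=0) if pinch_coords else np.empty((0, 3))

    # interleave pinch residues into the numbering between cap-distal wall
    # atoms (every 5th position near the start of the sequence), so their
    # sequence neighbors are spatially remote wall atoms
    coords: list[np.ndarray] = []
    names: list[str] = []
    n_pinch = len(pinch)
    wall_iter = iter(range(len(wall)))
    inserted = 0
    for k, wi in enumerate(wall_iter):
        coords.append(wall[wi])
        names.append("GLY")
        if inserted < n_pinch and (k + 1) % 5 == 0:
            coords.append(pinch[inserted])
            names.append("TRP")
            inserted += 1
    while inserted < n_pinch:  # pragma: no cover - tiny walls only
        coords.append(pinch[inserted])
        names.append("TRP")
        inserted += 1
    coords_arr = np.asarray(coords)
    n = len(coords_arr)
    structure = Structure(
        atom_name=np.array(["CA"] * n),
        element=np.array([element] * n),
        res_seq=np.arange(1, n + 1),
        res_name=np.array(names),
        chain=np.array(["A"] * n),
        coords=coords_arr,
        hetero=np.zeros(n, dtype=bool),
    )
    pinch_labels = [
        f"Trp{seq}" for seq, name in zip(structure.res_seq, structure.res_name)
        if name == "TRP"
    ]
    axial = [(z, r - spec.atom_vdw) for z, r in profile]
    bottleneck = r_min - spec.atom_vdw
    truth = {
        "axial_free_radius": axial,
        "bottleneck_radius": bottleneck,
        "bottleneck_z": z_pinch,
        "pinch_residues": pinch_labels,
        "n_exits": 1 if spec.capped else 2,
        "closed": bottleneck < spec.probe_radius,
        "start_xyz": (0.0, 0.0, z0 + 2 * spec.ring_spacing),
    }
    return structure, truth


def make_branching_channel(
    trunk_length: float = 15.0,
    branch_length: float = 25.0,
    branch_angles_deg: tuple[float, ...] = (-50.0, 50.0),
    branch_pinch_radii: tuple[float | None, ...] | None = None,
    ring_radius: float = 4.0,
    ring_spacing: float = 2.5,
    atoms_per_ring: int = 16,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """A Y-shaped (or multi-branch) channel: capped trunk along +z that
    splits into straight branches at the branch point.

    ``branch_pinch_radii`` optionally narrows one mid-branch ring per
    branch; a sub-probe pinch makes that branch unrecoverable.  Truth
    records the expected exits, the branch point and per-branch
    bottlenecks.  Branches closer than 25 degrees are rejected as
    overlapping.
    """
    angles = list(branch_angles_deg)
    for a, b in zip(sorted(angles), sorted(angles)[1:]):
        if abs(b - a) < 25.0:
            raise ValueError("overlapping branches: angles closer than 25 degrees")
    if branch_pinch_radii is None:
        branch_pinch_radii = tuple(None for _ in angles)
    if len(branch_pinch_radii) != len(angles):
        raise ValueError("one pinch radius (or None) per branch required")

    rng = np.random.default_rng(seed)
    jitter = math.radians(2.0)
    branch_point = np.array([0.0, 0.0, trunk_length])
    axes = []
    for a in angles:
        u = np.array([math.sin(math.radians(a)), 0.0, math.cos(math.radians(a))])
        e1 = np.array([math.cos(math.radians(a)), 0.0, -math.sin(math.radians(a))])
        e2 = np.array([0.0, 1.0, 0.0])
        axes.append((e1, e2, u))

    def clearance(points: np.ndarray, skip: int | None) -> np.ndarray:
        """Min distance of points to every *other* tube axis segment."""
        keep = np.full(len(points), np.inf)
        segs = [(np.array([0.0, 0.0, 0.0]), branch_point, -1)]
        for bi, (_, _, u) in enumerate(axes):
            segs.append((branch_point, branch_point + branch_length * u, bi))
        for p0, p1, tag in segs:
            if tag == skip:
                continue
            d = p1 - p0
            t = np.clip((points - p0) @ d / (d @ d), 0.0, 1.0)
            proj = p0[None, :] + t[:, None] * d[None, :]
            keep = np.minimum(keep, np.linalg.norm(points - proj, axis=1))
        return keep

    coords: list[np.ndarray] = []
    n_trunk_rings = int(round(trunk_length / ring_spacing))
    for i in range(n_trunk_rings):
        phase = (i % 2) * (math.pi / atoms_per_ring)
        pts = _ring(i * ring_spacing, ring_radius, atoms_per_ring, phase, jitter, rng)
        pts = pts[clearance(pts, skip=-1) > ring_radius - 0.7]
        coords.append(pts)
    coords.append(_cap_coords(0.0, rng, jitter))

    truth_bottlenecks = []
    n_branch_rings = int(round(branch_length / ring_spacing))
    for bi, ((e1, e2, u), pinch_r) in enumerate(zip(axes, branch_pinch_radii)):
        branch_bneck = ring_radius - WALL_VDW
        for j in range(1, n_branch_rings + 1):
            r = ring_radius
            if pinch_r is not None and j == n_branch_rings // 2:
                r = pinch_r
                branch_bneck = pinch_r - WALL_VDW
            phase = (j % 2) * (math.pi / atoms_per_ring)
            pts = _ring(
                j * ring_spacing, r, atoms_per_ring, phase, jitter, rng,
                basis=(e1, e2, u), origin=branch_point,
            )
            pts = pts[clearance(pts, skip=bi) > ring_radius - 0.7]
            coords.append(pts)
        truth_bottlenecks.append(branch_bneck)

    all_coords = np.concatenate(coords, axis=0)
    n = len(all_coords)
    structure = Structure(
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        res_seq=np.arange(1, n + 1),
        res_name=np.array(["GLY"] * n),
        chain=np.array(["A"] * n),
        coords=all_coords,
        hetero=np.zeros(n, dtype=bool),
    )
    recoverable = sum(1 for b in truth_bottlenecks if b >= 0.8)
    truth = {
        "n_exits": len(angles),
        "n_recoverable_exits": recoverable,
        "branch_point": tuple(branch_point),
        "branch_bottlenecks": truth_bottlenecks,
        "start_xyz": (0.0, 0.0, 2 * ring_spacing),
    }
    return structure, truth


# ------------------------------------------------------------- annotation
HYDROPHOBIC = "LIVFAM"
HYDROPHILIC = "DEKRNQSTGH"

_SOURCE_FEATURES = {
    "domain": "PF00083",
    "family": "IPR003663",
    "ortholog_group": "KOG0254",
    "transporter_class": "2.A.1.1",
}


def _random_sequence(rng, n, alphabet) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def make_evidence_tables(
    n_proteins: int = 40,
    n_transporters: int = 12,
    dropout: float | dict[str, float] = 0.0,
    decoy_rate: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Evidence table + sequences with a planted transporter set.

    Planted transporters carry passing evidence in each source (subject
    to per-source ``dropout``) and membrane-like sequences.  Decoys carry
    evidence that fails the default thresholds (high E-value, low
    identity, or a disallowed transporter class); "trap" decoys carry
    passing evidence but soluble (no-TM) sequences, exercising the
    membrane gate.  Returns (evidence table, id -> sequence, truth).
    """
    if isinstance(dropout, (int, float)):
        dropout = {s: float(dropout) for s in _SOURCE_FEATURES}
    for s, rate in dropout.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"dropout rate for {s} must be in [0, 1]")
    if not 0 <= decoy_rate <= 1:
        raise ValueError("decoy_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    planted = set(ids[:n_transporters])
    others = ids[n_transporters:]
    n_trap = max(1, len(others) // 5) if others else 0
    traps = set(others[:n_trap])
    decoys = set(others[n_trap:])

    sequences: dict[str, str] = {}
    rows: list[dict] = []
    tm_block = lambda: _random_sequence(rng, 21, HYDROPHOBIC)  # noqa: E731
    for pid in ids:
        if pid in planted:
            sequences[pid] = (
                _random_sequence(rng, 30, HYDROPHILIC)
                + tm_block()
                + _random_sequence(rng, 25, HYDROPHILIC)
                + tm_block()
                + _random_sequence(rng, 30, HYDROPHILIC)
            )
            for source, feature in _SOURCE_FEATURES.items():
                if rng.random() < dropout[source]:
                    continue
                rows.append(
                    {
                        "protein_id": pid,
                        "source": source,
                        "feature_id": feature,
                        "e_value": 10.0 ** rng.uniform(-30, -8),
                        "identity_pct": rng.uniform(35, 90),
                    }
                )
        elif pid in traps:
            # passing evidence, but soluble sequence: TM gate must reject
            sequences[pid] = _random_sequence(rng, 120, HYDROPHILIC)
            rows.append(
                {
                    "protein_id": pid,
                    "source": "domain",
                    "feature_id": "PF00083",
                    "e_value": 1e-10,
                    "identity_pct": 60.0,
                }
            )
        else:
            sequences[pid] = (
                _random_sequence(rng, 40, HYDROPHILIC)
                + tm_block()
                + _random_sequence(rng, 40, HYDROPHILIC)
            )
            if rng.random() < decoy_rate:
                mode = rng.integers(0, 3)
                if mode == 0:  # failing E-value
                    rows.append(
                        {
                            "protein_id": pid,
                            "source": "family",
                            "feature_id": "IPR005828",
                            "e_value": 10.0 ** rng.uniform(-4, -1),
                            "identity_pct": rng.uniform(30, 90),
                        }
                    )
                elif mode == 1:  # failing identity
                    rows.append(
                        {
                            "protein_id": pid,
                            "source": "transporter_class",
                            "feature_id": "2.A.1.2",
                            "e_value": 1e-12,
                            "identity_pct": rng.uniform(2, 20),
                        }
                    )
                else:  # disallowed transporter class
                    rows.append(
                        {
                            "protein_id": pid,
                            "source": "transporter_class",
                            "feature_id": "3.A.1.5",
                            "e_value": 1e-12,
                            "identity_pct": rng.uniform(40, 90),
                        }
                    )
    evidence = pd.DataFrame(
        rows, columns=["protein_id", "source", "feature_id", "e_value", "identity_pct"]
    )
    truth = {
        "planted_transporters": sorted(planted),
        "trap_decoys": sorted(traps),
        "threshold_decoys": sorted(decoys),
    }
    return evidence, sequences, truth


# ------------------------------------------------------------- expression
SUBFAMILY_LABELS = (
    "pentose",
    "glucose",
    "hexose",
    "lactose",
    "alpha_glucoside",
    "polyol",
    "quinate",
    "organic_anion",
    "carboxylate",
)


@dataclass
class PlantedExpressionSpec:
    """Planted condition-specific up-regulation of one subfamily.

    Defaults emulate a 9-subfamily transporter complement grown on three
    carbon sources with a strong (+4 log2) pentose-subfamily response in
    the xylose culture and modest log-normal replicate noise.
    """

    n_per_subfamily: int = 10
    effect_log2fc: float = 4.0
    sigma: float = 0.2  # log2-scale replicate noise SD
    conditions: tuple[str, ...] = ("glucose", "sucrose", "xylose")
    n_replicates: int = 3
    target_condition: str = "xylose"
    planted_label: str = "pentose"
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    seed: int = 0
    labels: tuple[str, ...] = dc_field(default=SUBFAMILY_LABELS)

    def __post_init__(self) -> None:
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.planted_label not in self.labels:
            raise ValueError("planted_label must be one of labels")
        if self.target_condition not in self.conditions:
            raise ValueError("target_condition must be one of conditions")


def make_expression(
    spec: PlantedExpressionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], dict]:
    """FPKM replicate table, differential table, gene sets and truth.

    Baseline per-gene FPKM is log-normal; replicates add log-normal
    noise; planted-subfamily genes are multiplied by 2**effect in the
    target condition.  The differential table contrasts the target
    condition against the first non-target condition and is computed
    from the generative model itself: the replicate noise SD is known,
    so the per-gene statistic is an exact z-test on the difference of
    mean log2 values (var sigma^2 * 2/n), with BH correction.
    """
    from scipy.stats import norm

    from .expression import bh_fdr
    rng = np.random.default_rng(spec.seed)
    sets: dict[str, list[str]] = {}
    genes: list[str] = []
    for si, label in enumerate(spec.labels):
        members = [
            f"ST{si * spec.n_per_subfamily + j + 1:04d}"
            for j in range(spec.n_per_subfamily)
        ]
        sets[label] = members
        genes.extend(members)
    base = 2.0 ** rng.normal(
        spec.baseline_log2_mean, spec.baseline_log2_sd, size=len(genes)
    )
    planted = set(sets[spec.planted_label])
    columns = {}
    for cond in spec.conditions:
        for rep in range(1, spec.n_replicates + 1):
            noise = 2.0 ** rng.normal(0.0, spec.sigma, size=len(genes))
            vals = base * noise
            if cond == spec.target_condition:
                boost = np.array(
                    [2.0 ** spec.effect_log2fc if g in planted else 1.0 for g in genes]
                )
                vals = vals * boost
            columns[f"{cond}_{rep}"] = vals
    fpkm = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))

    reference = next(c for c in spec.conditions if c != spec.target_condition)
    cols_a = [f"{spec.target_condition}_{r}" for r in range(1, spec.n_replicates + 1)]
    cols_b = [f"{reference}_{r}" for r in range(1, spec.n_replicates + 1)]
    lfc = (
        np.log2(fpkm[cols_a]).mean(axis=1) - np.log2(fpkm[cols_b]).mean(axis=1)
    ).to_numpy()
    se = spec.sigma * math.sqrt(2.0 / spec.n_replicates)
    p = 2.0 * norm.sf(np.abs(lfc) / se)
    diff = pd.DataFrame(
        {
            "gene_id": genes,
            "contrast": f"{spec.target_condition}/{reference}",
            "log2fc": lfc,
            "p_value": p,
            "fdr": bh_fdr(p),
        }
    )
    target_cols = [
        f"{spec.target_condition}_{r}" for r in range(1, spec.n_replicates + 1)
    ]
    planted_means = fpkm.loc[sorted(planted), target_cols].mean(axis=1)
    truth = {
        "planted_subfamily": spec.planted_label,
        "planted_genes": sorted(planted),
        "top_gene": str(planted_means.idxmax()),
        "effect_log2fc": spec.effect_log2fc,
        "contrast": f"{spec.target_condition}/{reference}",
    }
    return fpkm, diff, sets, truth


# ------------------------------------------------------------------ energy
_AA3 = ("ALA", "VAL", "LEU", "ILE", "PHE", "TRP", "MET", "PRO", "SER", "THR")


def make_energy_table(
    n_residues: int = 25,
    seed: int = 0,
    planted_top_residue: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-residue energy component table with exact dG_bind sums.

    The planted top residue (generated if not supplied) is guaranteed
    the most negative total binding energy.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [
        f"{_AA3[i % len(_AA3)].capitalize()}{10 + 3 * i}" for i in range(n_residues)
    ]
    if planted_top_residue is None:
        planted_top_residue = labels[int(rng.integers(0, n_residues))]
    elif planted_top_residue not in labels:
        labels[0] = planted_top_residue
    dE_MM = rng.normal(-1.2, 0.8, size=n_residues)
    dG_polar = rng.normal(0.6, 0.5, size=n_residues)
    dG_SASA = rng.normal(-0.2, 0.1, size=n_residues)
    dG_bind = dE_MM + dG_polar + dG_SASA
    top_ix = labels.index(planted_top_residue)
    dE_MM[top_ix] = (dG_bind.min() - 1.5) - dG_polar[top_ix] - dG_SASA[top_ix]
    dG_bind = dE_MM + dG_polar + dG_SASA
    table = pd.DataFrame(
        {
            "residue": labels,
            "dE_MM": dE_MM,
            "dG_polar": dG_polar,
            "dG_SASA": dG_SASA,
            "dG_bind": dG_bind,
        }
    )
    truth = {"top_residue": planted_top_residue}
    return table, truth


# --------------------------------------------------------------- file I/O
def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for set_id, members in sets.items():
            fh.write("\t".join([set_id, set_id] + list(members)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets
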