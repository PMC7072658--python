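"""Protein structure container and PDB input/output.

Atoms are held as flat numpy arrays; residues are lightweight named tuples
used as node identifiers by the residue-interaction-network and tunnel
modules.  Parsing and writing go through biotite; this module adds van der
Waals radius assignment and the polymer/ligand split the downstream stages
need.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

#: Standard van der Waals radii (Å) for the elements that dominate protein
#: heavy atoms.  Unknown elements fall back to the carbon radius.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

#: Backbone (main-chain) atom names; everything else counts as side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class Residue(NamedTuple):
    """Identifier of one residue: (chain, sequence number, 3-letter name)."""

    chain: str
    seq: int
    name: str

    @property
    def label(self) -> str:
        """Human-readable label such as ``Trp441``."""
        return f"{self.name.capitalize()}{self.seq}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (warns on unknowns)."""
    el = element.strip().upper()
    if el not in VDW_RADII:
        warnings.warn(
            f"unknown element {element!r}: using default vdW radius "
            f"{DEFAULT_VDW} Å",
            stacklevel=2,
        )
        return DEFAULT_VDW
    return VDW_RADII[el]


@dataclass
class Structure:
    """A set of atoms with coordinates, residue assignment and vdW radii."""

    atom_name: np.ndarray  # (n,) str
    element: np.ndarray  # (n,) str
    res_seq: np.ndarray  # (n,) int
    res_name: np.ndarray  # (n,) str
    chain: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float, Å
    hetero: np.ndarray  # (n,) bool
    vdw: np.ndarray = field(default=None)  # (n,) float, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.vdw is None:
            with warnings.catch_warnings():
                warnings.simplefilter("once")
                self.vdw = np.array([vdw_radius(e) for e in self.element])
        self.vdw = np.asarray(self.vdw, dtype=float)
        if np.any(self.vdw <= 0):
            raise ValueError("vdW radii must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            res_seq=self.res_seq[mask],
            res_name=self.res_name[mask],
            chain=self.chain[mask],
            coords=self.coords[mask],
            hetero=self.hetero[mask],
            vdw=self.vdw[mask],
        )

    def polymer(self) -> "Structure":
        """Atoms belonging to the polymer (ATOM records)."""
        return self.subset(~self.hetero)

    def ligands(self) -> "Structure":
        """HETATM atoms (ligands, waters, ions)."""
        return self.subset(self.hetero)

    def heavy(self) -> "Structure":
        """Atoms that are not hydrogen/deuterium."""
        el = np.char.upper(self.element.astype(str))
        return self.subset(~np.isin(el, ["H", "D"]))

    def atom_residues(self) -> list[Residue]:
        """Residue identifier of every atom, in atom order."""
        return [
            Residue(str(c), int(s), str(n))
            for c, s, n in zip(self.chain, self.res_seq, self.res_name)
        ]

    @property
    def residues(self) -> list[Residue]:
        """Ordered unique polymer residues (order of first appearance)."""
        seen: dict[Residue, None] = {}
        poly = self.polymer()
        for res in poly.atom_residues():
            seen.setdefault(res, None)
        return list(seen)

    def residue_atom_index(self) -> dict[Residue, np.ndarray]:
        """Map each residue to the indices of its atoms (within self)."""
        out: dict[Residue, list[int]] = {}
        for i, res in enumerate(self.atom_residues()):
            out.setdefault(res, []).append(i)
        return {r: np.asarray(ix, dtype=int) for r, ix in out.items()}

    def residue_centroid(self, residue: Residue, side_chain: bool = True) -> np.ndarray:
        """Centroid of a residue; side-chain atoms preferred if present."""
        index = self.residue_atom_index()
        if residue not in index:
            raise KeyError(f"residue {residue.label} not in structure")
        ix = index[residue]
        if side_chain:
            sc = [i for i in ix if self.atom_name[i] not in BACKBONE_ATOMS]
            if sc:
                ix = np.asarray(sc)
        return self.coords[ix].mean(axis=0)

    # ------------------------------------------------------------------ I/O
    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coords.astype(np.float32)
        arr.atom_name = self.atom_name.astype(str)
        arr.element = np.char.upper(self.element.astype(str))
        arr.res_id = self.res_seq.astype(int)
        arr.res_name = self.res_name.astype(str)
        arr.chain_id = self.chain.astype(str)
        arr.hetero = self.hetero.astype(bool)
        return arr

    def to_pdb(self, path: str | Path) -> None:
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(self.to_atom_array())
        pdb_file.write(str(path))


def _locate_bad_atom_line(text: str) -> int | None:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except (ValueError, IndexError):
            return lineno
    return None


def read_structure(source) -> Structure:
    """Read a PDB file (path, string content, or file-like) into a Structure.

    Alternate locations are resolved to the highest-occupancy conformer;
    insertion-coded residues are kept (insertion codes folded into the
    residue name to preserve uniqueness); HETATM records are retained but
    flagged so the polymer can be separated from ligands and waters.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        p = Path(str(source))
        if p.exists():
            text = p.read_text()
        else:
            text = str(source)
    try:
        pdb_file = pdbio.PDBFile.read(io.StringIO(text))
        array = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        lineno = _locate_bad_atom_line(text)
        if lineno is not None:
            raise ValueError(
                f"unparseable ATOM/HETATM record at line {lineno}"
            ) from exc
        raise ValueError(f"could not parse PDB input: {exc}") from exc

    res_name = array.res_name.astype(str)
    if "ins_code" in array.get_annotation_categories():
        ins = array.ins_code.astype(str)
        has_ins = ins != ""
        if np.any(has_ins):
            res_name = np.array(
                [f"{n}{i}" if i else n for n, i in zip(res_name, ins)]
            )
    return Structure(
        atom_name=array.atom_name.astype(str),
        element=array.element.astype(str),
        res_seq=array.res_id.astype(int),
        res_name=res_name,
        chain=array.chain_id.astype(str),
        coords=np.asarray(array.coord, dtype=float),
        hetero=array.hetero.astype(bool),
    )
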