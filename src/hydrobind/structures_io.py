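"""Molecular structure I/O and binding-pocket extraction.

Proteins are read from PDB files (heavy atoms only, chemistry from fixed
residue templates), ligands from Mol2/SDF via RDKit with explicit bonds, and
crystallographic waters become :class:`WaterSite` records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from hydrobind.residue_templates import lookup as template_lookup

__all__ = [
    "Atom",
    "MolecularStructure",
    "WaterSite",
    "ComplexStructure",
    "StructureParseError",
    "EmptyPocketError",
    "read_pdb",
    "read_ligand",
    "write_pdb",
    "extract_pocket",
]

#: ligand element vocabulary used for the node one-hot (order fixed)
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")

_WATER_RESNAMES = {"HOH", "WAT"}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyPocketError(ValueError):
    """Raised when pocket extraction retains no protein atoms."""


@dataclass
class Atom:
    """One heavy atom (or water oxygen) with coordinates and chemical context."""

    serial: int
    element: str
    coords: np.ndarray
    residue_name: str = ""
    residue_index: int = 0
    chain: str = "A"
    role: str = "protein"  # protein | ligand | water
    name: str = ""
    explicit_valence: int = 0
    heavy_neighbor_count: int = 0
    attached_h_count: int = 0
    implicit_valence: int = 0
    is_aromatic: bool = False
    is_in_ring: bool = False
    is_c_alpha: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.role == "water" and self.element != "O":
            raise ValueError("water atoms must be oxygen")
        if self.is_c_alpha and self.role != "protein":
            raise ValueError("is_c_alpha implies role=protein")
        if self.heavy_neighbor_count < 0:
            raise ValueError("heavy_neighbor_count must be >= 0")


@dataclass
class MolecularStructure:
    """An ordered list of heavy atoms plus an explicit bond list."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    role: str = "protein"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references invalid atom index")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class WaterSite:
    """Predicted or experimental water-oxygen position."""

    coords: np.ndarray
    score: float | None = None
    provenance: str = "experimental"  # hydramap | rism | experimental

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("water site coords must be a finite 3-vector")
        if self.provenance not in {"hydramap", "rism", "experimental"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class ComplexStructure:
    """Protein + ligand + water sites for one (optionally labelled) complex."""

    id: str
    protein: MolecularStructure
    ligand: MolecularStructure
    waters: list[WaterSite] = field(default_factory=list)
    affinity_label: float | None = None
    pocket_cutoff: float | None = None

    def __post_init__(self) -> None:
        if len(self.ligand) < 1:
            raise ValueError("ligand must contain at least one heavy atom")
        if self.affinity_label is not None and not np.isfinite(self.affinity_label):
            raise ValueError("affinity label must be finite")

    def waters_of(self, provenance: str) -> list[WaterSite]:
        return [w for w in self.waters if w.provenance == provenance]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    """Cheap column sanity scan so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}:{lineno}: record too short for coordinates"
                )
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}:{lineno}: unparseable coordinates"
                ) from exc


def read_pdb(path: str | Path) -> tuple[MolecularStructure, list[WaterSite]]:
    """Read a protein PDB file into a heavy-atom structure plus water sites.

    Hydrogens are dropped; per-atom chemical context comes from the residue
    template table.  HOH/WAT records become experimental water sites.
    Alternate locations keep the highest-occupancy conformer (Biopython's
    default disordered-atom selection).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises several exception types
        raise StructureParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    waters: list[WaterSite] = []
    model = next(iter(structure), None)
    if model is None:
        raise StructureParseError(f"{path}: no model records")
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in _WATER_RESNAMES:
                for at in residue:
                    if at.element.strip().upper() != "O":
                        continue
                    waters.append(
                        WaterSite(coords=np.asarray(at.get_coord(), dtype=float),
                                  provenance="experimental")
                    )
                continue
            for at in residue:
                element = (at.element or "").strip()
                element = element[0].upper() + element[1:].lower() if element else ""
                if element == "H" or element == "D":
                    continue
                name = at.get_name().strip().upper()
                tpl = template_lookup(resname, name)
                if tpl is not None:
                    _, ev, hn, hc, ar, ring = tpl
                else:
                    ev = hn = hc = ar = ring = 0
                atoms.append(
                    Atom(
                        serial=at.get_serial_number() or len(atoms) + 1,
                        element=element,
                        coords=np.asarray(at.get_coord(), dtype=float),
                        residue_name=resname,
                        residue_index=residue.get_id()[1],
                        chain=chain.get_id() or "A",
                        role="protein",
                        name=name,
                        explicit_valence=ev,
                        heavy_neighbor_count=hn,
                        attached_h_count=hc,
                        implicit_valence=hc,
                        is_aromatic=bool(ar),
                        is_in_ring=bool(ring),
                        is_c_alpha=(name == "CA" and element == "C"),
                    )
                )
    if not atoms and not waters:
        raise StructureParseError(f"{path}: no atoms found")
    return MolecularStructure(atoms=atoms, role="protein"), waters


def write_pdb(
    path: str | Path,
    structure: MolecularStructure | None = None,
    waters: list[WaterSite] | None = None,
) -> None:
    """Write a structure (ATOM records) and/or water sites (HETATM HOH)."""
    lines: list[str] = []
    serial = 0
    if structure is not None:
        for atom in structure.atoms:
            serial += 1
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:>5} {atom.name:<4.4}{'':1}{atom.residue_name:<3.3}"
                f" {atom.chain:1}{atom.residue_index:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2.2}"
            )
    for i, w in enumerate(waters or [], start=1):
        serial += 1
        x, y, z = w.coords
        lines.append(
            f"HETATM{serial:>5} O    HOH W{i:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"           O"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ligand reading (RDKit)
# ---------------------------------------------------------------------------

def _rdkit_mol(path: Path, fmt: str):
    from rdkit import Chem

    if fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mol = next(iter(supplier), None)
    else:
        raise ValueError(f"unsupported ligand format {fmt!r}")
    if mol is None:
        raise StructureParseError(f"{path}: RDKit could not parse file")
    return mol


def read_ligand(path: str | Path, format: str | None = None) -> MolecularStructure:
    """Read a ligand from Mol2 or SDF; bonds must be explicit in the file.

    The molecule is rebuilt heavy-atom-only and sanitized so that implicit
    hydrogen counts, aromaticity and ring perception are consistent even for
    files without explicit hydrogens.
    """
    from rdkit import Chem
    from rdkit.Chem import RWMol

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "mol":
        fmt = "sdf"
    raw = _rdkit_mol(path, fmt)
    if raw.GetNumBonds() == 0 and raw.GetNumAtoms() > 1:
        raise StructureParseError(
            f"{path}: no bond block; bond perception from geometry is unsupported"
        )

    conf = raw.GetConformer() if raw.GetNumConformers() else None
    has_h = any(a.GetAtomicNum() == 1 for a in raw.GetAtoms())
    # RDKit's Mol2 reader guesses formal charges when hydrogens are absent
    # (e.g. terminal O -> alkoxide); neutralize in that case
    keep_charges = fmt == "sdf" or has_h
    heavy_idx = [a.GetIdx() for a in raw.GetAtoms() if a.GetAtomicNum() > 1]
    index_map = {old: new for new, old in enumerate(heavy_idx)}
    explicit_h = {i: 0 for i in heavy_idx}
    rw = RWMol()
    for old in heavy_idx:
        src = raw.GetAtomWithIdx(old)
        na = Chem.Atom(src.GetSymbol())
        na.SetFormalCharge(src.GetFormalCharge() if keep_charges else 0)
        rw.AddAtom(na)
    for bond in raw.GetBonds():
        b, e = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if b in index_map and e in index_map:
            rw.AddBond(index_map[b], index_map[e], bond.GetBondType())
        elif b in index_map:
            explicit_h[b] += 1
        elif e in index_map:
            explicit_h[e] += 1
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise StructureParseError(f"{path}: sanitization failed ({exc})") from exc

    atoms: list[Atom] = []
    for new, old in enumerate(heavy_idx):
        a = mol.GetAtomWithIdx(new)
        symbol = a.GetSymbol()
        if symbol not in LIGAND_ELEMENTS:
            warnings.warn(
                f"{path}: ligand element {symbol!r} outside the supported "
                f"vocabulary {LIGAND_ELEMENTS}; atom kept",
                stacklevel=2,
            )
        coords = (
            np.asarray(conf.GetAtomPosition(old), dtype=float)
            if conf is not None
            else np.zeros(3)
        )
        h_count = a.GetTotalNumHs() + explicit_h[old]
        atoms.append(
            Atom(
                serial=new + 1,
                element=symbol,
                coords=coords,
                residue_name="LIG",
                residue_index=1,
                chain="L",
                role="ligand",
                name=f"{symbol}{new + 1}",
                explicit_valence=a.GetExplicitValence() + a.GetImplicitValence(),
                heavy_neighbor_count=sum(
                    1 for nb in a.GetNeighbors() if nb.GetAtomicNum() > 1
                ),
                attached_h_count=h_count,
                implicit_valence=h_count,
                is_aromatic=a.GetIsAromatic(),
                is_in_ring=a.IsInRing(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    return MolecularStructure(atoms=atoms, bonds=bonds, role="ligand")


# ---------------------------------------------------------------------------
# Pocket extraction
# ---------------------------------------------------------------------------

def extract_pocket(complex_: ComplexStructure, cutoff: float = 10.0) -> ComplexStructure:
    """Retain whole protein residues with any heavy atom within ``cutoff`` of
    the ligand, and waters within ``cutoff`` of the ligand or kept protein.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_xyz = complex_.ligand.coords
    prot_atoms = complex_.protein.atoms
    if prot_atoms:
        prot_xyz = complex_.protein.coords
        dmin = cdist(prot_xyz, lig_xyz).min(axis=1)
        keep_res = {
            (a.chain, a.residue_index)
            for a, d in zip(prot_atoms, dmin)
            if d < cutoff
        }
        kept = [a for a in prot_atoms if (a.chain, a.residue_index) in keep_res]
    else:
        kept = []
    if not kept:
        raise EmptyPocketError(
            f"no protein residue within {cutoff} Å of the ligand; "
            "try a larger cutoff"
        )
    env_xyz = np.vstack([lig_xyz, np.array([a.coords for a in kept])])
    waters = [
        w
        for w in complex_.waters
        if cdist(w.coords[None, :], env_xyz).min() < cutoff
    ]
    return replace(
        complex_,
        protein=MolecularStructure(atoms=kept, role="protein"),
        waters=waters,
        pocket_cutoff=cutoff,
    )
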