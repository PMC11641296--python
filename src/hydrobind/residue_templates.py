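"""Fixed per-residue chemical-context templates for protein heavy atoms.

PDB files carry no bond information, so per-atom chemistry (explicit valence,
heavy-neighbour count, attached hydrogens, aromaticity, ring membership) for
protein atoms is taken from this deterministic table instead of on-the-fly
perception.  Values follow the standard amino-acid connectivity with backbone
atoms in their peptide-bonded state (N has the preceding carbonyl carbon as a
neighbour, C the following amide nitrogen).

Each entry maps an amino acid three-letter code to a dict of
``atom_name -> (element, explicit_valence, heavy_neighbors, attached_h,
is_aromatic, is_in_ring)``.
"""

from __future__ import annotations

# (element, explicit_valence, heavy_neighbors, attached_h, aromatic, ring)
AtomTemplate = tuple[str, int, int, int, int, int]

_BACKBONE: dict[str, AtomTemplate] = {
    "N": ("N", 3, 2, 1, 0, 0),
    "CA": ("C", 4, 3, 1, 0, 0),
    "C": ("C", 4, 3, 0, 0, 0),
    "O": ("O", 2, 1, 0, 0, 0),
    "OXT": ("O", 2, 1, 0, 0, 0),
}

_CH3 = ("C", 4, 1, 3, 0, 0)
_CH2 = ("C", 4, 2, 2, 0, 0)
_CH = ("C", 4, 3, 1, 0, 0)
_C_SP2 = ("C", 4, 3, 0, 0, 0)  # carbonyl / carboxylate carbon
_O_CARBONYL = ("O", 2, 1, 0, 0, 0)
_O_HYDROXYL = ("O", 2, 1, 1, 0, 0)
_C_AROM_H = ("C", 4, 2, 1, 1, 1)
_C_AROM_SUB = ("C", 4, 3, 0, 1, 1)

_SIDECHAINS: dict[str, dict[str, AtomTemplate]] = {
    "GLY": {},
    "ALA": {"CB": _CH3},
    "VAL": {"CB": _CH, "CG1": _CH3, "CG2": _CH3},
    "LEU": {"CB": _CH2, "CG": _CH, "CD1": _CH3, "CD2": _CH3},
    "ILE": {"CB": _CH, "CG1": _CH2, "CG2": _CH3, "CD1": _CH3},
    "SER": {"CB": _CH2, "OG": _O_HYDROXYL},
    "THR": {"CB": _CH, "OG1": _O_HYDROXYL, "CG2": _CH3},
    "CYS": {"CB": _CH2, "SG": ("S", 2, 1, 1, 0, 0)},
    "MET": {"CB": _CH2, "CG": _CH2, "SD": ("S", 2, 2, 0, 0, 0), "CE": _CH3},
    "ASP": {"CB": _CH2, "CG": _C_SP2, "OD1": _O_CARBONYL, "OD2": _O_CARBONYL},
    "GLU": {"CB": _CH2, "CG": _CH2, "CD": _C_SP2, "OE1": _O_CARBONYL,
            "OE2": _O_CARBONYL},
    "ASN": {"CB": _CH2, "CG": _C_SP2, "OD1": _O_CARBONYL,
            "ND2": ("N", 3, 1, 2, 0, 0)},
    "GLN": {"CB": _CH2, "CG": _CH2, "CD": _C_SP2, "OE1": _O_CARBONYL,
            "NE2": ("N", 3, 1, 2, 0, 0)},
    "LYS": {"CB": _CH2, "CG": _CH2, "CD": _CH2, "CE": _CH2,
            "NZ": ("N", 4, 1, 3, 0, 0)},
    "ARG": {"CB": _CH2, "CG": _CH2, "CD": _CH2,
            "NE": ("N", 3, 2, 1, 0, 0), "CZ": ("C", 6, 3, 0, 0, 0),
            "NH1": ("N", 3, 1, 2, 0, 0), "NH2": ("N", 4, 1, 2, 0, 0)},
    "HIS": {"CB": _CH2, "CG": _C_AROM_SUB, "ND1": ("N", 3, 2, 1, 1, 1),
            "CD2": _C_AROM_H, "CE1": _C_AROM_H, "NE2": ("N", 3, 2, 0, 1, 1)},
    "PHE": {"CB": _CH2, "CG": _C_AROM_SUB, "CD1": _C_AROM_H, "CD2": _C_AROM_H,
            "CE1": _C_AROM_H, "CE2": _C_AROM_H, "CZ": _C_AROM_H},
    "TYR": {"CB": _CH2, "CG": _C_AROM_SUB, "CD1": _C_AROM_H, "CD2": _C_AROM_H,
            "CE1": _C_AROM_H, "CE2": _C_AROM_H, "CZ": _C_AROM_SUB,
            "OH": _O_HYDROXYL},
    "TRP": {"CB": _CH2, "CG": _C_AROM_SUB, "CD1": _C_AROM_H,
            "CD2": _C_AROM_SUB, "NE1": ("N", 3, 2, 1, 1, 1),
            "CE2": _C_AROM_SUB, "CE3": _C_AROM_H, "CZ2": _C_AROM_H,
            "CZ3": _C_AROM_H, "CH2": _C_AROM_H},
    "PRO": {"CB": ("C", 4, 2, 2, 0, 1), "CG": ("C", 4, 2, 2, 0, 1),
            "CD": ("C", 4, 2, 2, 0, 1)},
}

# proline's backbone is part of the pyrrolidine ring
_PRO_BACKBONE: dict[str, AtomTemplate] = {
    "N": ("N", 3, 3, 0, 0, 1),
    "CA": ("C", 4, 3, 1, 0, 1),
    "C": ("C", 4, 3, 0, 0, 0),
    "O": ("O", 2, 1, 0, 0, 0),
    "OXT": ("O", 2, 1, 0, 0, 0),
}

_GLY_BACKBONE = dict(_BACKBONE)
_GLY_BACKBONE["CA"] = ("C", 4, 2, 2, 0, 0)

STANDARD_RESIDUES: tuple[str, ...] = (
    "VAL", "ILE", "LEU", "GLU", "GLN", "ASP", "ASN", "HIS", "TRP", "PHE",
    "TYR", "ARG", "LYS", "SER", "THR", "MET", "ALA", "GLY", "PRO", "CYS",
)


def _build() -> dict[str, dict[str, AtomTemplate]]:
    table: dict[str, dict[str, AtomTemplate]] = {}
    for res in STANDARD_RESIDUES:
        if res == "PRO":
            bb = _PRO_BACKBONE
        elif res == "GLY":
            bb = _GLY_BACKBONE
        else:
            bb = _BACKBONE
        table[res] = {**bb, **_SIDECHAINS[res]}
    return table


RESIDUE_TEMPLATES: dict[str, dict[str, AtomTemplate]] = _build()


def lookup(residue_name: str, atom_name: str) -> AtomTemplate | None:
    """Template for a named protein heavy atom, or None if unknown."""
    res = RESIDUE_TEMPLATES.get(residue_name.upper())
    if res is None:
        return None
    return res.get(atom_name.upper())
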