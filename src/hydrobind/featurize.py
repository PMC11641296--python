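"""Node and edge feature encoding.

Feature layout (58 slots per node):

====== ===========================================================
slots  meaning
====== ===========================================================
0-19   residue type one-hot (protein atoms only)
20-41  protein atom-type one-hot (ECIF-style strings, 22 types)
42-50  ligand/water element one-hot (C, N, O, S, F, Cl, Br, I, P)
51     distance (Å) from the atom to the pocket centroid
52     implicit valence (implicit-hydrogen count)
53-54  aromatic yes/no one-hot
55-56  ring yes/no one-hot
57     attached-hydrogen count
====== ===========================================================

Slot 51 is deliberately a rigid-motion-invariant scalar: raw Cartesian
coordinates stay on the :class:`~hydrobind.structures_io.Atom` and enter the
model only through pairwise distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hydrobind.structures_io import Atom, LIGAND_ELEMENTS

__all__ = [
    "RESIDUE_VOCABULARY",
    "ECIF_VOCABULARY",
    "LIGAND_ELEMENTS",
    "NODE_FEATURE_DIM",
    "EDGE_PAIR_TYPES",
    "EdgeFeature",
    "ecif_type",
    "encode_node",
    "encode_edge",
]

RESIDUE_VOCABULARY: tuple[str, ...] = (
    "VAL", "ILE", "LEU", "GLU", "GLN", "ASP", "ASN", "HIS", "TRP", "PHE",
    "TYR", "ARG", "LYS", "SER", "THR", "MET", "ALA", "GLY", "PRO", "CYS",
)

#: protein atom-type vocabulary, "Element,ExplicitValence,HeavyNeighbors,
#: AttachedH,Aromatic,Ring", fixed order
ECIF_VOCABULARY: tuple[str, ...] = (
    "C,4,2,2,0,0", "N,4,1,2,0,0", "S,2,2,0,0,0", "C,4,3,0,1,1",
    "N,3,1,2,0,0", "C,4,3,0,0,0", "C,4,1,3,0,0", "N,3,2,1,1,1",
    "S,2,1,1,0,0", "C,4,3,1,0,1", "N,3,2,0,1,1", "C,4,3,1,0,0",
    "O,2,1,1,0,0", "N,4,2,1,0,0", "N,3,2,1,0,0", "N,4,1,3,0,0",
    "C,6,3,0,0,0", "C,4,2,2,0,1", "C,4,2,1,1,1", "O,2,1,0,0,0",
    "N,3,3,0,0,1", "C,5,3,0,0,0",
)

NODE_FEATURE_DIM = 58

_N_RES = len(RESIDUE_VOCABULARY)
_N_ECIF = len(ECIF_VOCABULARY)
_N_ELEM = len(LIGAND_ELEMENTS)
_RES_INDEX = {r: i for i, r in enumerate(RESIDUE_VOCABULARY)}
_ECIF_INDEX = {t: i for i, t in enumerate(ECIF_VOCABULARY)}
_ELEM_INDEX = {e: i for i, e in enumerate(LIGAND_ELEMENTS)}

EDGE_PAIR_TYPES: tuple[str, ...] = ("LL", "PL", "PP", "WL", "WP", "WW")
_PAIR_FROM_ROLES = {
    frozenset({"ligand"}): "LL",
    frozenset({"protein", "ligand"}): "PL",
    frozenset({"protein"}): "PP",
    frozenset({"water", "ligand"}): "WL",
    frozenset({"water", "protein"}): "WP",
    frozenset({"water"}): "WW",
}


def ecif_type(atom: Atom) -> str:
    """Assemble the atom-type string "E,v,h,H,a,r" for a protein atom.

    Strings outside the 22-type vocabulary fall back to the nearest type with
    the same element (minimal numeric difference) with a warning.
    """
    if atom.role != "protein":
        raise ValueError("ecif_type applies to protein atoms only")
    raw = (
        f"{atom.element},{atom.explicit_valence},{atom.heavy_neighbor_count},"
        f"{atom.attached_h_count},{int(atom.is_aromatic)},{int(atom.is_in_ring)}"
    )
    if raw in _ECIF_INDEX:
        return raw
    candidates = [t for t in ECIF_VOCABULARY if t.split(",")[0] == atom.element]
    if not candidates:
        raise ValueError(
            f"atom type {raw!r} has no same-element fallback in the vocabulary"
        )
    own = np.array(raw.split(",")[1:], dtype=float)

    def _dist(t: str) -> float:
        return float(np.abs(np.array(t.split(",")[1:], dtype=float) - own).sum())

    best = min(candidates, key=_dist)
    warnings.warn(
        f"atom type {raw!r} not in vocabulary; falling back to {best!r}",
        stacklevel=2,
    )
    return best


def encode_node(atom: Atom, pocket_center: np.ndarray) -> np.ndarray:
    """Encode one atom into the fixed 58-slot feature vector."""
    pocket_center = np.asarray(pocket_center, dtype=float)
    vec = np.zeros(NODE_FEATURE_DIM)
    res = vec[0:_N_RES]
    ecif = vec[_N_RES:_N_RES + _N_ECIF]
    elem = vec[_N_RES + _N_ECIF:_N_RES + _N_ECIF + _N_ELEM]
    base = _N_RES + _N_ECIF + _N_ELEM

    if atom.role == "protein":
        if atom.residue_name in _RES_INDEX:
            res[_RES_INDEX[atom.residue_name]] = 1.0
        else:
            warnings.warn(
                f"residue {atom.residue_name!r} outside the 20-residue "
                "vocabulary; residue block left zero",
                stacklevel=2,
            )
        ecif[_ECIF_INDEX[ecif_type(atom)]] = 1.0
        implicit, aromatic, ring, h_count = (
            atom.implicit_valence, atom.is_aromatic, atom.is_in_ring,
            atom.attached_h_count,
        )
    elif atom.role == "ligand":
        if atom.element in _ELEM_INDEX:
            elem[_ELEM_INDEX[atom.element]] = 1.0
        else:
            warnings.warn(
                f"ligand element {atom.element!r} outside the 9-element "
                "vocabulary; element block left zero",
                stacklevel=2,
            )
        implicit, aromatic, ring, h_count = (
            atom.implicit_valence, atom.is_aromatic, atom.is_in_ring,
            atom.attached_h_count,
        )
    elif atom.role == "water":
        elem[_ELEM_INDEX["O"]] = 1.0
        implicit, aromatic, ring, h_count = 2, False, False, 2
    else:
        raise ValueError(f"unknown atom role {atom.role!r}")

    vec[base] = float(np.linalg.norm(atom.coords - pocket_center))
    vec[base + 1] = float(implicit)
    vec[base + 2:base + 4] = (1.0, 0.0) if aromatic else (0.0, 1.0)
    vec[base + 4:base + 6] = (1.0, 0.0) if ring else (0.0, 1.0)
    vec[base + 6] = float(h_count)
    return vec


@dataclass(frozen=True)
class EdgeFeature:
    """Typed distance edge."""

    distance: float
    pair_type: str

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.pair_type not in EDGE_PAIR_TYPES:
            raise ValueError(f"unknown pair type {self.pair_type!r}")

    def vector(self) -> np.ndarray:
        """7-dim numeric form: [distance, pair-type one-hot(6)]."""
        v = np.zeros(1 + len(EDGE_PAIR_TYPES))
        v[0] = self.distance
        v[1 + EDGE_PAIR_TYPES.index(self.pair_type)] = 1.0
        return v


def pair_type_of(role_a: str, role_b: str) -> str:
    """Order-insensitive pair type for two endpoint roles."""
    key = frozenset({role_a, role_b})
    if key not in _PAIR_FROM_ROLES:
        raise ValueError(f"no pair type for roles ({role_a}, {role_b})")
    return _PAIR_FROM_ROLES[key]


def encode_edge(a: Atom, b: Atom) -> EdgeFeature:
    """Euclidean distance plus role-derived pair type; symmetric in (a, b)."""
    if a is b or (a.role == b.role and a.serial == b.serial
                  and np.allclose(a.coords, b.coords)):
        raise ValueError("cannot build an edge between identical atoms")
    return EdgeFeature(
        distance=float(np.linalg.norm(a.coords - b.coords)),
        pair_type=pair_type_of(a.role, b.role),
    )
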