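"""Attributed complex-graph assembly.

Three variants of the same complex are supported: ``G_A`` (protein + ligand
only), and the water-bearing ``G_B``/``G_C`` built from hydration sites of a
chosen provenance (grid-clustering vs density-peak pipelines by default).

Edge rules (representative-atom mode, the default):

* ligand-ligand: heavy-atom pairs closer than the base cutoff, plus all
  covalent bonds regardless of length;
* protein-ligand: Cα ↔ ligand heavy atom under the base cutoff;
* protein-protein: Cα ↔ Cα under the base cutoff, consecutive-residue Cα
  backbone edges, and residue-internal atom ↔ own-Cα edges (so side-chain
  nodes are never isolated);
* water edges: water O ↔ ligand heavy / protein Cα / water O under the
  water threshold ``T``.

All distance comparisons are strict (<).  Waters left without any edge are
removed from the graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from hydrobind.featurize import EdgeFeature, encode_node, pair_type_of
from hydrobind.structures_io import Atom, ComplexStructure

__all__ = ["ComplexGraph", "build_graph", "graph_stats"]

_VARIANT_PROVENANCE = {"G_A": None, "G_B": "hydramap", "G_C": "rism"}


@dataclass
class ComplexGraph:
    """Undirected attributed graph over pocket atoms (+ optional waters)."""

    atoms: list[Atom]
    node_features: np.ndarray
    edges: list[tuple[int, int, EdgeFeature]]
    variant: str
    water_threshold_T: float
    base_cutoff: float
    complex_id: str = ""
    label: float | None = None
    roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roles:
            self.roles = [a.role for a in self.atoms]
        seen = set()
        for i, j, _ in self.edges:
            if not (0 <= i < j < len(self.atoms)):
                raise ValueError(f"edge ({i},{j}) must satisfy 0 <= i < j < n")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))

    @property
    def n_nodes(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j, _ in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_json_dict(self) -> dict:
        return {
            "complex_id": self.complex_id,
            "variant": self.variant,
            "water_threshold_T": self.water_threshold_T,
            "base_cutoff": self.base_cutoff,
            "label": self.label,
            "roles": self.roles,
            "node_features": [[round(float(v), 9) for v in row]
                              for row in self.node_features],
            "edges": [
                [i, j, round(f.distance, 9), f.pair_type]
                for i, j, f in self.edges
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True)


def _water_atoms(complex_: ComplexStructure, provenance: str | None) -> list[Atom]:
    if provenance is None:
        return []
    return [
        Atom(serial=k + 1, element="O", coords=w.coords, residue_name="HOH",
             residue_index=k + 1, chain="W", role="water", name="O")
        for k, w in enumerate(complex_.waters_of(provenance))
    ]


def build_graph(
    complex_: ComplexStructure,
    variant: str = "G_A",
    water_provenance: str | None = None,
    T: float = 6.0,
    base_cutoff: float = 6.0,
    protein_edge_mode: str = "calpha",
) -> ComplexGraph:
    """Assemble one graph variant from an extracted-pocket complex.

    ``water_provenance`` defaults per variant (G_B -> hydramap, G_C -> rism)
    and can be overridden, e.g. to build a water graph from experimental
    sites.  ``protein_edge_mode`` switches the protein side of inter-node
    distance edges between the default Cα representative and all heavy atoms.
    """
    if T <= 0:
        raise ValueError("water threshold T must be positive")
    if variant not in _VARIANT_PROVENANCE:
        raise ValueError(f"unknown graph variant {variant!r}")
    if protein_edge_mode not in ("calpha", "allheavy"):
        raise ValueError(f"unknown protein_edge_mode {protein_edge_mode!r}")
    if variant == "G_A":
        if water_provenance is not None:
            warnings.warn("variant G_A ignores waters", stacklevel=2)
        provenance = None
    else:
        provenance = water_provenance or _VARIANT_PROVENANCE[variant]

    prot = complex_.protein.atoms
    lig = complex_.ligand.atoms
    wat = _water_atoms(complex_, provenance)
    if variant != "G_A" and not wat:
        warnings.warn(
            f"{complex_.id}: no {provenance!r} waters; {variant} degenerates "
            "to the waterless topology",
            stacklevel=2,
        )

    atoms = list(prot) + list(lig) + wat
    n_p, n_l, n_w = len(prot), len(lig), len(wat)
    xyz = np.array([a.coords for a in atoms]).reshape(-1, 3)
    p_idx = np.arange(n_p)
    l_idx = np.arange(n_p, n_p + n_l)
    w_idx = np.arange(n_p + n_l, n_p + n_l + n_w)
    if protein_edge_mode == "calpha":
        p_rep = np.array([i for i in p_idx if atoms[i].is_c_alpha], dtype=int)
    else:
        p_rep = p_idx

    edge_map: dict[tuple[int, int], float] = {}

    def _add(i: int, j: int) -> None:
        if i == j:
            return
        key = (min(i, j), max(i, j))
        if key not in edge_map:
            edge_map[key] = float(np.linalg.norm(xyz[key[0]] - xyz[key[1]]))

    def _add_pairs(idx_a: np.ndarray, idx_b: np.ndarray, cutoff: float) -> None:
        if len(idx_a) == 0 or len(idx_b) == 0:
            return
        d = cdist(xyz[idx_a], xyz[idx_b])
        for ai, bi in zip(*np.nonzero(d < cutoff)):
            _add(int(idx_a[ai]), int(idx_b[bi]))

    # ligand: distance rule plus covalent bonds kept unconditionally
    _add_pairs(l_idx, l_idx, base_cutoff)
    for bi, bj, _order in complex_.ligand.bonds:
        _add(int(l_idx[bi]), int(l_idx[bj]))
    # protein-ligand and protein-protein at representative level
    _add_pairs(p_rep, l_idx, base_cutoff)
    _add_pairs(p_rep, p_rep, base_cutoff)
    # backbone: consecutive-residue Cα edges, always present
    ca = sorted(
        (i for i in p_idx if atoms[i].is_c_alpha),
        key=lambda i: (atoms[i].chain, atoms[i].residue_index),
    )
    for a, b in zip(ca, ca[1:]):
        if (atoms[a].chain == atoms[b].chain
                and atoms[b].residue_index - atoms[a].residue_index == 1):
            _add(a, b)
    # residue-internal: every non-Cα protein atom to its own residue's Cα
    ca_of = {(atoms[i].chain, atoms[i].residue_index): i for i in ca}
    for i in p_idx:
        if atoms[i].is_c_alpha:
            continue
        anchor = ca_of.get((atoms[i].chain, atoms[i].residue_index))
        if anchor is not None:
            _add(int(i), anchor)
    # water edges under the water threshold T
    _add_pairs(w_idx, l_idx, T)
    _add_pairs(w_idx, p_rep, T)
    _add_pairs(w_idx, w_idx, T)

    # drop waters left isolated, remapping indices
    touched = set()
    for i, j in edge_map:
        touched.update((i, j))
    keep = [
        k for k, a in enumerate(atoms)
        if a.role != "water" or k in touched
    ]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [atoms[k] for k in keep]
    edges = sorted(
        (remap[i], remap[j], d)
        for (i, j), d in edge_map.items()
        if i in remap and j in remap
    )

    pl_xyz = np.array([a.coords for a in atoms if a.role != "water"])
    center = pl_xyz.mean(axis=0)
    features = np.array([encode_node(a, center) for a in atoms])
    edge_feats = [
        (i, j, EdgeFeature(distance=d,
                           pair_type=pair_type_of(atoms[i].role, atoms[j].role)))
        for i, j, d in edges
    ]
    return ComplexGraph(
        atoms=atoms,
        node_features=features,
        edges=edge_feats,
        variant=variant,
        water_threshold_T=T,
        base_cutoff=base_cutoff,
        complex_id=complex_.id,
        label=complex_.affinity_label,
    )


def graph_stats(g: ComplexGraph) -> dict:
    """Node/edge counts by role/pair type plus a degree histogram."""
    role_counts: dict[str, int] = {}
    for r in g.roles:
        role_counts[r] = role_counts.get(r, 0) + 1
    pair_counts = {t: 0 for t in ("LL", "PL", "PP", "WL", "WP", "WW")}
    for _, _, f in g.edges:
        pair_counts[f.pair_type] += 1
    deg = g.degrees()
    hist = np.bincount(deg, minlength=1)
    return {
        "n_nodes": g.n_nodes,
        "n_edges": len(g.edges),
        "nodes_by_role": role_counts,
        "edges_by_pair_type": pair_counts,
        "degree_histogram": hist.tolist(),
    }
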