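"""Synthetic complex generator with a planted, water-driven affinity law.

Produces syntactically valid toy PDB/Mol2 files (and in-memory structures)
whose label follows ``beta + alpha * n_bridge_waters + noise``: bridge waters
sit between a protein backbone oxygen and a ligand heavy atom (< 3.5 Å from
both), decoy waters float far (> 8 Å) from everything so contact filtering
and isolated-node removal both have work to do.  Geometry is idealized, not
physical — parsers and featurizers only need well-formed records and
controllable distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hydrobind.hydration import PocketGrid
from hydrobind.structures_io import (
    Atom,
    ComplexStructure,
    MolecularStructure,
    WaterSite,
    write_pdb,
)

__all__ = ["FixtureSpec", "make_complex", "make_dataset", "make_density_grid",
           "write_mol2"]

_RESIDUE_CYCLE = ("SER", "ALA", "GLY", "VAL", "THR", "LEU")

# local heavy-atom offsets (Å) from the residue anchor; side chains point to
# -y, the ligand sits on the +y side
_RES_OFFSETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "_backbone": {
        "N": (-1.35, 0.40, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (1.20, 0.60, 0.0),
        "O": (1.25, 1.85, 0.0),
    },
    "SER": {"CB": (0.0, -1.20, 0.90), "OG": (0.20, -2.40, 0.20)},
    "ALA": {"CB": (0.0, -1.20, 0.90)},
    "GLY": {},
    "VAL": {"CB": (0.0, -1.20, 0.90), "CG1": (-0.70, -2.30, 0.30),
            "CG2": (1.20, -1.70, 1.20)},
    "THR": {"CB": (0.0, -1.20, 0.90), "OG1": (-0.70, -2.30, 0.30),
            "CG2": (1.20, -1.70, 1.20)},
    "LEU": {"CB": (0.0, -1.20, 0.90), "CG": (0.0, -2.50, 0.50),
            "CD1": (-1.20, -3.20, 0.80), "CD2": (1.10, -3.10, 0.90)},
}

_LIG_ELEMENT_CYCLE = ("C", "C", "O", "C", "N", "C")
_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}
_SYBYL = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3",
          "F": "F", "Cl": "Cl", "Br": "Br", "I": "I"}

_RESIDUE_SPACING = 3.8
_LIGAND_Y = 5.6
_BRIDGE_JITTER = 0.10
_SITE_JITTER = 0.15


@dataclass
class FixtureSpec:
    n_residues: int = 6
    n_ligand_atoms: int = 8
    n_bridge_waters: int = 2
    n_decoy_waters: int = 2
    noise_sd: float = 0.0
    seed: int = 0
    alpha: float = 1.0  # pKd per bridge water
    beta: float = 5.0   # baseline pKd

    def __post_init__(self) -> None:
        if min(self.n_residues, self.n_ligand_atoms) < 1:
            raise ValueError("need at least one residue and one ligand atom")
        if min(self.n_bridge_waters, self.n_decoy_waters) < 0:
            raise ValueError("water counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _protein_atoms(spec: FixtureSpec, rng: np.random.Generator) -> list[Atom]:
    from hydrobind.residue_templates import lookup

    atoms: list[Atom] = []
    serial = 0
    for i in range(spec.n_residues):
        resname = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        anchor = np.array([_RESIDUE_SPACING * i, 0.0, 0.0])
        names = dict(_RES_OFFSETS["_backbone"])
        names.update(_RES_OFFSETS[resname])
        for name, offset in names.items():
            element, ev, hn, hc, ar, ring = lookup(resname, name)
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    element=element,
                    coords=anchor + np.array(offset) + rng.normal(0, 0.05, 3),
                    residue_name=resname,
                    residue_index=i + 1,
                    chain="A",
                    role="protein",
                    name=name,
                    explicit_valence=ev,
                    heavy_neighbor_count=hn,
                    attached_h_count=hc,
                    implicit_valence=hc,
                    is_aromatic=bool(ar),
                    is_in_ring=bool(ring),
                    is_c_alpha=(name == "CA"),
                )
            )
    return atoms


def _ligand(spec: FixtureSpec, rng: np.random.Generator) -> MolecularStructure:
    n = spec.n_ligand_atoms
    x0 = 0.5 * _RESIDUE_SPACING * (spec.n_residues - 1) - 0.7 * (n // 2)
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, float]] = []
    chain: list[int] = []  # backbone-chain atom indices; others are branches
    for j in range(n):
        if j % 4 == 3 and len(chain) >= 2:
            parent = chain[-2]
            coords.append(coords[parent] + np.array([0.0, 1.1, 1.0]))
            bonds.append((parent, j, 1.0))
        else:
            coords.append(np.array([x0 + 1.45 * len(chain), _LIGAND_Y, 0.4]))
            if chain:
                bonds.append((chain[-1], j, 1.0))
            chain.append(j)
    neighbor_count = [0] * n
    for a, b, _ in bonds:
        neighbor_count[a] += 1
        neighbor_count[b] += 1
    atoms = []
    for j in range(n):
        element = _LIG_ELEMENT_CYCLE[j % len(_LIG_ELEMENT_CYCLE)]
        h = max(0, _DEFAULT_VALENCE[element] - neighbor_count[j])
        atoms.append(
            Atom(
                serial=j + 1,
                element=element,
                coords=coords[j] + rng.normal(0, 0.05, 3),
                residue_name="LIG",
                residue_index=1,
                chain="L",
                role="ligand",
                name=f"{element}{j + 1}",
                explicit_valence=_DEFAULT_VALENCE[element],
                heavy_neighbor_count=neighbor_count[j],
                attached_h_count=h,
                implicit_valence=h,
            )
        )
    return MolecularStructure(atoms=atoms, bonds=bonds, role="ligand")


def _bridge_positions(
    spec: FixtureSpec,
    protein: list[Atom],
    ligand: MolecularStructure,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    if spec.n_bridge_waters == 0:
        return []
    lig_xyz = ligand.coords
    pairs: list[tuple[float, np.ndarray, np.ndarray]] = []
    for anchor in (a for a in protein if a.name == "O"):
        d = np.linalg.norm(lig_xyz - anchor.coords, axis=1)
        j = int(np.argmin(d))
        if d[j] < 6.4:  # midpoint then sits < 3.5 Å from both partners
            pairs.append((float(d[j]), anchor.coords, lig_xyz[j]))
    pairs.sort(key=lambda p: p[0])
    if not pairs:
        raise ValueError("no protein oxygen close enough to bridge the ligand")
    # extra waters revisit pairs with a perpendicular offset
    offsets = (0.0, 0.7, -0.7, 1.0, -1.0)
    positions = []
    for k in range(spec.n_bridge_waters):
        rounds, idx = divmod(k, len(pairs))
        if rounds >= len(offsets):
            raise ValueError(
                f"cannot place {spec.n_bridge_waters} bridge waters in a "
                f"pocket with {len(pairs)} anchor pairs"
            )
        _, axyz, lxyz = pairs[idx]
        pos = (0.5 * (axyz + lxyz) + np.array([0.0, 0.0, offsets[rounds]])
               + rng.normal(0, _BRIDGE_JITTER, 3))
        if (np.linalg.norm(pos - axyz) >= 3.5
                or np.linalg.norm(pos - lxyz) >= 3.5):
            raise ValueError("bridge-water geometry infeasible for this spec")
        positions.append(pos)
    return positions


def make_complex(
    spec: FixtureSpec,
    out_dir: str | Path | None = None,
    complex_id: str | None = None,
) -> ComplexStructure:
    """Build one synthetic labelled complex; optionally write PDB/Mol2 files.

    Water sites are attached under all three provenances: exact bridge
    positions as ``experimental``, independently jittered copies as
    ``hydramap`` and ``rism`` (decoys included everywhere).
    """
    rng = np.random.default_rng(spec.seed)
    protein_atoms = _protein_atoms(spec, rng)
    ligand = _ligand(spec, rng)
    bridges = _bridge_positions(spec, protein_atoms, ligand, rng)
    x_span = _RESIDUE_SPACING * spec.n_residues
    decoys = [
        np.array([rng.uniform(0, x_span), rng.uniform(0.0, 4.0), 12.0])
        for _ in range(spec.n_decoy_waters)
    ]
    waters: list[WaterSite] = []
    for provenance in ("experimental", "hydramap", "rism"):
        jitter = 0.0 if provenance == "experimental" else _SITE_JITTER
        for pos in bridges:
            waters.append(WaterSite(coords=pos + rng.normal(0, jitter, 3),
                                    provenance=provenance))
        for pos in decoys:
            waters.append(WaterSite(coords=pos + rng.normal(0, jitter, 3),
                                    provenance=provenance))

    label = spec.beta + spec.alpha * spec.n_bridge_waters
    if spec.noise_sd > 0:
        label += rng.normal(0.0, spec.noise_sd)
    cid = complex_id or f"syn{spec.seed:04d}"
    complex_ = ComplexStructure(
        id=cid,
        protein=MolecularStructure(atoms=protein_atoms, role="protein"),
        ligand=ligand,
        waters=waters,
        affinity_label=float(label),
    )
    if out_dir is not None:
        out = Path(out_dir) / cid
        out.mkdir(parents=True, exist_ok=True)
        write_pdb(out / f"{cid}_protein.pdb", complex_.protein,
                  complex_.waters_of("experimental"))
        write_mol2(out / f"{cid}_ligand.mol2", ligand, name=cid)
    return complex_


def write_mol2(path: str | Path, ligand: MolecularStructure, name: str = "LIG") -> None:
    """Write a minimal Tripos Mol2 file (heavy atoms, explicit bonds)."""
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{len(ligand)} {len(ligand.bonds)} 0 0 0",
        "SMALL",
        "NO_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for k, a in enumerate(ligand.atoms, start=1):
        x, y, z = a.coords
        sybyl = _SYBYL.get(a.element, a.element)
        lines.append(
            f"{k:>4} {a.name:<4} {x:>10.4f} {y:>10.4f} {z:>10.4f} {sybyl:<5} 1 LIG"
        )
    lines.append("@<TRIPOS>BOND")
    for k, (i, j, order) in enumerate(ligand.bonds, start=1):
        kind = "ar" if order == 1.5 else str(int(order))
        lines.append(f"{k:>4} {i + 1:>4} {j + 1:>4} {kind}")
    Path(path).write_text("\n".join(lines) + "\n")


def make_dataset(
    n: int,
    seed: int = 0,
    n_residues: tuple[int, int] = (5, 8),
    n_ligand_atoms: tuple[int, int] = (6, 10),
    max_bridge_waters: int = 5,
    n_decoy_waters: int = 2,
    noise_sd: float = 0.3,
    alpha: float = 1.0,
    beta: float = 5.0,
    out_dir: str | Path | None = None,
) -> list[ComplexStructure]:
    """Generate ``n`` labelled complexes with varied bridge-water counts.

    Bridge counts cycle through 0..max so the planted signal spans its full
    range regardless of ``n``.  When ``out_dir`` is given, files plus a
    PDBbind-style index (``INDEX_synthetic.data``) are written.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    complexes = []
    index_lines = ["# synthetic affinity index", "# code  resolution  year  pK"]
    for k in range(n):
        spec = FixtureSpec(
            n_residues=int(rng.integers(n_residues[0], n_residues[1] + 1)),
            n_ligand_atoms=int(rng.integers(n_ligand_atoms[0],
                                            n_ligand_atoms[1] + 1)),
            n_bridge_waters=k % (max_bridge_waters + 1),
            n_decoy_waters=n_decoy_waters,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            alpha=alpha,
            beta=beta,
        )
        cid = f"syn{k:04d}"
        complex_ = make_complex(spec, out_dir=out_dir, complex_id=cid)
        complexes.append(complex_)
        index_lines.append(
            f"{cid}  2.00  2024  {complex_.affinity_label:.3f}"
        )
    if out_dir is not None:
        Path(out_dir, "INDEX_synthetic.data").write_text(
            "\n".join(index_lines) + "\n"
        )
    return complexes


def make_density_grid(
    sites: list[np.ndarray],
    spacing: float = 0.5,
    peak_width: float = 0.6,
    margin: float = 3.0,
    box: tuple[np.ndarray, np.ndarray] | None = None,
    baseline: float = 1.0,
    peak_height: float = 25.0,
) -> PocketGrid:
    """Sum-of-Gaussians solvent-density grid around planted water positions.

    The baseline plays the role of bulk density, so planted peaks stand out
    for relative-threshold peak extraction.
    """
    sites = [np.asarray(s, dtype=float) for s in sites]
    if box is None:
        if not sites:
            raise ValueError("need sites or an explicit box")
        stack = np.vstack(sites)
        lo, hi = stack.min(axis=0) - margin, stack.max(axis=0) + margin
    else:
        lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)
        for s in sites:
            if np.any(s < lo) or np.any(s > hi):
                raise ValueError("planted site outside the grid box")
    dims = tuple(max(1, int(np.ceil((hi[k] - lo[k]) / spacing))) for k in range(3))
    grid = PocketGrid(origin=lo, spacing=spacing, dims=dims, values=np.zeros(dims))
    centers = grid.voxel_centers()
    values = np.full(len(centers), baseline)
    for s in sites:
        d2 = ((centers - s) ** 2).sum(axis=1)
        values += peak_height * np.exp(-d2 / (2 * peak_width**2))
    grid.values = values.reshape(dims)
    return grid
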