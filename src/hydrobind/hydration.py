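"""Hydration-site prediction for binding pockets.

Two complementary site sources are implemented:

* a grid pipeline — box the pocket, score a water probe on every voxel with a
  pluggable scorer, threshold, then cluster passing voxels with weighted
  flat-kernel mean shift (provenance ``hydramap``);
* density-peak extraction from a 3D solvent-density grid, e.g. parsed from an
  OpenDX file (provenance ``rism``).

Experimental waters from the PDB are carried through unchanged.  The default
probe scorer is a documented surrogate (a sum of Gaussian attractions centred
on polar protein atoms); real statistical potentials can be plugged in via the
``scorer`` callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from hydrobind.structures_io import ComplexStructure, MolecularStructure, WaterSite

__all__ = [
    "PocketGrid",
    "HydrationParams",
    "GaussianPolarScorer",
    "build_pocket_box",
    "score_grid",
    "mean_shift_sites",
    "sites_from_density",
    "filter_contact_waters",
    "match_waters",
]

#: sentinel score for voxels sterically excluded by a heavy atom
CLASH_SCORE = -1.0e9
#: minimum probe-to-heavy-atom distance before a voxel counts as clashing
CLASH_DISTANCE = 2.0


@dataclass
class PocketGrid:
    """Regular axis-aligned scalar grid; values live at voxel centers."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        if self.values.shape != tuple(self.dims):
            raise ValueError("values shape must match dims")

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of voxel-center coordinates in grid flat order."""
        axes = [
            self.origin[k] + (np.arange(self.dims[k]) + 0.5) * self.spacing
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class HydrationParams:
    """Tunables of the grid clustering pipeline."""

    box_margin: float = 4.0
    score_cutoff: float = 5.0
    cluster_radius: float = 2.0
    min_cluster_size: int = 1
    contact_distance: float = 4.0

    def __post_init__(self) -> None:
        for name in ("box_margin", "score_cutoff", "cluster_radius",
                     "min_cluster_size", "contact_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class GaussianPolarScorer:
    """Surrogate probe scorer: sum of Gaussian attractions on polar atoms.

    score(p) = amplitude * sum_a exp(-|p - x_a|^2 / (2 w^2)) over protein
    N/O/S atoms.  Stands in for a knowledge-based potential; the interface is
    any callable mapping an (m, 3) array of probe positions to (m,) scores.
    """

    def __init__(self, protein: MolecularStructure, width: float = 1.0,
                 amplitude: float = 10.0):
        self.centers = np.array(
            [a.coords for a in protein.atoms if a.element in ("N", "O", "S")]
        ).reshape(-1, 3)
        self.width = width
        self.amplitude = amplitude

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        if self.centers.size == 0:
            return np.zeros(len(points))
        d2 = cdist(points, self.centers) ** 2
        return self.amplitude * np.exp(-d2 / (2.0 * self.width**2)).sum(axis=1)


def build_pocket_box(
    ligand: MolecularStructure, margin: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned ligand bounding box expanded by ``margin`` on all faces."""
    if len(ligand) == 0:
        raise ValueError("ligand is empty")
    xyz = ligand.coords
    return xyz.min(axis=0) - margin, xyz.max(axis=0) + margin


def score_grid(
    box: tuple[np.ndarray, np.ndarray],
    spacing: float,
    scorer: Callable[[np.ndarray], np.ndarray],
    protein: MolecularStructure,
    ligand: MolecularStructure | None = None,
) -> PocketGrid:
    """Score a water probe at each voxel center of a grid tiling ``box``.

    Voxels closer than ``CLASH_DISTANCE`` to any protein/ligand heavy atom get
    the ``CLASH_SCORE`` sentinel instead of a scorer value.
    """
    if not (0 < spacing <= 2.0):
        raise ValueError("spacing must lie in (0, 2] Å")
    lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)
    dims = tuple(max(1, int(np.ceil((hi[k] - lo[k]) / spacing))) for k in range(3))
    grid = PocketGrid(origin=lo, spacing=spacing, dims=dims,
                      values=np.zeros(dims))
    centers = grid.voxel_centers()
    values = np.asarray(scorer(centers), dtype=float).reshape(-1)
    bad = ~np.isfinite(values)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"scorer returned non-finite value at voxel {idx}")
    env = [protein.coords] if len(protein) else []
    if ligand is not None and len(ligand):
        env.append(ligand.coords)
    if env:
        dmin = cdist(centers, np.vstack(env)).min(axis=1)
        values = np.where(dmin < CLASH_DISTANCE, CLASH_SCORE, values)
    grid.values = values.reshape(dims)
    return grid


def mean_shift_sites(
    grid: PocketGrid,
    params: HydrationParams | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> list[WaterSite]:
    """Cluster above-threshold voxels with weighted flat-kernel mean shift.

    Every voxel with score >= ``params.score_cutoff`` seeds a trajectory that
    iteratively moves to the score-weighted centroid of passing voxels within
    ``cluster_radius``.  Converged modes closer than ``cluster_radius`` are
    merged; clusters with fewer than ``min_cluster_size`` member voxels are
    dropped.  Site score = summed member weight.
    """
    params = params or HydrationParams()
    centers = grid.voxel_centers()
    values = grid.values.reshape(-1)
    mask = values >= params.score_cutoff
    if not mask.any():
        return []
    pts = centers[mask]
    w = values[mask]
    bw = params.cluster_radius

    modes = pts.copy()
    for _ in range(max_iter):
        d = cdist(modes, pts)
        k = (d <= bw).astype(float) * w[None, :]
        denom = k.sum(axis=1, keepdims=True)
        new = (k @ pts) / denom
        shift = np.linalg.norm(new - modes, axis=1).max()
        modes = new
        if shift < tol:
            break

    # merge converged modes, strongest local density first
    density = ((cdist(modes, pts) <= bw) * w[None, :]).sum(axis=1)
    order = np.argsort(-density)
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(modes[i] - modes[j]) >= bw for j in kept):
            kept.append(i)
    sites: list[WaterSite] = []
    assigned = cdist(modes, modes[kept]).argmin(axis=1)
    for rank, _ in enumerate(kept):
        members = assigned == rank
        if members.sum() < params.min_cluster_size:
            continue
        sites.append(
            WaterSite(
                coords=modes[kept[rank]],
                score=float(w[members].sum()),
                provenance="hydramap",
            )
        )
    return sites


def sites_from_density(
    grid: PocketGrid,
    threshold: float = 2.0,
    provenance: str = "rism",
    merge_distance: float = 2.0,
) -> list[WaterSite]:
    """Extract local density maxima (26-neighbourhood) as water sites.

    A voxel qualifies when it is a strict local maximum and its value is at
    least ``threshold`` times the bulk (grid-wide) mean.  Qualifying maxima
    closer than ``merge_distance`` are merged, keeping the higher peak.
    """
    values = grid.values
    if np.allclose(values, values.reshape(-1)[0]):
        return []
    bulk = float(values.mean())
    footprint_max = ndimage.maximum_filter(values, size=3, mode="constant",
                                           cval=-np.inf)
    is_peak = (values >= footprint_max) & (values >= threshold * bulk)
    idx = np.argwhere(is_peak)
    if idx.size == 0:
        return []
    coords = grid.origin + (idx + 0.5) * grid.spacing
    peak_vals = values[tuple(idx.T)]
    order = np.argsort(-peak_vals)
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(coords[i] - coords[j]) >= merge_distance
               for j in kept):
            kept.append(i)
    return [
        WaterSite(coords=coords[i], score=float(peak_vals[i]),
                  provenance=provenance)
        for i in kept
    ]


def filter_contact_waters(
    sites: list[WaterSite],
    complex_: ComplexStructure,
    contact_distance: float = 4.0,
) -> list[WaterSite]:
    """Keep sites with at least one protein/ligand heavy atom within range.

    Sites of different provenance are never merged — downstream graph variants
    draw on one provenance each.
    """
    if contact_distance <= 0:
        raise ValueError("contact_distance must be positive")
    if not sites:
        return []
    env = np.vstack([complex_.protein.coords, complex_.ligand.coords])
    xyz = np.array([s.coords for s in sites])
    dmin = cdist(xyz, env).min(axis=1)
    return [s for s, d in zip(sites, dmin) if d < contact_distance]


def predict_waters(
    complex_: ComplexStructure,
    mode: str,
    params: HydrationParams | None = None,
    spacing: float = 1.0,
    scorer: Callable[[np.ndarray], np.ndarray] | None = None,
    density_grid: PocketGrid | None = None,
    density_threshold: float = 2.0,
) -> list[WaterSite]:
    """End-to-end site prediction for one complex.

    mode ``hydramap``: box the ligand, score a probe grid (default surrogate
    scorer), mean-shift cluster; mode ``rism``: extract density peaks from
    ``density_grid``; mode ``experimental``: pass the parsed waters through.
    All modes finish with the protein/ligand contact filter.
    """
    params = params or HydrationParams()
    if mode == "hydramap":
        box = build_pocket_box(complex_.ligand, params.box_margin)
        grid = score_grid(box, spacing, scorer or GaussianPolarScorer(complex_.protein),
                          complex_.protein, complex_.ligand)
        sites = mean_shift_sites(grid, params)
    elif mode == "rism":
        if density_grid is None:
            raise ValueError("mode 'rism' needs a density grid")
        sites = sites_from_density(density_grid, threshold=density_threshold)
    elif mode == "experimental":
        sites = complex_.waters_of("experimental")
    else:
        raise ValueError(f"unknown hydration mode {mode!r}")
    return filter_contact_waters(sites, complex_, params.contact_distance)


def match_waters(
    predicted: list[WaterSite],
    reference: list[WaterSite],
    tolerance: float = 2.0,
) -> tuple[int, int]:
    """Greedy one-to-one nearest-neighbour matching under ``tolerance``.

    Returns ``(matched, misplaced)`` where misplaced counts predicted sites
    without a reference partner within tolerance.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not predicted or not reference:
        return 0, len(predicted)
    d = cdist(
        np.array([s.coords for s in predicted]),
        np.array([s.coords for s in reference]),
    )
    matched = 0
    free_pred = set(range(len(predicted)))
    free_ref = set(range(len(reference)))
    while free_pred and free_ref:
        sub = [(d[i, j], i, j) for i in free_pred for j in free_ref]
        dist, i, j = min(sub)
        if dist >= tolerance:
            break
        matched += 1
        free_pred.remove(i)
        free_ref.remove(j)
    return matched, len(predicted) - matched
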