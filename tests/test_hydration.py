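import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from hydrobind.fixtures import FixtureSpec, make_complex, make_density_grid
from hydrobind.hydration import (
    CLASH_SCORE,
    GaussianPolarScorer,
    HydrationParams,
    PocketGrid,
    build_pocket_box,
    filter_contact_waters,
    match_waters,
    mean_shift_sites,
    predict_waters,
    score_grid,
    sites_from_density,
)
from hydrobind.structures_io import Atom, ComplexStructure, MolecularStructure, WaterSite
from hydrobind.volumetric import read_dx, write_dx


def _point_structure(points, role="protein", element="N"):
    atoms = [
        Atom(serial=i + 1, element=element, coords=p,
             residue_name="GLY" if role == "protein" else "LIG", role=role)
        for i, p in enumerate(points)
    ]
    return MolecularStructure(atoms=atoms, role=role)


class TestPocketBox:
    def test_single_atom_margin(self):
        lig = _point_structure([[0.0, 0.0, 0.0]], role="ligand", element="C")
        lo, hi = build_pocket_box(lig, margin=4.0)
        np.testing.assert_allclose(lo, [-4.0, -4.0, -4.0])
        np.testing.assert_allclose(hi, [4.0, 4.0, 4.0])

    def test_zero_margin_is_bounding_box(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        lig = _point_structure(pts, role="ligand", element="C")
        lo, hi = build_pocket_box(lig, margin=0.0)
        np.testing.assert_allclose(lo, pts.min(axis=0))
        np.testing.assert_allclose(hi, pts.max(axis=0))

    def test_containment_and_face_distance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, size=(20, 3))
        margin = 3.0
        lig = _point_structure(pts, role="ligand", element="C")
        lo, hi = build_pocket_box(lig, margin=margin)
        assert np.all(pts > lo) and np.all(pts < hi)
        for axis in range(3):  # exhaustive face scan
            assert (pts[:, axis] - lo[axis]).min() >= margin - 1e-9
            assert (hi[axis] - pts[:, axis]).min() >= margin - 1e-9

    def test_empty_ligand(self):
        with pytest.raises(ValueError):
            build_pocket_box(MolecularStructure(atoms=[], role="ligand"), 4.0)


class TestScoreGrid:
    def test_constant_scorer_uniform_except_clash(self):
        protein = _point_structure([[0.0, 0.0, 0.0]])
        box = (np.array([-3.0, -3.0, -3.0]), np.array([3.0, 3.0, 3.0]))
        grid = score_grid(box, 1.0, lambda pts: np.full(len(pts), 7.0), protein)
        centers = grid.voxel_centers()
        values = grid.values.reshape(-1)
        clash = cdist(centers, np.array([[0.0, 0.0, 0.0]])).min(axis=1) < 2.0
        assert np.all(values[clash] == CLASH_SCORE)
        assert np.all(values[~clash] == 7.0)
        assert clash.any() and (~clash).any()

    def test_clash_voxel_at_1p5(self):
        protein = _point_structure([[0.0, 0.0, 0.0]])
        box = (np.array([1.0, -0.5, -0.5]), np.array([2.0, 0.5, 0.5]))
        grid = score_grid(box, 1.0, lambda pts: np.ones(len(pts)), protein)
        # single voxel centered at (1.5, 0, 0) -> 1.5 Å from the atom
        assert grid.values.reshape(-1)[0] == CLASH_SCORE

    def test_surrogate_scorer_peak_near_polar_atom(self):
        polar = np.array([1.0, -0.5, 0.3])
        protein = _point_structure([polar])
        spacing = 0.5
        box = (polar - 4.0, polar + 4.0)
        grid = score_grid(box, spacing, GaussianPolarScorer(protein), protein)
        centers = grid.voxel_centers()
        values = grid.values.reshape(-1)
        # dense-grid-search oracle over the same voxel centers
        d = cdist(centers, polar[None, :]).ravel()
        oracle = 10.0 * np.exp(-(d**2) / 2.0)
        oracle[d < 2.0] = CLASH_SCORE
        best = centers[np.argmax(values)]
        oracle_best = centers[np.argmax(oracle)]
        assert np.linalg.norm(best - oracle_best) <= spacing + 1e-9

    def test_non_finite_scorer_rejected(self):
        protein = _point_structure([[10.0, 10.0, 10.0]])
        box = (np.array([0.0, 0.0, 0.0]), np.array([2.0, 2.0, 2.0]))

        def bad(points):
            v = np.ones(len(points))
            v[3] = np.nan
            return v

        with pytest.raises(ValueError, match="voxel 3"):
            score_grid(box, 1.0, bad, protein)

    def test_spacing_bounds(self):
        protein = _point_structure([[0.0, 0.0, 0.0]])
        box = (np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            score_grid(box, 2.5, lambda p: np.ones(len(p)), protein)


def _blob_grid(blobs, spacing=0.5, box_lo=(-8, -8, -8), box_hi=(8, 8, 8)):
    """Grid whose value is a weight > cutoff inside given spheres, 0 outside."""
    lo = np.array(box_lo, float)
    hi = np.array(box_hi, float)
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
    grid = PocketGrid(origin=lo, spacing=spacing, dims=dims, values=np.zeros(dims))
    centers = grid.voxel_centers()
    values = np.zeros(len(centers))
    for center, radius, weight in blobs:
        inside = np.linalg.norm(centers - np.asarray(center), axis=1) <= radius
        values[inside] += weight
    grid.values = values.reshape(dims)
    return grid


class TestMeanShift:
    def test_single_tight_blob(self):
        grid = _blob_grid([((1.0, 2.0, -1.0), 0.6, 9.0)])
        sites = mean_shift_sites(grid, HydrationParams())
        assert len(sites) == 1
        assert np.linalg.norm(sites[0].coords - [1.0, 2.0, -1.0]) < 0.5

    def test_two_blobs_ten_angstrom_apart(self):
        grid = _blob_grid([((-5.0, 0.0, 0.0), 0.8, 9.0),
                           ((5.0, 0.0, 0.0), 0.8, 6.0)])
        sites = mean_shift_sites(grid, HydrationParams(cluster_radius=2.0))
        assert len(sites) == 2
        centers = grid.voxel_centers()
        values = grid.values.reshape(-1)
        for blob_center in ([-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]):
            near = np.linalg.norm(centers - blob_center, axis=1) <= 2.0
            w = np.where(values > 0, values, 0.0) * near
            centroid = (centers * w[:, None]).sum(axis=0) / w.sum()
            best = min(
                np.linalg.norm(s.coords - centroid) for s in sites
            )
            assert best < 0.5

    def test_empty_threshold_set(self):
        grid = _blob_grid([((0.0, 0.0, 0.0), 0.6, 2.0)])  # below cutoff 5
        assert mean_shift_sites(grid, HydrationParams()) == []

    def test_sites_inside_box(self):
        grid = _blob_grid([((-5.0, 3.0, 2.0), 1.0, 8.0),
                           ((4.0, -4.0, 0.0), 1.0, 8.0)])
        for site in mean_shift_sites(grid, HydrationParams()):
            assert np.all(site.coords >= grid.origin)
            assert np.all(site.coords <= grid.origin
                          + np.array(grid.dims) * grid.spacing)

    def test_monotone_in_cutoff_and_min_size(self):
        grid = _blob_grid([((-5.0, 0.0, 0.0), 1.0, 6.0),
                           ((5.0, 0.0, 0.0), 0.5, 9.0)])
        counts = [
            len(mean_shift_sites(grid, HydrationParams(score_cutoff=c)))
            for c in (5.0, 7.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)
        counts = [
            len(mean_shift_sites(grid, HydrationParams(min_cluster_size=m)))
            for m in (1, 5, 10_000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDensitySites:
    def test_single_gaussian_peak(self):
        grid = make_density_grid([np.array([1.0, 0.0, -2.0])], spacing=0.5)
        sites = sites_from_density(grid, threshold=2.0)
        assert len(sites) == 1
        assert np.linalg.norm(sites[0].coords - [1.0, 0.0, -2.0]) <= 0.5

    def test_close_peaks_merged(self):
        grid = make_density_grid(
            [np.array([0.0, 0.0, 0.0]), np.array([1.5, 0.0, 0.0])], spacing=0.5
        )
        assert len(sites_from_density(grid, threshold=1.5)) == 1

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_planted_peak_recovery(self, k):
        rng = np.random.default_rng(k)
        while True:  # rejection-sample well-separated sites
            sites = rng.uniform(-6, 6, size=(k, 3))
            if k == 1 or cdist(sites, sites)[np.triu_indices(k, 1)].min() >= 4.0:
                break
        grid = make_density_grid(list(sites), spacing=0.5)
        found = sites_from_density(grid, threshold=2.0)
        assert len(found) == k
        d = cdist(np.array([s.coords for s in found]), sites)
        assert d.min(axis=1).max() <= grid.spacing * np.sqrt(3)

    def test_flat_grid_empty(self):
        grid = PocketGrid(origin=np.zeros(3), spacing=1.0, dims=(4, 4, 4),
                          values=np.full((4, 4, 4), 3.0))
        assert sites_from_density(grid) == []


class TestContactFilter:
    def _complex(self):
        protein = _point_structure([[0.0, 0.0, 0.0]])
        ligand = _point_structure([[5.0, 0.0, 0.0]], role="ligand", element="C")
        return ComplexStructure(id="t", protein=protein, ligand=ligand)

    def test_boundary_inside(self):
        sites = [WaterSite(coords=[5.0, 3.9, 0.0], provenance="hydramap")]
        assert len(filter_contact_waters(sites, self._complex(), 4.0)) == 1

    def test_far_site_dropped(self):
        sites = [WaterSite(coords=[50.0, 0.0, 0.0], provenance="hydramap")]
        assert filter_contact_waters(sites, self._complex(), 4.0) == []

    def test_matches_brute_force(self):
        complex_ = make_complex(FixtureSpec(n_bridge_waters=3,
                                            n_decoy_waters=3, seed=13))
        sites = complex_.waters
        kept = filter_contact_waters(sites, complex_, 4.0)
        env = np.vstack([complex_.protein.coords, complex_.ligand.coords])
        expected = sum(
            1 for s in sites if cdist(s.coords[None, :], env).min() < 4.0
        )
        assert len(kept) == expected
        assert expected > 0

    def test_provenances_kept_separate(self):
        complex_ = make_complex(FixtureSpec(n_bridge_waters=2, seed=13))
        kept = filter_contact_waters(complex_.waters, complex_, 4.0)
        assert {s.provenance for s in kept} == {"experimental", "hydramap", "rism"}


class TestMatchWaters:
    def _sites(self, points, provenance="hydramap"):
        return [WaterSite(coords=p, provenance=provenance) for p in points]

    def test_identical_lists(self):
        pts = np.random.default_rng(0).uniform(-5, 5, size=(6, 3))
        matched, misplaced = match_waters(self._sites(pts), self._sites(pts), 2.0)
        assert (matched, misplaced) == (6, 0)

    def test_shift_beyond_tolerance(self):
        pts = np.random.default_rng(1).uniform(-5, 5, size=(4, 3))
        shifted = pts + np.array([10.0, 0.0, 0.0])
        matched, misplaced = match_waters(self._sites(pts), self._sites(shifted), 2.0)
        assert (matched, misplaced) == (0, 4)

    def test_against_optimal_assignment(self):
        rng = np.random.default_rng(7)
        # well-separated references so the optimal matching is unambiguous
        refs = np.array(list(itertools.product([0.0, 6.0], repeat=3)))[:6]
        preds = refs[:4] + rng.normal(0, 0.3, size=(4, 3))
        preds = np.vstack([preds, [[30.0, 30.0, 30.0]]])
        matched, misplaced = match_waters(self._sites(preds), self._sites(refs), 2.0)
        # brute-force optimal bipartite matching over all assignments
        d = cdist(preds, refs)
        best = 0
        for perm in itertools.permutations(range(len(refs)), len(preds)):
            best = max(best, sum(d[i, j] < 2.0 for i, j in enumerate(perm)))
        assert matched == best
        assert misplaced == len(preds) - best


class TestPipelines:
    def test_hydramap_pipeline_finds_contact_sites(self):
        complex_ = make_complex(FixtureSpec(seed=21))
        params = HydrationParams(score_cutoff=5.0)
        sites = predict_waters(complex_, "hydramap", params=params, spacing=1.0)
        assert all(s.provenance == "hydramap" for s in sites)
        if sites:
            env = np.vstack([complex_.protein.coords, complex_.ligand.coords])
            xyz = np.array([s.coords for s in sites])
            assert cdist(xyz, env).min(axis=1).max() < params.contact_distance

    def test_rism_pipeline_recovers_bridges(self):
        complex_ = make_complex(FixtureSpec(n_bridge_waters=2, seed=22))
        bridges = [w.coords for w in complex_.waters_of("experimental")][:2]
        grid = make_density_grid(bridges, spacing=0.5)
        sites = predict_waters(complex_, "rism", density_grid=grid)
        assert len(sites) == 2

    def test_experimental_passthrough(self):
        complex_ = make_complex(FixtureSpec(n_bridge_waters=2,
                                            n_decoy_waters=2, seed=23))
        sites = predict_waters(complex_, "experimental")
        assert len(sites) == 2  # decoys filtered out

    def test_unknown_mode(self):
        complex_ = make_complex(FixtureSpec(seed=1))
        with pytest.raises(ValueError):
            predict_waters(complex_, "md")


class TestVolumetric:
    def test_dx_round_trip(self, tmp_path):
        grid = make_density_grid([np.array([0.0, 1.0, 2.0])], spacing=0.8)
        path = tmp_path / "grid.dx"
        write_dx(path, grid)
        back = read_dx(path)
        assert back.dims == grid.dims
        np.testing.assert_allclose(back.origin, grid.origin, atol=1e-6)
        np.testing.assert_allclose(back.values, grid.values, rtol=1e-5)

    def test_rejects_garbage(self, tmp_path):
        path = tmp_path / "bad.dx"
        path.write_text("not a grid\n")
        with pytest.raises(ValueError):
            read_dx(path)
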