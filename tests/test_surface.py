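from dataclasses import replace

import numpy as np
import pytest

from patchscreen.pipeline import analyze_structure
from patchscreen.simulate import ClusterSpec, PatchSpec, make_toy_structure
from patchscreen.surface import (
    PatchParams,
    SurfaceCloud,
    assign_surface_values,
    compute_sasa,
    detect_patches,
    patch_summary,
    residue_patch_contributions,
    unit_sphere_points,
    _atom_frames,
)
from tests.conftest import bead_model


def naive_sasa(model, params):
    """Brute-force all-pairs retention on the same dot set as compute_sasa.

    Returns (per-atom SASA, per-atom retained dot counts); the counts are
    the discrete quantity both routes must agree on exactly.
    """
    coords = model.coords()
    radii = model.radii() + params.probe_radius
    sphere = unit_sphere_points(params.points_per_atom)
    frames = _atom_frames(coords)
    out = np.zeros(len(coords))
    counts = np.zeros(len(coords), dtype=int)
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * (sphere @ frames[i].T)
        keep = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            keep &= np.einsum("ij,ij->i", pts - coords[j], pts - coords[j]) > radii[j] ** 2
        counts[i] = keep.sum()
        out[i] = counts[i] * 4.0 * np.pi * radii[i] ** 2 / params.points_per_atom
    return out, counts


class TestSasa:
    def test_isolated_sphere_analytic(self, single_atom_model):
        """An isolated atom's SASA is the expanded-sphere area 4π(r+rp)²."""
        res = compute_sasa(single_atom_model, PatchParams())
        expected = 4.0 * np.pi * (1.7 + 1.8) ** 2
        assert res.total == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_unoccluded(self):
        model = bead_model([(0, 0, 0), (20.0, 0, 0)], ["G", "G"], radius=1.7)
        res = compute_sasa(model, PatchParams())
        expected = 4.0 * np.pi * 3.5**2
        np.testing.assert_allclose(res.atom_sasa, expected, rtol=0.01)

    def test_overlapping_pair_matches_bruteforce_exactly(self):
        model = bead_model([(0, 0, 0), (2.0, 0, 0)], ["G", "G"], radius=1.7)
        params = PatchParams()
        res = compute_sasa(model, params)
        expected, counts = naive_sasa(model, params)
        got_counts = np.round(
            res.atom_sasa * params.points_per_atom
            / (4.0 * np.pi * (model.radii() + params.probe_radius) ** 2)
        ).astype(int)
        np.testing.assert_array_equal(got_counts, counts)
        np.testing.assert_allclose(res.atom_sasa, expected, rtol=1e-12)

    def test_random_cluster_matches_bruteforce(self, rng):
        pos = rng.uniform(0, 8, size=(6, 3))
        model = bead_model(pos, ["G"] * 6, radius=1.7)
        params = PatchParams(points_per_atom=240)
        res = compute_sasa(model, params)
        expected, counts = naive_sasa(model, params)
        got_counts = np.round(
            res.atom_sasa * params.points_per_atom
            / (4.0 * np.pi * (model.radii() + params.probe_radius) ** 2)
        ).astype(int)
        np.testing.assert_array_equal(got_counts, counts)
        np.testing.assert_allclose(res.atom_sasa, expected, rtol=1e-12)

    def test_dot_density_convergence(self):
        """Doubling the dot count moves total SASA by < 0.5%."""
        model, _ = make_toy_structure(
            PatchSpec(clusters=(), n_residues=30, seed=2)
        )
        a = compute_sasa(model, PatchParams(points_per_atom=960)).total
        b = compute_sasa(model, PatchParams(points_per_atom=1920)).total
        assert abs(a - b) / a < 0.005

    def test_empty_model_raises(self):
        from patchscreen.structure import StructureModel

        with pytest.raises(ValueError):
            compute_sasa(StructureModel(atoms=[], residues=[]), PatchParams())

    def test_rigid_motion_invariance(self):
        """SASA and patch areas are unchanged by rotation + translation."""
        model, _ = make_toy_structure(
            PatchSpec(clusters=(ClusterSpec("hydrophobic", 6),), n_residues=60, seed=1)
        )
        params = PatchParams()
        _, _, _, _, s1 = analyze_structure(model, params)
        sasa1 = compute_sasa(model, params).total
        theta = 0.9
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        shift = np.array([5.0, -3.0, 2.0])
        moved = bead_model(
            [rot @ np.array(a.coordinates) + shift for a in model.atoms],
            [r.amino_acid for r in model.residues],
            radius=3.0,
        )
        _, _, _, _, s2 = analyze_structure(moved, params)
        sasa2 = compute_sasa(moved, params).total
        assert abs(sasa1 - sasa2) / sasa1 < 1e-6
        for cls in ("hydrophobic", "positive", "negative"):
            a, b = s1.total_area[cls], s2.total_area[cls]
            assert a == pytest.approx(b, rel=1e-6, abs=1e-6)

    def test_against_independent_dot_surface_implementation(self):
        """Cross-check against biotite's solvent-accessible surface routine.

        Different dot distributions, same geometry: totals should agree to a
        few percent on a small cluster.
        """
        import biotite.structure as struc

        pos = np.array(
            [[0.0, 0, 0], [2.5, 0, 0], [1.2, 2.2, 0], [1.0, 1.0, 2.0]]
        )
        model = bead_model(pos, ["G"] * 4, radius=1.7)
        ours = compute_sasa(model, PatchParams(points_per_atom=1920)).atom_sasa

        arr = struc.AtomArray(4)
        arr.coord = pos.astype(np.float32)
        arr.chain_id = np.array(["A"] * 4)
        arr.res_id = np.arange(1, 5)
        arr.res_name = np.array(["GLY"] * 4)
        arr.atom_name = np.array(["CA"] * 4)
        arr.element = np.array(["C"] * 4)
        theirs = struc.sasa(
            arr,
            probe_radius=1.8,
            point_number=1920,
            vdw_radii=np.full(4, 1.7),
        )
        np.testing.assert_allclose(ours, theirs, rtol=0.03)


def synthetic_cloud(positions, weights, hyd=None, elec=None):
    n = len(positions)
    return SurfaceCloud(
        positions=np.asarray(positions, dtype=float),
        owner_atom=np.zeros(n, dtype=int),
        owner_residue=np.zeros(n, dtype=int),
        area_weight=np.asarray(weights, dtype=float),
        hydrophobic_value=np.asarray(
            hyd if hyd is not None else np.zeros(n), dtype=float
        ),
        electrostatic_value=np.asarray(
            elec if elec is not None else np.zeros(n), dtype=float
        ),
    )


def oracle_components(points, mask, radius):
    """Exhaustive breadth-first connected components under the adjacency rule."""
    idx = [i for i in range(len(points)) if mask[i]]
    unvisited = set(idx)
    comps = []
    while unvisited:
        start = min(unvisited)
        stack, comp = [start], set()
        unvisited.discard(start)
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in list(unvisited):
                if np.linalg.norm(points[u] - points[v]) <= radius:
                    unvisited.discard(v)
                    stack.append(v)
        comps.append(frozenset(comp))
    return set(comps)


class TestDetectPatches:
    def test_no_threshold_exceedance_no_patches(self):
        cloud = synthetic_cloud([[0, 0, 0], [1, 0, 0]], [10, 10], hyd=[0.0, 0.05])
        assert detect_patches(cloud, PatchParams()) == []

    def test_min_area_excludes_small_cluster(self):
        """A contiguous 25 Å² hydrophobic cluster fails the 30 Å² floor."""
        pts = [[i * 0.5, 0, 0] for i in range(5)]
        cloud = synthetic_cloud(pts, [5.0] * 5, hyd=[1.0] * 5)
        assert detect_patches(cloud, PatchParams(adjacency_radius=1.0)) == []

    def test_two_separated_clusters(self):
        pts = [[i * 0.5, 0, 0] for i in range(8)] + [
            [50 + i * 0.5, 0, 0] for i in range(11)
        ]
        w = [5.0] * 8 + [5.0] * 11
        cloud = synthetic_cloud(pts, w, hyd=[1.0] * 19)
        patches = detect_patches(cloud, PatchParams(adjacency_radius=1.0))
        assert sorted(p.area for p in patches) == [40.0, 55.0]

    def test_threshold_is_inclusive(self):
        """A value exactly at the cutoff is included (>= rule)."""
        pts = [[i * 0.5, 0, 0] for i in range(10)]
        cloud = synthetic_cloud(pts, [4.0] * 10, hyd=[0.09] * 10)
        patches = detect_patches(cloud, PatchParams(adjacency_radius=1.0))
        assert len(patches) == 1

    def test_charge_classes_sign_exclusive(self):
        pts = [[i * 0.5, 0, 0] for i in range(10)] + [[20 + i * 0.5, 0, 0] for i in range(10)]
        elec = [40.0] * 10 + [-40.0] * 10
        cloud = synthetic_cloud(pts, [4.0] * 20, elec=elec)
        patches = detect_patches(cloud, PatchParams(adjacency_radius=1.0))
        classes = sorted(p.patch_class for p in patches)
        assert classes == ["negative", "positive"]
        pos = next(p for p in patches if p.patch_class == "positive")
        neg = next(p for p in patches if p.patch_class == "negative")
        assert set(pos.point_indices).isdisjoint(set(neg.point_indices))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_connected_components_oracle(self, seed):
        """Clustering equals exhaustive BFS on random point fixtures."""
        rng = np.random.default_rng(seed)
        n = 60
        pts = rng.uniform(0, 10, size=(n, 3))
        hyd = rng.uniform(-0.2, 0.3, size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        radius = 1.5
        params = PatchParams(adjacency_radius=radius, min_area=1e-9)
        cloud = synthetic_cloud(pts, w, hyd=hyd)
        patches = detect_patches(cloud, params)
        got = {frozenset(int(i) for i in p.point_indices)
               for p in patches if p.patch_class == "hydrophobic"}
        want = oracle_components(pts, hyd >= params.hydrophobic_cutoff, radius)
        assert got == want

    def test_patch_disjointness_and_area_bound(self):
        model, _ = make_toy_structure(
            PatchSpec(clusters=(ClusterSpec("hydrophobic", 6),), n_residues=40, seed=9)
        )
        sasa, cloud, patches, _, _ = analyze_structure(model, PatchParams())
        seen = set()
        for p in patches:
            if p.patch_class != "hydrophobic":
                continue
            pts = set(int(i) for i in p.point_indices)
            assert pts.isdisjoint(seen)
            seen |= pts
        assert sum(p.area for p in patches if p.patch_class == "hydrophobic") <= sasa.total + 1e-9


class TestSurfaceValues:
    def test_single_charge_coulomb(self):
        """+1 e at 10 Å with distance-dependent dielectric 4r: 332.06/400."""
        model = bead_model([(0, 0, 0)], ["K"], radius=1.7)
        cloud = synthetic_cloud([[10.0, 0, 0]], [1.0])
        cloud = assign_surface_values(
            cloud, model, charge_map={"K": 1.0}, include_termini=False
        )
        assert cloud.electrostatic_value[0] == pytest.approx(332.06 / 400.0)

    def test_constant_dielectric(self):
        model = bead_model([(0, 0, 0)], ["K"], radius=1.7)
        cloud = synthetic_cloud([[10.0, 0, 0]], [1.0])
        cloud = assign_surface_values(
            cloud, model, charge_map={"K": 1.0}, dielectric=2.0, include_termini=False
        )
        assert cloud.electrostatic_value[0] == pytest.approx(332.06 / 20.0)

    def test_opposite_charges_cancel_at_midpoint(self):
        model = bead_model([(0, 0, 0), (10.0, 0, 0)], ["K", "D"], radius=1.7)
        cloud = synthetic_cloud([[5.0, 0, 0]], [1.0])
        cloud = assign_surface_values(cloud, model, include_termini=False)
        assert cloud.electrostatic_value[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_glycine_no_hydrophobic_patches(self):
        model, _ = make_toy_structure(PatchSpec(clusters=(), n_residues=20, seed=4))
        model = bead_model(model.coords(), ["G"] * 20)
        sasa = compute_sasa(model, PatchParams())
        cloud = assign_surface_values(sasa.cloud, model, include_termini=False)
        assert np.all(cloud.hydrophobic_value == 0.0)
        assert detect_patches(cloud, PatchParams()) == []

    def test_surface_plot_written(self, tmp_path):
        from patchscreen.surface import save_surface_plot

        model, _ = make_toy_structure(PatchSpec(clusters=(), n_residues=20, seed=1))
        sasa = compute_sasa(model, PatchParams(points_per_atom=60))
        cloud = assign_surface_values(sasa.cloud, model)
        out = tmp_path / "surface.png"
        save_surface_plot(cloud, out)
        assert out.stat().st_size > 0

    def test_missing_scale_entry_names_residue(self):
        model = bead_model([(0, 0, 0)], ["W"])
        sasa = compute_sasa(model, PatchParams(points_per_atom=60))
        with pytest.raises(KeyError, match="W"):
            assign_surface_values(sasa.cloud, model, hydrophobicity_scale={"G": 0.0})


class TestContributionsAndSummary:
    def fixture(self):
        model, members = make_toy_structure(
            PatchSpec(clusters=(ClusterSpec("hydrophobic", 6),), n_residues=60, seed=7)
        )
        sasa, cloud, patches, contribs, summary = analyze_structure(model, PatchParams())
        return model, members, sasa, cloud, patches, contribs, summary

    def test_zero_patches_zero_contributions(self):
        model, _ = make_toy_structure(PatchSpec(clusters=(), n_residues=20, seed=3))
        sasa, cloud, patches, contribs, _ = analyze_structure(model, PatchParams())
        hyd = [p for p in patches if p.patch_class == "hydrophobic"]
        assert hyd == []
        assert all(c.res_hyd == 0.0 for c in contribs)
        assert all(c.res_asa > 0 for c in contribs)

    def test_shares_sum_to_patch_area(self):
        _, _, sasa, cloud, patches, contribs, _ = self.fixture()
        for p in patches:
            assert sum(p.residue_shares.values()) == pytest.approx(p.area, abs=1e-6)

    def test_contributions_match_pointwise_tally(self):
        _, _, sasa, cloud, patches, contribs, _ = self.fixture()
        tally = {}
        for p in patches:
            if p.patch_class != "hydrophobic":
                continue
            for i in p.point_indices:
                r = int(cloud.owner_residue[i])
                tally[r] = tally.get(r, 0.0) + float(cloud.area_weight[i])
        for c in contribs:
            assert c.res_hyd == pytest.approx(tally.get(c.residue_index, 0.0), abs=1e-9)

    def test_contribution_bounded_by_asa(self):
        _, _, _, _, _, contribs, _ = self.fixture()
        for c in contribs:
            assert 0.0 <= c.res_hyd <= c.res_asa + 1e-9

    def test_summary_totals_conserve(self):
        model, _, _, _, patches, _, summary = self.fixture()
        for cls in ("hydrophobic", "positive", "negative"):
            assert summary.total_area[cls] == pytest.approx(
                sum(p.area for p in patches if p.patch_class == cls)
            )

    def test_near_cdr_counting(self):
        from patchscreen.structure import annotate_regions

        model, members, *_ = self.fixture()
        cluster = sorted(members[0])
        # annotate the cluster residues as a CDR, everything else untouched
        lo, hi = str(cluster[0] + 1), str(cluster[0] + 1)
        annotated = annotate_regions(model, [("A", lo, hi, "CDR-H1")])
        _, _, patches, _, summary = analyze_structure(annotated, PatchParams())
        assert summary.near_cdr_count["hydrophobic"] == 1
        plain = annotate_regions(model, [])
        _, _, _, _, s0 = analyze_structure(plain, PatchParams())
        assert s0.near_cdr_count["hydrophobic"] == 0
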