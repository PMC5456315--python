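import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episurf.constants import KT_TO_KCAL
from episurf.electrostatics import GridSpec, PotentialGrid
from episurf.epsim import (
    DistanceMatrix,
    RegionMask,
    RegionSpec,
    anchor_from_motif,
    anchor_sphere_mask,
    compute_skin_mask,
    ep_distance_matrix,
    mean_potential_difference,
    similarity_index,
)
from episurf.structure_io import Atom, Structure


def single_atom(radius=2.0, center=(0.0, 0.0, 0.0)):
    return Structure(atoms=[Atom(1, "X", "C", "ALA", 1, "A",
                                 np.asarray(center, float),
                                 charge=0.0, radius=radius)])


def brute_force_skin(s, g, sigma, delta):
    pts = g.point_coords()
    centers, radii = s.coords(), s.radii()
    member = np.zeros(len(pts), dtype=bool)
    for k, p in enumerate(pts):
        dmin = min(np.linalg.norm(p - c) - r
                   for c, r in zip(centers, radii))
        member[k] = sigma <= dmin <= sigma + delta
    return member.reshape(g.dims)


class TestSkinMask:
    def test_single_atom_matches_brute_force(self):
        s = single_atom(radius=2.0)
        g = GridSpec(origin=(-12.0,) * 3, h=0.5, dims=(49, 49, 49))
        mask = compute_skin_mask(s, g, sigma=3.0, delta=4.0)
        np.testing.assert_array_equal(mask.members,
                                      brute_force_skin(s, g, 3.0, 4.0))
        # shell bounds: 5 <= |x| <= 9 for the on-axis points
        pts = g.point_coords()[mask.members.ravel()]
        d = np.linalg.norm(pts, axis=1)
        assert d.min() >= 5.0 - 1e-9 and d.max() <= 9.0 + 1e-9

    def test_zero_delta_rejected(self):
        s = single_atom()
        g = GridSpec(origin=(-12.0,) * 3, h=1.0, dims=(25, 25, 25))
        with pytest.raises(ValueError, match="delta"):
            compute_skin_mask(s, g, sigma=3.0, delta=0.0)

    def test_two_distant_atoms_disjoint_shells(self):
        s2 = Structure(atoms=[
            Atom(1, "X", "C", "ALA", 1, "A", np.array([-20.0, 0, 0]),
                 radius=2.0),
            Atom(2, "Y", "C", "ALA", 2, "A", np.array([20.0, 0, 0]),
                 radius=2.0)])
        g = GridSpec(origin=(-32.0, -12.0, -12.0), h=1.0, dims=(65, 25, 25))
        mask = compute_skin_mask(s2, g, 3.0, 4.0)
        np.testing.assert_array_equal(mask.members,
                                      brute_force_skin(s2, g, 3.0, 4.0))
        s1 = single_atom(radius=2.0)
        g1 = GridSpec(origin=(-12.0,) * 3, h=1.0, dims=(25, 25, 25))
        single_count = compute_skin_mask(s1, g1, 3.0, 4.0).n_points
        assert mask.n_points == 2 * single_count

    def test_no_atoms_error(self):
        g = GridSpec(origin=(0, 0, 0), h=1.0, dims=(4, 4, 4))
        with pytest.raises(ValueError, match="no atoms"):
            compute_skin_mask(Structure(), g, 3.0, 4.0)

    def test_empty_mask_error(self):
        s = single_atom(radius=2.0)
        g = GridSpec(origin=(-1.0,) * 3, h=1.0, dims=(3, 3, 3))
        with pytest.raises(ValueError, match="empty skin"):
            compute_skin_mask(s, g, 3.0, 4.0)


def line_of_ca(sequence, spacing=1.0):
    atoms = []
    for i, aa in enumerate(sequence):
        from episurf.structure_io import ONE_TO_THREE

        atoms.append(Atom(i + 1, "CA", "C", ONE_TO_THREE[aa], i + 1, "A",
                          np.array([i * spacing, 0.0, 0.0])))
    return Structure(atoms=atoms)


class TestAnchorFromMotif:
    def test_centroid_of_first_occurrence(self):
        s = line_of_ca("AAACFTAAA")
        anchor = anchor_from_motif(s, "CFT", "A")
        np.testing.assert_allclose(anchor, [4.0, 0.0, 0.0])

    def test_missing_motif_error(self):
        with pytest.raises(ValueError, match="CFT"):
            anchor_from_motif(line_of_ca("AAAA"), "CFT", "A")

    def test_double_occurrence_warns_uses_first(self):
        s = line_of_ca("CFTACFTA")
        with pytest.warns(UserWarning, match="first occurrence"):
            anchor = anchor_from_motif(s, "CFT", "A")
        np.testing.assert_allclose(anchor, [1.0, 0.0, 0.0])


def tiny_grid_pair(values_a, values_b, member_idx):
    g = GridSpec(origin=(0, 0, 0), h=1.0, dims=(2, 2, 2))
    va = np.zeros(g.dims)
    vb = np.zeros(g.dims)
    members = np.zeros(g.dims, dtype=bool)
    for idx, a_val, b_val in zip(member_idx, values_a, values_b):
        va[idx], vb[idx] = a_val, b_val
        members[idx] = True
    return (PotentialGrid(g, va), PotentialGrid(g, vb),
            RegionMask(g, members))


class TestSimilarityIndex:
    def test_self_similarity(self):
        a, _, m = tiny_grid_pair([1.0, 2.0], [0, 0],
                                 [(0, 0, 0), (1, 1, 1)])
        res = similarity_index(a, a, m)
        assert res.si == pytest.approx(1.0)
        assert res.distance == pytest.approx(0.0)

    def test_negation(self):
        g = GridSpec(origin=(0, 0, 0), h=1.0, dims=(2, 2, 2))
        vals = np.arange(8, dtype=float).reshape(2, 2, 2) + 1
        a = PotentialGrid(g, vals)
        b = PotentialGrid(g, -vals)
        m = RegionMask(g, np.ones(g.dims, dtype=bool))
        res = similarity_index(a, b, m)
        assert res.si == pytest.approx(-1.0)
        assert res.distance == pytest.approx(2.0)

    def test_hand_computed_hodgkin(self):
        a, b, m = tiny_grid_pair([1.0, 1.0], [1.0, 0.0],
                                 [(0, 0, 0), (1, 1, 1)])
        res = similarity_index(a, b, m, "hodgkin")
        assert res.si == pytest.approx(2.0 / 3.0)
        assert res.distance == pytest.approx(np.sqrt(2.0 / 3.0))
        assert res.n_points == 2

    def test_hand_computed_carbo(self):
        a, b, m = tiny_grid_pair([1.0, 1.0], [1.0, 0.0],
                                 [(0, 0, 0), (1, 1, 1)])
        res = similarity_index(a, b, m, "carbo")
        assert res.si == pytest.approx(1.0 / np.sqrt(2.0))

    def test_zero_fields_error(self):
        a, b, m = tiny_grid_pair([0.0], [0.0], [(0, 0, 0)])
        with pytest.raises(ValueError, match="zero"):
            similarity_index(a, b, m)

    def test_mismatched_grids_error(self):
        a, _, m = tiny_grid_pair([1.0], [0.0], [(0, 0, 0)])
        g2 = GridSpec(origin=(1, 0, 0), h=1.0, dims=(2, 2, 2))
        b = PotentialGrid(g2, np.ones(g2.dims))
        with pytest.raises(ValueError, match="share"):
            similarity_index(a, b, m)

    def test_symmetry(self):
        a, b, m = tiny_grid_pair([1.0, -2.0], [0.5, 1.5],
                                 [(0, 0, 0), (1, 0, 1)])
        assert similarity_index(a, b, m).si == \
            pytest.approx(similarity_index(b, a, m).si)

    @given(lam=st.floats(min_value=0.1, max_value=50.0),
           mu=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scaling_invariance(self, lam, mu):
        g = GridSpec(origin=(0, 0, 0), h=1.0, dims=(2, 2, 2))
        rng = np.random.default_rng(7)
        va = rng.normal(size=g.dims)
        vb = rng.normal(size=g.dims)
        m = RegionMask(g, np.ones(g.dims, dtype=bool))
        base_h = similarity_index(PotentialGrid(g, va),
                                  PotentialGrid(g, vb), m, "hodgkin").si
        same_h = similarity_index(PotentialGrid(g, lam * va),
                                  PotentialGrid(g, lam * vb), m,
                                  "hodgkin").si
        assert same_h == pytest.approx(base_h, rel=1e-9)
        base_c = similarity_index(PotentialGrid(g, va),
                                  PotentialGrid(g, vb), m, "carbo").si
        indep_c = similarity_index(PotentialGrid(g, lam * va),
                                   PotentialGrid(g, mu * vb), m, "carbo").si
        assert indep_c == pytest.approx(base_c, rel=1e-9)


class TestMeanPotentialDifference:
    def test_identical_fields(self):
        a, _, m = tiny_grid_pair([1.0, 2.0], [0, 0],
                                 [(0, 0, 0), (0, 1, 1)])
        assert mean_potential_difference(a, a, m) == 0.0

    def test_constant_offset(self):
        g = GridSpec(origin=(0, 0, 0), h=1.0, dims=(2, 2, 2))
        rng = np.random.default_rng(3)
        va = rng.normal(size=g.dims)
        c = 1.7
        a = PotentialGrid(g, va)
        b = PotentialGrid(g, va + c)
        m = RegionMask(g, np.ones(g.dims, dtype=bool))
        assert mean_potential_difference(b, a, m) == \
            pytest.approx(c * KT_TO_KCAL)

    def test_hand_computed(self):
        a, b, m = tiny_grid_pair([2.0, 0.0], [0.0, 0.0],
                                 [(0, 0, 0), (1, 1, 0)])
        assert mean_potential_difference(a, b, m) == pytest.approx(0.5922)

    def test_antisymmetry(self):
        a, b, m = tiny_grid_pair([2.0, -1.0], [0.5, 0.25],
                                 [(0, 0, 0), (1, 1, 0)])
        assert mean_potential_difference(a, b, m) == \
            pytest.approx(-mean_potential_difference(b, a, m))


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_csv_round_trip(self, tmp_path):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1.0, 2.0], [1.0, 0, 0.5],
                                      [2.0, 0.5, 0]]))
        path = tmp_path / "d.csv"
        dm.to_csv(path)
        again = DistanceMatrix.from_csv(path)
        assert again.labels == dm.labels
        np.testing.assert_allclose(again.values, dm.values)

    def test_phylip_output(self, tmp_path):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        path = tmp_path / "d.phy"
        dm.to_phylip(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("a")


class TestEpDistanceMatrix:
    def grids_for(self, n, seed=0):
        """n superposed single-atom structures with random potentials."""
        g = GridSpec(origin=(-12.0,) * 3, h=1.0, dims=(25, 25, 25))
        rng = np.random.default_rng(seed)
        entries = []
        for k in range(n):
            s = single_atom(radius=2.0)
            vals = rng.normal(size=g.dims)
            entries.append((f"s{k}", s, PotentialGrid(g, vals)))
        return entries

    def test_single_entry(self):
        dm = ep_distance_matrix(self.grids_for(1))
        assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0.0

    def test_duplicate_entries_zero_distance(self):
        entries = self.grids_for(1)
        lab, s, grid = entries[0]
        dm = ep_distance_matrix([(lab, s, grid), ("dup", s, grid)])
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_symmetry_and_bounds(self):
        dm = ep_distance_matrix(self.grids_for(4))
        np.testing.assert_allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values >= 0) and np.all(dm.values <= 2)

    def test_mismatched_grids_rejected(self):
        entries = self.grids_for(2)
        lab, s, _ = entries[1]
        g2 = GridSpec(origin=(-13.0,) * 3, h=1.0, dims=(25, 25, 25))
        entries[1] = (lab, s, PotentialGrid(g2, np.zeros(g2.dims)))
        with pytest.raises(ValueError, match="differs"):
            ep_distance_matrix(entries)

    def test_anchored_region_restricts_points(self):
        entries = self.grids_for(2)
        whole = ep_distance_matrix(entries)
        anchored = ep_distance_matrix(
            entries, RegionSpec(mode="anchored", anchor=(0.0, 0.0, 0.0),
                                radius=6.0))
        n_whole = whole.metadata["n_points"]["s0|s1"]
        n_anch = anchored.metadata["n_points"]["s0|s1"]
        assert 0 < n_anch < n_whole


class TestRegionSpec:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            RegionSpec(sigma=-1.0)
        with pytest.raises(ValueError):
            RegionSpec(delta=0.0)
        with pytest.raises(ValueError):
            RegionSpec(radius=0.0)
        with pytest.raises(ValueError):
            RegionSpec(mode="anchored")  # no anchor

    def test_anchor_sphere(self):
        g = GridSpec(origin=(-5.0,) * 3, h=1.0, dims=(11, 11, 11))
        m = anchor_sphere_mask(g, (0, 0, 0), 2.0)
        pts = g.point_coords()[m.members.ravel()]
        assert np.all(np.linalg.norm(pts, axis=1) <= 2.0 + 1e-9)
        assert m.n_points > 0
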