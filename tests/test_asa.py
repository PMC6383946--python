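import numpy as np
import pytest

from macromol.asa import (AsaParams, AsaResult, UnknownRadiusError,
                          atom_radius, buried_surface, calc_asa,
                          max_asa_table, relative_asa, sphere_points)
from macromol.fixtures import make_polyala
from macromol.geometry import RigidTransform, apply_transform
from macromol.model import Atom, Group


def lone_atom(element="C", coords=(0.0, 0.0, 0.0), serial=1, name=None):
    g = Group("LIG", serial, category="hetero")
    a = Atom(serial, name or element, element, coords)
    g.add_atom(a)
    return a


def cap_area(r: float, d: float) -> float:
    """Spherical-cap area cut from a sphere of radius r by the bisector
    plane of two centers separated by d (closed form)."""
    h = r - d / 2.0
    return 2.0 * np.pi * r * h


class TestSpherePoints:
    def test_unit_norm(self):
        for n in (12, 100, 960):
            pts = sphere_points(n)
            np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                       atol=1e-12)

    def test_centroid_near_origin(self):
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 0.05

    def test_minimum_count_distinct(self):
        pts = sphere_points(12)
        assert len(np.unique(np.round(pts, 9), axis=0)) == 12

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            sphere_points(11)


class TestCalcAsa:
    def test_isolated_carbon_analytic(self):
        a = lone_atom("C")
        res = calc_asa([a])
        assert res.total == pytest.approx(4 * np.pi * 3.10 ** 2, rel=1e-12)

    def test_distant_atoms_unoccluded(self):
        a = lone_atom("C", (0, 0, 0), 1)
        b = lone_atom("C", (100, 0, 0), 2)
        res = calc_asa([a, b])
        iso = 4 * np.pi * 3.10 ** 2
        assert res.per_atom[a] == pytest.approx(iso)
        assert res.per_atom[b] == pytest.approx(iso)

    def test_two_atom_occlusion_matches_cap_formula(self):
        d = 2.0
        a = lone_atom("C", (0, 0, 0), 1)
        b = lone_atom("C", (d, 0, 0), 2)
        res = calc_asa([a, b])
        r = 1.70 + 1.4
        expect = 4 * np.pi * r * r - cap_area(r, d)
        assert res.per_atom[a] == pytest.approx(expect, rel=0.02)
        assert res.per_atom[b] == pytest.approx(expect, rel=0.02)

    def test_total_is_sum_of_atoms_and_residues(self, helix):
        res = calc_asa(helix.atoms)
        assert res.total == pytest.approx(sum(res.per_atom.values()))
        assert res.total == pytest.approx(sum(res.per_residue_abs.values()))
        assert all(v >= 0 for v in res.per_atom.values())

    def test_translation_invariance_exact(self, helix):
        atoms = helix.atoms
        before = calc_asa(atoms).total
        for a in atoms:
            a.coords = a.coords + np.array([11.0, -3.0, 7.0])
        after = calc_asa(atoms).total
        assert after == pytest.approx(before, rel=1e-9)

    def test_rotation_invariance_to_discretization(self, helix):
        """Rotating the molecule re-samples the fixed test-point
        directions, so the total only matches to the discretization
        error of the point set (well under 1%)."""
        atoms = helix.atoms
        before = calc_asa(atoms).total
        ang = 0.83
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        t = RigidTransform(R, np.zeros(3))
        for a in atoms:
            a.coords = apply_transform(t, a.coords)
        after = calc_asa(atoms).total
        assert after == pytest.approx(before, rel=0.01)

    def test_point_count_convergence(self, helix):
        atoms = helix.atoms
        coarse = calc_asa(atoms, AsaParams(n_sphere_points=960)).total
        fine = calc_asa(atoms, AsaParams(n_sphere_points=3000)).total
        assert abs(fine - coarse) / fine < 0.01

    def test_unknown_element_reported(self):
        a = lone_atom("XX", name="XX1")
        with pytest.raises(UnknownRadiusError, match="XX1"):
            calc_asa([a])

    def test_reference_implementation_agreement(self, helix):
        """Per-residue absolute ASA within 3% of an independent
        Shrake-Rupley implementation at matched radii and probe."""
        import tempfile

        import biotite.structure as bst
        import biotite.structure.io.pdb as bpdb

        from macromol.pdbio import write_pdb

        atoms = helix.atoms
        mine = calc_asa(atoms, AsaParams(n_sphere_points=960))
        with tempfile.NamedTemporaryFile("w", suffix=".pdb") as fh:
            fh.write(write_pdb(helix))
            fh.flush()
            arr = bpdb.PDBFile.read(fh.name).get_structure(model=1)
        radii = np.array([atom_radius(a) for a in atoms])
        ref = bst.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                       point_number=960)
        ref_per_res: dict[int, float] = {}
        for rid, area in zip(arr.res_id, ref):
            ref_per_res[rid] = ref_per_res.get(rid, 0.0) + float(area)
        for g, area in mine.per_residue_abs.items():
            assert area == pytest.approx(ref_per_res[g.seq_id_auth],
                                         rel=0.03, abs=0.5)


class TestRelativeAsa:
    def test_table_lookup_exact(self):
        assert max_asa_table()["GLY"] == 104.0

    def test_exposed_central_residue_fraction_near_one(self):
        """The central residue of an extended tripeptide is the reference
        state of the max-ASA table, so its backbone-only fraction must not
        exceed ~1 and a full side chain would approach 1."""
        s = make_polyala(3, phi=-139.0, psi=135.0)
        res = calc_asa(s.atoms)
        mid = s.chains[0].groups[1]
        frac = res.per_residue_rel[mid]
        # backbone-only alanine: clearly positive, bounded by full exposure
        assert 0.3 < frac < 1.1

    def test_non_standard_residue_has_null_fraction(self):
        a = lone_atom("C")
        res = calc_asa([a])
        assert res.per_residue_rel[a.group] is None


class TestBuriedSurface:
    def test_distant_components_bury_nothing(self):
        a = lone_atom("C", (0, 0, 0), 1)
        b = lone_atom("C", (100, 0, 0), 2)
        bsa, _ = buried_surface([a, b], [a], [b])
        assert abs(bsa) < 1e-6

    def test_two_sphere_bsa_matches_cap_closed_form(self):
        d = 3.0
        a = lone_atom("C", (0, 0, 0), 1)
        b = lone_atom("C", (d, 0, 0), 2)
        bsa, per_res = buried_surface([a, b], [a], [b])
        r = 1.70 + 1.4
        assert bsa == pytest.approx(2 * cap_area(r, d), rel=0.02)
        assert per_res[a.group] == pytest.approx(cap_area(r, d), rel=0.02)

    def test_symmetric_in_component_swap(self):
        rng = np.random.default_rng(21)
        atoms_a = [lone_atom("C", c, i + 1)
                   for i, c in enumerate(rng.uniform(0, 6, (5, 3)))]
        atoms_b = [lone_atom("C", c + np.array([4.0, 0, 0]), i + 6)
                   for i, c in enumerate(rng.uniform(0, 6, (5, 3)))]
        both = atoms_a + atoms_b
        bsa_ab, _ = buried_surface(both, atoms_a, atoms_b)
        bsa_ba, _ = buried_surface(both, atoms_b, atoms_a)
        assert bsa_ab == pytest.approx(bsa_ba)
        assert bsa_ab >= -1e-6

    def test_non_partition_rejected(self):
        a = lone_atom("C", (0, 0, 0), 1)
        b = lone_atom("C", (2, 0, 0), 2)
        with pytest.raises(ValueError, match="partition"):
            buried_surface([a, b], [a], [a])
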