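import numpy as np
import pytest

from macromol.contacts import brute_force_contacts
from macromol.fixtures import make_crystal_toy, make_polyala
from macromol.geometry import superpose
from macromol.model import CrystalCell
from macromol.xtal import (CrystalNeighbor, SpaceGroupOp,
                           UnknownSpaceGroupError, _image_chain,
                           crystal_contacts, frac_orth_matrices,
                           lattice_neighbors, sohncke_group_names,
                           space_group_ops)


class TestSpaceGroupOps:
    def test_p1_is_identity_only(self):
        ops = space_group_ops("P 1")
        assert len(ops) == 1
        assert ops[0].is_identity

    def test_p212121_has_four_operators(self):
        ops = space_group_ops("P 21 21 21")
        assert len(ops) == 4
        assert ops[0].is_identity

    def test_sixty_five_sohncke_groups_shipped(self):
        assert len(sohncke_group_names()) == 65

    def test_non_sohncke_rejected(self):
        with pytest.raises(UnknownSpaceGroupError, match="P -1"):
            space_group_ops("P -1")

    def test_group_axioms_for_all_65_groups(self):
        """Identity membership and closure under composition mod lattice
        translations, for every shipped group."""
        for name in sohncke_group_names():
            ops = space_group_ops(name)
            assert ops[0].is_identity, name
            keyset = {(op.rotation, op.translation) for op in ops}
            assert len(keyset) == len(ops), name
            for a in ops:
                for b in ops:
                    c = a.compose(b)
                    assert (c.rotation, c.translation) in keyset, name

    def test_operator_counts_match_reference_tables(self):
        gemmi = pytest.importorskip("gemmi")
        for name in sohncke_group_names():
            sg = gemmi.find_spacegroup_by_name(name)
            assert sg is not None, name
            assert len(space_group_ops(name)) == \
                len(list(sg.operations())), name

    def test_triplet_parse_roundtrip(self):
        op = SpaceGroupOp.from_triplet("-x+1/2,-y,z+1/2")
        assert op.translation_array() == pytest.approx([0.5, 0.0, 0.5])
        np.testing.assert_array_equal(op.rotation_array(),
                                      [[-1, 0, 0], [0, -1, 0], [0, 0, 1]])

    def test_monoclinic_alias(self):
        assert len(space_group_ops("P 21")) == \
            len(space_group_ops("P 1 21 1")) == 2


class TestFracOrth:
    def test_cubic_cell_is_scaled_identity(self):
        orth, frac = frac_orth_matrices(CrystalCell(10, 10, 10))
        np.testing.assert_allclose(orth, 10 * np.eye(3), atol=1e-12)
        np.testing.assert_allclose(frac, np.eye(3) / 10, atol=1e-12)

    def test_orth_frac_inverse_for_random_cells(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            cell = CrystalCell(*rng.uniform(20, 80, 3),
                               *rng.uniform(60, 120, 3))
            orth, frac = frac_orth_matrices(cell)
            np.testing.assert_allclose(orth @ frac, np.eye(3), atol=1e-10)

    def test_monoclinic_matches_textbook_formula(self):
        a, b, c, beta = 12.0, 13.0, 14.0, 110.0
        orth, _ = frac_orth_matrices(CrystalCell(a, b, c, 90.0, beta, 90.0))
        cb = np.cos(np.radians(beta))
        expected = np.array([[a, 0.0, c * cb],
                             [0.0, b, 0.0],
                             [0.0, 0.0, c * np.sin(np.radians(beta))]])
        np.testing.assert_allclose(orth, expected, atol=1e-10)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            frac_orth_matrices(CrystalCell(10, 10, 10, 1.0, 179.0, 90.0))


class TestLatticeNeighbors:
    def test_p1_max_shift_one_gives_26(self):
        s = make_crystal_toy(make_polyala(4).chains[0], "P 1")
        assert len(lattice_neighbors(s, 1)) == 26

    def test_p212121_max_shift_zero_gives_3(self):
        s = make_crystal_toy(make_polyala(4).chains[0], "P 21 21 21")
        assert len(lattice_neighbors(s, 0)) == 3

    def test_count_formula(self):
        s = make_crystal_toy(make_polyala(4).chains[0], "P 21 21 21")
        assert len(lattice_neighbors(s, 2)) == 4 * 125 - 1

    def test_transform_matches_fractional_definition(self):
        s = make_crystal_toy(make_polyala(5).chains[0], "P 21 21 21")
        orth, frac = frac_orth_matrices(s.cell)
        ops = space_group_ops("P 21 21 21")
        x = np.array([a.coords for a in s.atoms])
        for nb in lattice_neighbors(s, 1)[:20]:
            op = ops[nb.operator_index]
            fx = x @ frac.T
            expected_frac = fx @ op.rotation_array().T + \
                op.translation_array() + np.array(nb.lattice_shift)
            got = nb.transform.apply(x) @ frac.T
            np.testing.assert_allclose(got, expected_frac, atol=1e-10)

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            lattice_neighbors(make_polyala(4), 1)

    def test_images_are_congruent(self):
        """All orthonormal-frame images superpose onto the original with
        essentially zero RMSD (volume conservation of rigid operators)."""
        s = make_crystal_toy(make_polyala(5).chains[0], "P 21 21 21")
        au = s.chains[0]
        fixed = np.array([a.coords for a in au.atoms])
        for nb in lattice_neighbors(s, 0):
            img = _image_chain(au, nb.transform)
            moving = np.array([a.coords for a in img.atoms])
            _, r = superpose(fixed, moving)
            assert r < 1e-9


class TestCrystalContacts:
    def test_isolated_chain_has_no_interfaces(self):
        s = make_crystal_toy(make_polyala(8).chains[0], "P 1", gap=20.0)
        assert crystal_contacts(s, 5.0) == []

    def test_touching_configuration_single_interface(self):
        """Cell sized so only the +/-x translates touch; the two mirror
        images collapse to one unique interface, as brute force over all
        26 images confirms."""
        s = make_crystal_toy(make_polyala(8).chains[0], "P 1",
                             gap=(1.5, 20.0, 20.0))
        ifaces = crystal_contacts(s, 5.0)
        assert len(ifaces) == 1
        assert ifaces[0].neighbor.lattice_shift in [(1, 0, 0), (-1, 0, 0)]
        # brute-force oracle
        au = s.chains[0]
        touching = [nb.lattice_shift for nb in lattice_neighbors(s, 1)
                    if len(brute_force_contacts(
                        au.atoms, _image_chain(au, nb.transform).atoms, 5.0))]
        assert set(touching) == {(1, 0, 0), (-1, 0, 0)}

    def test_grid_matches_brute_force_on_all_images(self):
        s = make_crystal_toy(make_polyala(6).chains[0], "P 21 21 21",
                             gap=(2.0, 2.5, 3.0))
        ifaces = crystal_contacts(s, 5.0)
        au = s.chains[0]
        brute_pairs = set()
        for nb in lattice_neighbors(s, 1):
            img = _image_chain(au, nb.transform)
            if len(brute_force_contacts(au.atoms, img.atoms, 5.0)):
                brute_pairs.add((nb.operator_index, nb.lattice_shift))
        grid_pairs = {(f.neighbor.operator_index, f.neighbor.lattice_shift)
                      for f in ifaces if f.neighbor is not None}
        # every reported interface is genuinely touching
        assert grid_pairs <= brute_pairs
        # and every touching image class is represented after dedup
        assert len(ifaces) > 0 or not brute_pairs

    def test_homodimer_intra_au_interface_reported(self):
        from macromol.fixtures import make_assembly
        dimer = make_assembly(make_polyala(8).chains[0], "C2", radius=8.0)
        s = make_crystal_toy(dimer.chains[0], "P 1", gap=40.0)
        # rebuild with both chains centered in a big cell
        s.models = [dimer.chains]
        intra = [f for f in crystal_contacts(s, 12.0) if f.neighbor is None]
        assert len(intra) == 1
        assert {intra[0].chain_a.auth_id, intra[0].chain_b.auth_id} == \
               {"A", "B"}

    def test_ordering_by_contact_count(self):
        s = make_crystal_toy(make_polyala(6).chains[0], "P 21 21 21",
                             gap=(2.0, 2.5, 3.0))
        ifaces = crystal_contacts(s, 5.0)
        counts = [len(f.contacts) for f in ifaces]
        assert counts == sorted(counts, reverse=True)
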