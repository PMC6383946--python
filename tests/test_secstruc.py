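import numpy as np
import pytest

from conftest import dssp_reference_labels
from macromol.fixtures import (add_noise, make_polyala, make_strand_pair)
from macromol.geometry import RigidTransform, apply_transform
from macromol.model import Atom, Group
from macromol.secstruc import (CONSTANTS, assign_secstruc, hbond_energy,
                               place_amide_hydrogen)


def labels(structure) -> str:
    return "".join(st.label for st in assign_secstruc(structure))


def bend_fixture():
    phis = [-139.0] * 11
    psis = [135.0] * 11
    phis[5], psis[5] = -90.0, 0.0
    return make_polyala(11, phi=phis, psi=psis)


def turn_fixture():
    phis = [-139.0] * 11
    psis = [135.0] * 11
    for k in range(4, 7):
        phis[k], psis[k] = -57.0, -47.0
    return make_polyala(11, phi=phis, psi=psis)


class TestAmideHydrogen:
    def _residue_pair(self):
        prev = Group("ALA", 1)
        prev.add_atom(Atom(1, "C", "C", (0.0, 0.0, 0.0)))
        prev.add_atom(Atom(2, "O", "O", (0.0, 1.231, 0.0)))
        cur = Group("ALA", 2)
        cur.add_atom(Atom(3, "N", "N", (1.329, 0.0, 0.0)))
        return prev, cur

    def test_position_matches_hand_vector_arithmetic(self):
        prev, cur = self._residue_pair()
        h = place_amide_hydrogen(cur, prev)
        # C->O is +y, so H = N + 1.0 * (C - O)/|C - O| = N - (0, 1, 0)
        np.testing.assert_allclose(h, [1.329, -1.0, 0.0], atol=1e-12)

    def test_proline_has_no_hydrogen(self):
        prev, _ = self._residue_pair()
        pro = Group("PRO", 2)
        pro.add_atom(Atom(3, "N", "N", (1.329, 0.0, 0.0)))
        assert place_amide_hydrogen(pro, prev) is None

    def test_chain_start_has_no_hydrogen(self):
        _, cur = self._residue_pair()
        assert place_amide_hydrogen(cur, None) is None


class TestHbondEnergy:
    def test_symmetric_geometry_cancels_exactly(self):
        # r(ON) = r(OH) and r(CH) = r(CN) make the four terms cancel
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([2.0, 0.0, 0.0])
        o = np.array([1.0, 1.0, 0.0])   # equidistant from N and H
        c = np.array([1.0, -1.0, 0.0])  # equidistant from N and H
        assert hbond_energy(n, h, c, o) == pytest.approx(0.0, abs=1e-12)

    def test_prefactor_value(self):
        assert CONSTANTS["q1"] * CONSTANTS["q2"] * CONSTANTS["f"] == \
            pytest.approx(27.888)

    def test_ideal_linear_geometry_is_bonded(self):
        # collinear N-H...O=C with r(ON) = 2.9
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        o = np.array([2.9, 0.0, 0.0])
        c = np.array([4.131, 0.0, 0.0])
        e = hbond_energy(n, h, c, o)
        hand = 27.888 * (1 / 2.9 + 1 / 3.131 - 1 / 1.9 - 1 / 4.131)
        assert e == pytest.approx(hand, rel=1e-12)
        assert e < CONSTANTS["hbond_threshold"]

    def test_coincident_atoms_clamped(self):
        p = np.zeros(3)
        assert hbond_energy(p, p, p, p) == CONSTANTS["energy_min"]


class TestAssignment:
    def test_helix_interior_is_alpha(self, helix):
        lab = labels(helix)
        assert set(lab[2:-2]) == {"H"}
        assert lab[0] != "H" and lab[-1] != "H"

    def test_antiparallel_pair_has_strands(self, strand_pair):
        lab = labels(strand_pair)
        assert "EEE" in lab

    def test_isolated_strand_has_no_bridges(self):
        lab = labels(make_polyala(8, phi=-139.0, psi=135.0))
        assert "E" not in lab and "B" not in lab

    def test_separated_pair_loses_strands(self):
        lab = labels(make_strand_pair(6, separation=12.0))
        assert "E" not in lab and "B" not in lab

    def test_three_ten_helix_is_g(self):
        lab = labels(make_polyala(10, phi=-49.0, psi=-26.0))
        assert "GGG" in lab and "H" not in lab

    def test_pi_helix_is_i(self):
        lab = labels(make_polyala(12, phi=-57.0, psi=-70.0))
        assert "III" in lab and "H" not in lab

    def test_short_chain_all_coil(self):
        assert labels(make_polyala(2)) == "--"

    def test_eight_state_alphabet_is_exactly_reachable(self):
        """Across the engineered suite the assignment emits each of the
        8 possible states and nothing else."""
        seen = set()
        for s in (make_polyala(18),                        # H
                  make_polyala(10, phi=-49.0, psi=-26.0),  # G
                  make_polyala(12, phi=-57.0, psi=-70.0),  # I
                  make_strand_pair(6),                     # E
                  make_strand_pair(4),                     # B
                  turn_fixture(),                          # T
                  bend_fixture(),                          # S
                  make_polyala(8, phi=-139.0, psi=135.0)):  # -
            seen |= set(labels(s))
        assert seen == {"H", "G", "I", "E", "B", "T", "S", "-"}

    def test_rigid_motion_invariance(self, strand_pair):
        before = labels(strand_pair)
        ang = 1.1
        R = np.array([[1, 0, 0],
                      [0, np.cos(ang), -np.sin(ang)],
                      [0, np.sin(ang), np.cos(ang)]])
        t = RigidTransform(R, np.array([5.0, -8.0, 2.0]))
        for a in strand_pair.atoms:
            a.coords = apply_transform(t, a.coords)
        assert labels(strand_pair) == before

    def test_dihedrals_match_generator_inputs(self):
        states = assign_secstruc(make_polyala(8))
        for st in states:
            if st.phi is not None:
                assert st.phi == pytest.approx(-57.0, abs=0.5)
            if st.psi is not None:
                assert st.psi == pytest.approx(-47.0, abs=0.5)


class TestReferenceAgreement:
    @pytest.mark.parametrize("structure_factory", [
        lambda: make_polyala(18),
        lambda: make_strand_pair(6),
        lambda: make_polyala(10, phi=-49.0, psi=-26.0),
        lambda: make_polyala(12, phi=-57.0, psi=-70.0),
        lambda: make_strand_pair(4),
        turn_fixture,
        bend_fixture,
    ], ids=["helix", "sheet", "threeten", "pi", "bridge", "turn", "bend"])
    def test_at_least_95_percent_identity_with_reference(
            self, structure_factory):
        s = structure_factory()
        mine = labels(s)
        ref = dssp_reference_labels(s)
        assert len(mine) == len(ref)
        identity = np.mean([a == b for a, b in zip(mine, ref)])
        assert identity >= 0.95

    def test_chain_break_rule_splits_h_bonding(self):
        """A CA-CA gap above 4.5 A severs the H-bond network: the two
        halves are assigned independently and no helix spans the break."""
        s = make_polyala(18)
        chain = s.chains[0]
        shift = np.array([6.0, 0.0, 0.0])
        for g in chain.groups[9:]:
            for a in g.atoms:
                a.coords = a.coords + shift
        lab = labels(s)
        assert lab[8:10].count("H") == 0
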