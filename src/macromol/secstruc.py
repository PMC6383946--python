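"""DSSP-style 8-state secondary structure assignment, from scratch.

The assignment follows the classic hydrogen-bond driven procedure: amide
hydrogens are reconstructed on the backbone, H-bonds are scored with the
Kabsch-Sander electrostatic model, n-turns (n = 3, 4, 5) and beta bridges
are derived from the bond pattern, and the 8-letter alphabet
``H G I E B T S -`` is assigned with the priority H > B/E > G > I > T > S.

All numeric constants live in :data:`CONSTANTS`; they are the values of
the original algorithm, not tunables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Chain, Group, Structure

__all__ = ["SecStrucState", "HBond", "assign_secstruc",
           "place_amide_hydrogen", "hbond_energy", "CONSTANTS"]

#: Constants of the Kabsch-Sander algorithm (energies kcal/mol, lengths
#: Angstrom, angles degrees).
CONSTANTS = {
    "q1": 0.42,            # carbonyl partial charge
    "q2": 0.20,            # amide partial charge
    "f": 332.0,            # dimensional electrostatic factor
    "hbond_threshold": -0.5,   # bond exists iff E below this
    "energy_min": -9.9,        # clamp for near-contact geometries
    "bend_kappa": 70.0,        # bend (S) when kappa exceeds this
    "nh_bond_length": 1.0,     # reconstructed N-H distance
    "ca_break_distance": 4.5,  # chain break when CA-CA exceeds this
    "ca_screen": 9.0,          # donor/acceptor CA pre-screen
}

_PREFACTOR = CONSTANTS["q1"] * CONSTANTS["q2"] * CONSTANTS["f"]  # 27.888


@dataclass
class HBond:
    """A stored backbone hydrogen bond (energy below threshold)."""

    donor_residue: Group
    acceptor_residue: Group
    energy: float


@dataclass
class SecStrucState:
    """Per-residue assignment with backbone dihedrals."""

    residue: Group
    label: str = "-"
    phi: Optional[float] = None
    psi: Optional[float] = None
    kappa: Optional[float] = None


def place_amide_hydrogen(residue: Group,
                         previous_residue: Optional[Group]) -> Optional[np.ndarray]:
    """Reconstructed amide H: 1 Angstrom from N, anti-parallel to the
    preceding carbonyl C->O bond.  Prolines and chain-start residues have
    no amide hydrogen (returns None)."""
    if previous_residue is None or residue.res_name.upper() == "PRO":
        return None
    n = residue.get_atom("N")
    c = previous_residue.get_atom("C")
    o = previous_residue.get_atom("O")
    if n is None or c is None or o is None:
        return None
    d = c.coords - o.coords
    norm = np.linalg.norm(d)
    if norm == 0:
        return None
    return n.coords + CONSTANTS["nh_bond_length"] * d / norm


def hbond_energy(n: np.ndarray, h: np.ndarray,
                 c: np.ndarray, o: np.ndarray) -> float:
    """Kabsch-Sander electrostatic H-bond energy in kcal/mol.

    ``E = 0.42 * 0.20 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)``,
    clamped below at -9.9.  Coincident atoms clamp to the minimum.
    """
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-9:
        return CONSTANTS["energy_min"]
    e = _PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(max(e, CONSTANTS["energy_min"]))


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class _Residue:
    """Internal: a complete backbone residue in the global chain order."""

    group: Group
    chain: Chain
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: Optional[np.ndarray] = None
    segment: int = 0          # contiguous segment id (chain breaks split)
    index: int = 0            # position in the global list
    # acceptor side of stored bonds: list of (donor_index, energy)
    nh_bonds: list = field(default_factory=list)   # bonds donated by this N-H
    label: str = "-"
    phi: Optional[float] = None
    psi: Optional[float] = None
    kappa: Optional[float] = None


def _collect_residues(structure: Structure, model_index: int) -> list[_Residue]:
    residues: list[_Residue] = []
    segment = 0
    for chain in structure.models[model_index]:
        if not chain.is_polymeric:
            continue
        prev: Optional[_Residue] = None
        first_in_chain = True
        for g in chain.groups:
            if g.category != "amino_acid":
                continue
            atoms = {name: g.get_atom(name) for name in ("N", "CA", "C", "O")}
            if any(a is None for a in atoms.values()):
                # incomplete backbone: excluded from H-bonding, breaks chain
                prev = None
                first_in_chain = True
                continue
            if first_in_chain or prev is None:
                segment += 1
            elif np.linalg.norm(atoms["CA"].coords - prev.ca) > \
                    CONSTANTS["ca_break_distance"]:
                segment += 1
                prev = None
            r = _Residue(g, chain, atoms["N"].coords, atoms["CA"].coords,
                         atoms["C"].coords, atoms["O"].coords,
                         segment=segment)
            r.h = place_amide_hydrogen(g, prev.group if prev else None)
            residues.append(r)
            prev = r
            first_in_chain = False
    for i, r in enumerate(residues):
        r.index = i
    return residues


def _compute_dihedrals(residues: list[_Residue]) -> None:
    for i, r in enumerate(residues):
        prev = residues[i - 1] if i > 0 and \
            residues[i - 1].segment == r.segment else None
        nxt = residues[i + 1] if i + 1 < len(residues) and \
            residues[i + 1].segment == r.segment else None
        if prev is not None:
            r.phi = _dihedral(prev.c, r.n, r.ca, r.c)
        if nxt is not None:
            r.psi = _dihedral(r.n, r.ca, r.c, nxt.n)
        if (i >= 2 and i + 2 < len(residues)
                and residues[i - 2].segment == r.segment
                and residues[i + 2].segment == r.segment):
            v1 = r.ca - residues[i - 2].ca
            v2 = residues[i + 2].ca - r.ca
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            r.kappa = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def _hbond_map(residues: list[_Residue]) -> tuple[set[tuple[int, int]],
                                                  list[HBond]]:
    """All stored bonds as (donor_index, acceptor_index) pairs."""
    bonds: set[tuple[int, int]] = set()
    records: list[HBond] = []
    cas = np.array([r.ca for r in residues]).reshape(-1, 3)
    screen = CONSTANTS["ca_screen"]
    for i, donor in enumerate(residues):
        if donor.h is None:
            continue
        d2 = np.sum((cas - donor.ca) ** 2, axis=1)
        for j in np.nonzero(d2 <= screen * screen)[0]:
            acceptor = residues[int(j)]
            if acceptor is donor:
                continue
            # the donated H is built from the acceptor's own carbonyl when
            # j == i-1; such a bond is geometrically meaningless
            if acceptor.index == donor.index - 1 and \
                    acceptor.segment == donor.segment:
                continue
            e = hbond_energy(donor.n, donor.h, acceptor.c, acceptor.o)
            if e < CONSTANTS["hbond_threshold"]:
                bonds.add((donor.index, acceptor.index))
                records.append(HBond(donor.group, acceptor.group, e))
    return bonds, records


def _contiguous(residues: list[_Residue], i: int, j: int) -> bool:
    """True when residues i..j exist and share one unbroken segment."""
    if i < 0 or j >= len(residues):
        return False
    return residues[i].segment == residues[j].segment


def assign_secstruc(structure: Structure,
                    model_index: int = 0) -> list[SecStrucState]:
    """Assign 8-state secondary structure to all protein residues.

    Returns one :class:`SecStrucState` per complete backbone residue of the
    polymeric protein chains, in chain order.  Chains with fewer than three
    complete residues come back all ``-``.
    """
    residues = _collect_residues(structure, model_index)
    n = len(residues)
    if n == 0:
        return []
    _compute_dihedrals(residues)
    bonds, _records = _hbond_map(residues)

    def hb(acceptor: int, donor: int) -> bool:
        """Kabsch-Sander Hbond(i, j): CO of i accepts from NH of j."""
        return (donor, acceptor) in bonds

    # n-turns: turn_n[i] iff CO(i) accepts from NH(i+n) within one segment
    turns: dict[int, np.ndarray] = {}
    for k in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - k):
            if _contiguous(residues, i, i + k) and hb(i, i + k):
                t[i] = True
        turns[k] = t

    # minimal helices: two consecutive n-turns
    helix = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(1, n - k):
            if turns[k][i - 1] and turns[k][i]:
                helix[k][i:i + k] = True

    # beta bridges
    par_pairs: list[tuple[int, int]] = []
    anti_pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 3, n):
            par = ((hb(i - 1, j) and hb(j, i + 1)
                    and _contiguous(residues, i - 1, i + 1))
                   or (hb(j - 1, i) and hb(i, j + 1)
                       and _contiguous(residues, j - 1, j + 1)))
            anti = ((hb(i, j) and hb(j, i))
                    or (hb(i - 1, j + 1) and hb(j - 1, i + 1)
                        and _contiguous(residues, i - 1, i + 1)
                        and _contiguous(residues, j - 1, j + 1)))
            if par:
                par_pairs.append((i, j))
            if anti:
                anti_pairs.append((i, j))

    # ladders: consecutive bridges of the same type
    in_ladder = np.zeros(n, dtype=bool)
    in_bridge = np.zeros(n, dtype=bool)
    par_set = set(par_pairs)
    anti_set = set(anti_pairs)
    for (i, j) in par_pairs:
        in_bridge[i] = in_bridge[j] = True
        if (i + 1, j + 1) in par_set or (i - 1, j - 1) in par_set:
            in_ladder[i] = in_ladder[j] = True
    for (i, j) in anti_pairs:
        in_bridge[i] = in_bridge[j] = True
        if (i + 1, j - 1) in anti_set or (i - 1, j + 1) in anti_set:
            in_ladder[i] = in_ladder[j] = True

    # turn (T) candidates: interior of any n-turn
    turn_t = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in np.nonzero(turns[k])[0]:
            turn_t[i + 1:i + k] = True

    labels = ["-"] * n
    for i in range(n):
        if helix[4][i]:
            labels[i] = "H"
        elif in_ladder[i]:
            labels[i] = "E"
        elif in_bridge[i]:
            labels[i] = "B"
        elif helix[3][i]:
            labels[i] = "G"
        elif helix[5][i]:
            labels[i] = "I"
        elif turn_t[i]:
            labels[i] = "T"
        elif residues[i].kappa is not None and \
                residues[i].kappa > CONSTANTS["bend_kappa"]:
            labels[i] = "S"

    return [SecStrucState(r.group, labels[i], r.phi, r.psi, r.kappa)
            for i, r in enumerate(residues)]


def backbone_hbonds(structure: Structure, model_index: int = 0) -> list[HBond]:
    """All stored backbone hydrogen bonds (energy < -0.5 kcal/mol)."""
    residues = _collect_residues(structure, model_index)
    _, records = _hbond_map(residues)
    return records
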