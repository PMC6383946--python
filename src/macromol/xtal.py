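"""Space-group operators, lattice reconstruction and crystal contacts.

Operators of the 65 Sohncke (chiral-compatible) space groups are shipped
as Jones-faithful triplets in the standard setting and parsed exactly with
rational arithmetic.  Applying an operator to Cartesian coordinates goes
through the fractional basis: ``y = O (R_frac F x + t + shift)`` with ``O``
and ``F`` the (de)orthogonalization matrices of the unit cell.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .contacts import ContactSet, atom_contacts, residue_contacts
from .geometry import RigidTransform
from .model import Chain, CrystalCell, Structure

__all__ = ["SpaceGroupOp", "space_group_ops", "frac_orth_matrices",
           "lattice_neighbors", "crystal_contacts", "CrystalNeighbor",
           "UnknownSpaceGroupError", "sohncke_group_names"]


class UnknownSpaceGroupError(ValueError):
    """Space group not among the shipped Sohncke groups."""

    def __init__(self, name: str):
        super().__init__(
            f"space group {name!r} is not one of the 65 Sohncke groups "
            f"(non-chiral groups cannot host protein crystals)")
        self.name = name


@dataclass(frozen=True)
class SpaceGroupOp:
    """One symmetry operator in the fractional basis."""

    rotation: tuple          # 3x3 of Fraction
    translation: tuple       # 3 of Fraction, each in [0, 1)

    @classmethod
    def from_triplet(cls, triplet: str) -> "SpaceGroupOp":
        rows = triplet.split(",")
        if len(rows) != 3:
            raise ValueError(f"bad operator triplet {triplet!r}")
        rot = []
        trans = []
        for row in rows:
            coeff = {"x": Fraction(0), "y": Fraction(0), "z": Fraction(0)}
            shift = Fraction(0)
            for sign, term in re.findall(r"([+-]?)\s*([xyz]|\d+/\d+|\d+)",
                                         row.replace(" ", "")):
                s = -1 if sign == "-" else 1
                if term in coeff:
                    coeff[term] += s
                elif "/" in term:
                    num, den = term.split("/")
                    shift += s * Fraction(int(num), int(den))
                else:
                    shift += s * Fraction(int(term))
            rot.append((coeff["x"], coeff["y"], coeff["z"]))
            trans.append(shift % 1)
        return cls(tuple(rot), tuple(trans))

    def triplet(self) -> str:
        names = ("x", "y", "z")
        parts = []
        for row, t in zip(self.rotation, self.translation):
            s = ""
            for c, nm in zip(row, names):
                if c == 0:
                    continue
                sign = "-" if c < 0 else ("+" if s else "")
                mag = abs(c)
                s += f"{sign}{'' if mag == 1 else mag}{nm}"
            if t != 0:
                s += f"+{t}"
            parts.append(s)
        return ",".join(parts)

    def compose(self, other: "SpaceGroupOp") -> "SpaceGroupOp":
        """self o other, translations reduced mod the lattice."""
        rot = []
        trans = []
        for i in range(3):
            rot.append(tuple(
                sum(self.rotation[i][k] * other.rotation[k][j]
                    for k in range(3)) for j in range(3)))
            tval = sum(self.rotation[i][k] * other.translation[k]
                       for k in range(3)) + self.translation[i]
            trans.append(tval % 1)
        return SpaceGroupOp(tuple(rot), tuple(trans))

    @property
    def is_identity(self) -> bool:
        ident = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
        return (all(self.rotation[i][j] == ident[i][j]
                    for i in range(3) for j in range(3))
                and all(t == 0 for t in self.translation))

    def rotation_array(self) -> np.ndarray:
        return np.array([[float(c) for c in row] for row in self.rotation])

    def translation_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.translation])


def _load_table() -> dict:
    with resources.files("macromol.data").joinpath(
            "spacegroups_sohncke.json").open() as fh:
        return json.load(fh)


_TABLE: Optional[dict] = None
_ALIASES: Optional[dict] = None


def _table() -> dict:
    global _TABLE, _ALIASES
    if _TABLE is None:
        _TABLE = _load_table()
        _ALIASES = {}
        for name in _TABLE:
            _ALIASES[name.upper()] = name
            # short monoclinic symbols: "P 1 2 1" -> "P 2"
            parts = name.split()
            if len(parts) == 4 and parts[1] == "1" and parts[3] == "1":
                _ALIASES.setdefault(f"{parts[0]} {parts[2]}".upper(), name)
            _ALIASES.setdefault(name.replace(" ", "").upper(), name)
    return _TABLE


def sohncke_group_names() -> list[str]:
    """Hermann-Mauguin names of all 65 shipped Sohncke space groups."""
    return sorted(_table(), key=lambda n: _table()[n]["number"])


def space_group_ops(name: str) -> list[SpaceGroupOp]:
    """Operators of a Sohncke space group in the standard setting.

    The first operator is always the identity.  Unknown or non-Sohncke
    Hermann-Mauguin symbols raise :class:`UnknownSpaceGroupError`.
    """
    table = _table()
    key = _ALIASES.get(name.strip().upper())
    if key is None:
        raise UnknownSpaceGroupError(name)
    ops = [SpaceGroupOp.from_triplet(t) for t in table[key]["ops"]]
    ops.sort(key=lambda op: not op.is_identity)
    return ops


def frac_orth_matrices(cell: CrystalCell) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonalization and fractionalization matrices (a along x).

    ``orth @ frac == I``; raises for degenerate (near-zero volume) cells.
    """
    a, b, c = cell.a, cell.b, cell.c
    al, be, ga = np.radians([cell.alpha, cell.beta, cell.gamma])
    ca_, cb, cg = np.cos([al, be, ga])
    sg = np.sin(ga)
    v2 = 1.0 - ca_ ** 2 - cb ** 2 - cg ** 2 + 2.0 * ca_ * cb * cg
    if v2 <= 1e-12:
        raise ValueError("degenerate cell: volume is zero")
    v = np.sqrt(v2)
    orth = np.array([
        [a, b * cg, c * cb],
        [0.0, b * sg, c * (ca_ - cb * cg) / sg],
        [0.0, 0.0, c * v / sg],
    ])
    return orth, np.linalg.inv(orth)


@dataclass
class CrystalNeighbor:
    """One symmetry image of the asymmetric unit in the lattice."""

    operator_index: int
    lattice_shift: tuple[int, int, int]
    transform: RigidTransform  # in the orthonormal (Cartesian) frame

    def __repr__(self) -> str:
        return (f"<CrystalNeighbor op={self.operator_index} "
                f"shift={self.lattice_shift}>")


def _cartesian_transform(op: SpaceGroupOp, shift: Sequence[int],
                         orth: np.ndarray, frac: np.ndarray) -> RigidTransform:
    r_frac = op.rotation_array()
    t_frac = op.translation_array() + np.asarray(shift, dtype=float)
    return RigidTransform(orth @ r_frac @ frac, orth @ t_frac)


def lattice_neighbors(structure: Structure,
                      max_shift: int = 1) -> list[CrystalNeighbor]:
    """All symmetry images within ``max_shift`` unit cells.

    Enumerates every (operator, lattice shift) combination except the
    identity operator with zero shift; the count is
    ``n_ops * (2*max_shift + 1)**3 - 1``.
    """
    if structure.cell is None or not structure.space_group_name:
        raise ValueError("structure lacks cell or space group information")
    ops = space_group_ops(structure.space_group_name)
    orth, frac = frac_orth_matrices(structure.cell)
    out: list[CrystalNeighbor] = []
    rng = range(-max_shift, max_shift + 1)
    for k, op in enumerate(ops):
        for sx in rng:
            for sy in rng:
                for sz in rng:
                    if k == 0 and sx == sy == sz == 0 and op.is_identity:
                        continue
                    out.append(CrystalNeighbor(
                        k, (sx, sy, sz),
                        _cartesian_transform(op, (sx, sy, sz), orth, frac)))
    return out


@dataclass
class CrystalInterface:
    """A unique chain-chain interface in the crystal."""

    chain_a: Chain
    chain_b: Chain
    neighbor: Optional[CrystalNeighbor]  # None for intra-AU pairs
    contacts: ContactSet

    @property
    def n_residue_contacts(self) -> int:
        return len(residue_contacts(self.contacts))


def _interface_fingerprint(iface: CrystalInterface) -> tuple:
    recs = []
    for rc in residue_contacts(iface.contacts):
        ka = (rc.group_a.chain.auth_id if rc.group_a.chain else "",
              rc.group_a.seq_id_auth, rc.group_a.res_name)
        kb = (rc.group_b.chain.auth_id if rc.group_b.chain else "",
              rc.group_b.seq_id_auth, rc.group_b.res_name)
        pair = tuple(sorted((ka, kb)))
        recs.append((pair, round(rc.min_distance, 3), rc.n_atom_pairs))
    return tuple(sorted(recs))


def _image_chain(chain: Chain, transform: RigidTransform) -> Chain:
    from .model import Atom, Group
    new = Chain(chain.auth_id, chain.asym_id, chain.entity_id,
                chain.chain_type)
    for g in chain.groups:
        ng = Group(g.res_name, g.seq_id_auth, g.ins_code, g.seq_id_label,
                   g.category)
        for a in g.atoms:
            ng.add_atom(Atom(a.serial, a.name, a.element,
                             transform.apply(a.coords), a.alt_loc,
                             a.occupancy, a.b_factor, a.is_hetero))
        new.add_group(ng)
    return new


def crystal_contacts(structure: Structure, cutoff: float = 5.0,
                     max_shift: int = 1,
                     include_waters: bool = False) -> list[CrystalInterface]:
    """Unique chain-chain interfaces in the crystal at the given cutoff.

    Pairs every AU chain against the other AU chains (intra-AU interfaces)
    and against every lattice image of every chain.  Symmetry-equivalent
    interfaces are reduced to one representative via residue-contact
    fingerprints; the result is ordered by atom-contact count descending.
    """
    if structure.cell is None or not structure.space_group_name:
        raise ValueError("structure lacks cell or space group information")
    chains = [c for c in structure.chains if c.groups]
    if not include_waters:
        chains = [c for c in chains
                  if not all(g.category == "water" for g in c.groups)]
    if not any(c.is_polymeric for c in chains):
        raise ValueError("no polymeric chains present")

    def chain_atoms(chain: Chain):
        return [a for g in chain.groups for a in g.atoms
                if include_waters or g.category != "water"]

    interfaces: list[CrystalInterface] = []
    seen: set[tuple] = set()
    # intra-AU
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            cs = atom_contacts(chain_atoms(chains[i]),
                               chain_atoms(chains[j]), cutoff)
            if len(cs):
                iface = CrystalInterface(chains[i], chains[j], None, cs)
                fp = _interface_fingerprint(iface)
                if fp not in seen:
                    seen.add(fp)
                    interfaces.append(iface)
    # AU vs lattice images
    for nb in lattice_neighbors(structure, max_shift):
        for cb in chains:
            image = _image_chain(cb, nb.transform)
            for ca in chains:
                cs = atom_contacts(chain_atoms(ca), chain_atoms(image),
                                   cutoff)
                if len(cs):
                    iface = CrystalInterface(ca, image, nb, cs)
                    fp = _interface_fingerprint(iface)
                    if fp not in seen:
                        seen.add(fp)
                        interfaces.append(iface)
    interfaces.sort(key=lambda f: -len(f.contacts))
    return interfaces
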