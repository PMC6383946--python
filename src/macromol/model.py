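"""Hierarchical macromolecular data model.

The hierarchy follows the PDBx/mmCIF dictionary: a :class:`Structure` holds
one or more models, each model is a list of :class:`Chain` objects, chains
hold :class:`Group` residues/molecules, and groups hold :class:`Atom` records.

Chains come in exactly two types, ``polymeric`` and ``non_polymeric``:
polypeptides and nucleic acids are polymeric; ligands, cofactors, ions and
waters live in non-polymeric chains.  Waters keep their mmCIF entity type
(``water``) on the :class:`Entity` and carry ``category="water"`` on the
group, but at the chain level they are simply non-polymeric.

Residues are addressed primarily by author numbering (``seq_id_auth`` plus
insertion code), with mmCIF label numbering kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Atom",
    "Group",
    "Chain",
    "Entity",
    "CrystalCell",
    "Structure",
    "partition_chains",
    "polymer_residues",
    "AMINO_ACIDS_3",
    "NUCLEOTIDES",
    "WATER_NAMES",
    "three_to_one",
]

#: Standard amino-acid 3-letter codes (20 canonical plus MSE selenomethionine).
AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}

#: Nucleotide component codes (DNA and RNA).
NUCLEOTIDES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}

WATER_NAMES = {"HOH", "DOD"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


def three_to_one(res_name: str) -> str:
    """One-letter code for a residue name; 'X' for unknown components."""
    return _THREE_TO_ONE.get(res_name.upper(), "X")


def group_category(res_name: str, is_hetero: bool = False) -> str:
    """Classify a component code into amino_acid/nucleotide/water/hetero."""
    name = res_name.upper()
    if name in WATER_NAMES:
        return "water"
    if name in AMINO_ACIDS_3:
        return "amino_acid"
    if name in NUCLEOTIDES:
        return "nucleotide"
    return "hetero"


class Atom:
    """A single atom record with Cartesian coordinates in Angstrom."""

    __slots__ = ("serial", "name", "element", "alt_loc", "coords",
                 "occupancy", "b_factor", "is_hetero", "group")

    def __init__(self, serial: int, name: str, element: str,
                 coords, alt_loc: str = "", occupancy: float = 1.0,
                 b_factor: float = 0.0, is_hetero: bool = False):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {name!r}: coords must be a finite 3-vector")
        if serial <= 0:
            raise ValueError(f"atom {name!r}: serial must be positive")
        self.serial = int(serial)
        self.name = name
        self.element = element.upper()
        self.alt_loc = alt_loc
        self.coords = coords
        self.occupancy = float(occupancy)
        self.b_factor = float(b_factor)
        self.is_hetero = bool(is_hetero)
        self.group: Optional[Group] = None  # back-reference, set by Group

    def __repr__(self) -> str:
        return f"<Atom {self.serial} {self.name} [{self.element}]>"


class Group:
    """A residue or small molecule: an ordered set of atoms with identity.

    ``category`` is one of ``amino_acid``, ``nucleotide``, ``hetero``,
    ``water``.  Author numbering (``seq_id_auth`` + ``ins_code``) is the
    primary key within a chain; ``seq_id_label`` keeps the mmCIF label
    sequence id when known.
    """

    __slots__ = ("res_name", "seq_id_auth", "ins_code", "seq_id_label",
                 "atoms", "category", "chain")

    def __init__(self, res_name: str, seq_id_auth: int, ins_code: str = "",
                 seq_id_label: Optional[int] = None,
                 category: Optional[str] = None):
        self.res_name = res_name
        self.seq_id_auth = int(seq_id_auth)
        self.ins_code = ins_code
        self.seq_id_label = seq_id_label
        self.category = category or group_category(res_name)
        self.atoms: list[Atom] = []
        self.chain: Optional[Chain] = None  # back-reference, set by Chain

    @property
    def group_id(self) -> tuple[int, str, str]:
        return (self.seq_id_auth, self.ins_code, self.res_name)

    def add_atom(self, atom: Atom, keep_alt_locs: bool = True) -> bool:
        """Append an atom; returns False when dropped by the alt-loc policy."""
        if not keep_alt_locs and atom.alt_loc:
            # keep only the first-listed alternate location per atom name
            for existing in self.atoms:
                if existing.name == atom.name:
                    return False
        atom.group = self
        self.atoms.append(atom)
        return True

    def get_atom(self, name: str) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (f"<Group {self.res_name} {self.seq_id_auth}{self.ins_code} "
                f"({self.category}, {len(self.atoms)} atoms)>")


class Chain:
    """An instance of a molecular entity: ordered groups under one chain id."""

    __slots__ = ("auth_id", "asym_id", "entity_id", "chain_type", "groups")

    POLYMERIC = "polymeric"
    NON_POLYMERIC = "non_polymeric"

    def __init__(self, auth_id: str, asym_id: Optional[str] = None,
                 entity_id: Optional[int] = None,
                 chain_type: str = POLYMERIC):
        if chain_type not in (self.POLYMERIC, self.NON_POLYMERIC):
            raise ValueError(f"unknown chain_type {chain_type!r}")
        self.auth_id = auth_id
        self.asym_id = asym_id if asym_id is not None else auth_id
        self.entity_id = entity_id
        self.chain_type = chain_type
        self.groups: list[Group] = []

    @property
    def is_polymeric(self) -> bool:
        return self.chain_type == self.POLYMERIC

    def add_group(self, group: Group) -> None:
        if self.is_polymeric and group.category == "water":
            raise ValueError(
                f"water group {group.group_id} cannot join polymeric "
                f"chain {self.auth_id!r}")
        group.chain = self
        self.groups.append(group)

    def get_group(self, seq_id_auth: int, ins_code: str = "") -> Optional[Group]:
        for g in self.groups:
            if g.seq_id_auth == seq_id_auth and g.ins_code == ins_code:
                return g
        return None

    @property
    def atoms(self) -> list[Atom]:
        return [a for g in self.groups for a in g.atoms]

    @property
    def sequence(self) -> str:
        """One-letter sequence over polymer residues (empty for non-polymer)."""
        if not self.is_polymeric:
            return ""
        return "".join(
            three_to_one(g.res_name) if g.category == "amino_acid"
            else g.res_name[-1].lower()
            for g in self.groups if g.category in ("amino_acid", "nucleotide"))

    def __iter__(self) -> Iterator[Group]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __repr__(self) -> str:
        return (f"<Chain {self.auth_id} ({self.chain_type}, "
                f"{len(self.groups)} groups)>")


@dataclass
class Entity:
    """A unique molecular species; chains are instances of entities."""

    entity_id: int
    entity_type: str = "polymer"  # polymer | non-polymer | water
    description: str = ""
    one_letter_sequence: str = ""
    polymer_type: str = "none"  # protein | dna | rna | other | none

    def __post_init__(self):
        if self.entity_type not in ("polymer", "non-polymer", "water"):
            raise ValueError(f"unknown entity_type {self.entity_type!r}")


@dataclass
class CrystalCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must be in (0, 180) degrees")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass
class Structure:
    """Root container: models of chains plus crystal and entity metadata."""

    struct_id: str = ""
    models: list[list[Chain]] = field(default_factory=lambda: [[]])
    entities: list[Entity] = field(default_factory=list)
    cell: Optional[CrystalCell] = None
    space_group_name: Optional[str] = None
    resolution: Optional[float] = None
    title: str = ""

    def model(self, index: int = 0) -> list[Chain]:
        return self.models[index]

    @property
    def chains(self) -> list[Chain]:
        """Chains of the first model."""
        return self.models[0]

    def polymer_chains(self, model_index: int = 0) -> list[Chain]:
        return [c for c in self.models[model_index] if c.is_polymeric]

    def get_chain(self, auth_id: str, model_index: int = 0) -> Optional[Chain]:
        for c in self.models[model_index]:
            if c.auth_id == auth_id:
                return c
        return None

    def get_entity(self, entity_id: int) -> Optional[Entity]:
        for e in self.entities:
            if e.entity_id == entity_id:
                return e
        return None

    @property
    def atoms(self) -> list[Atom]:
        return [a for c in self.models[0] for a in c.atoms]

    def validate(self) -> None:
        """Raise ValueError on any violated model invariant."""
        if not self.models:
            raise ValueError("structure must contain at least one model")
        ids0 = sorted(c.auth_id for c in self.models[0])
        for i, m in enumerate(self.models[1:], start=2):
            if sorted(c.auth_id for c in m) != ids0:
                raise ValueError(f"model {i} has different chain identifiers")
        for m in self.models:
            serials = [a.serial for c in m for a in c.atoms]
            if len(serials) != len(set(serials)):
                raise ValueError("duplicate atom serials within one model")
            for c in m:
                gids = [g.group_id for g in c.groups]
                if len(gids) != len(set(gids)):
                    raise ValueError(
                        f"duplicate group ids in chain {c.auth_id!r}")
                if c.is_polymeric and any(
                        g.category == "water" for g in c.groups):
                    raise ValueError(
                        f"water group in polymeric chain {c.auth_id!r}")
        # chains sharing an entity must share the sequence
        by_entity: dict[int, set[str]] = {}
        for c in self.models[0]:
            if c.entity_id is not None and c.is_polymeric:
                by_entity.setdefault(c.entity_id, set()).add(c.sequence)
        for eid, seqs in by_entity.items():
            if len(seqs) > 1:
                raise ValueError(
                    f"chains of entity {eid} have different sequences")

    def __repr__(self) -> str:
        return (f"<Structure {self.struct_id!r}: {len(self.models)} model(s), "
                f"{len(self.models[0])} chain(s)>")


def partition_chains(structure: Structure,
                     model_index: int = 0) -> dict[str, list[Chain]]:
    """Split the chains of one model into the two chain types.

    Returns a mapping with keys ``"polymeric"`` and ``"non_polymeric"``;
    every chain lands in exactly one bucket according to its ``chain_type``.
    """
    out: dict[str, list[Chain]] = {Chain.POLYMERIC: [], Chain.NON_POLYMERIC: []}
    for chain in structure.models[model_index]:
        out[chain.chain_type].append(chain)
    return out


def polymer_residues(chain: Chain) -> list[Group]:
    """Polymer residues (amino acids / nucleotides) of a polymeric chain,
    in author order; covalently attached hetero groups are excluded.
    """
    if not chain.is_polymeric:
        raise ValueError(
            f"polymer_residues requires a polymeric chain, got "
            f"{chain.chain_type!r} chain {chain.auth_id!r}")
    return [g for g in chain.groups if g.category in ("amino_acid", "nucleotide")]
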