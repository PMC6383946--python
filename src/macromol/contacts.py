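"""Atom- and residue-level contact networks via spatial hashing.

Atoms are bucketed into a uniform grid whose cell edge equals the distance
cutoff, so all neighbors of an atom lie in the 27 cells around its own.
This gives linear-time contact enumeration while returning exactly the same
pairs as the quadratic all-against-all definition (closed ball: a pair at
distance exactly equal to the cutoff counts).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterator, Optional, Sequence

import numpy as np

from .model import Atom, Group

__all__ = ["AtomContact", "ContactSet", "atom_contacts", "residue_contacts",
           "GroupContact"]


class AtomContact:
    """An unordered atom pair within the cutoff, with its distance."""

    __slots__ = ("atom_a", "atom_b", "distance")

    def __init__(self, atom_a: Atom, atom_b: Atom, distance: float):
        self.atom_a = atom_a
        self.atom_b = atom_b
        self.distance = float(distance)

    def __repr__(self) -> str:
        return f"<AtomContact {self.atom_a.name}-{self.atom_b.name} {self.distance:.2f} A>"


class ContactSet:
    """All atom contacts found at one cutoff."""

    def __init__(self, cutoff: float, contacts: Sequence[AtomContact] = ()):
        self.cutoff = float(cutoff)
        self.contacts = list(contacts)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self) -> Iterator[AtomContact]:
        return iter(self.contacts)

    def pair_keys(self) -> set[frozenset[int]]:
        """Unordered pairs keyed by atom object identity (for set algebra)."""
        return {frozenset((id(c.atom_a), id(c.atom_b))) for c in self.contacts}

    def __repr__(self) -> str:
        return f"<ContactSet cutoff={self.cutoff} A, {len(self.contacts)} contacts>"


class GroupContact:
    """Residue-pair summary of atom contacts."""

    __slots__ = ("group_a", "group_b", "min_distance", "n_atom_pairs")

    def __init__(self, group_a: Group, group_b: Group,
                 min_distance: float, n_atom_pairs: int):
        self.group_a = group_a
        self.group_b = group_b
        self.min_distance = float(min_distance)
        self.n_atom_pairs = int(n_atom_pairs)

    def __repr__(self) -> str:
        return (f"<GroupContact {self.group_a.res_name}{self.group_a.seq_id_auth}-"
                f"{self.group_b.res_name}{self.group_b.seq_id_auth} "
                f"min {self.min_distance:.2f} A, {self.n_atom_pairs} pairs>")


def _grid_index(coords: np.ndarray, origin: np.ndarray, edge: float) -> np.ndarray:
    return np.floor((coords - origin) / edge).astype(np.int64)


def _build_grid(coords: np.ndarray, origin: np.ndarray,
                edge: float) -> dict[tuple[int, int, int], list[int]]:
    cells: dict[tuple[int, int, int], list[int]] = defaultdict(list)
    for i, idx in enumerate(_grid_index(coords, origin, edge)):
        cells[tuple(idx)].append(i)
    return cells


_NEIGHBOR_OFFSETS = [(dx, dy, dz)
                     for dx in (-1, 0, 1)
                     for dy in (-1, 0, 1)
                     for dz in (-1, 0, 1)]


def atom_contacts(atoms_a: Sequence[Atom],
                  atoms_b: Optional[Sequence[Atom]] = None,
                  cutoff: float = 5.0) -> ContactSet:
    """Contacts within one atom set, or across two disjoint sets.

    With ``atoms_b=None``, all unordered intra-set pairs (i < j) at
    Euclidean distance <= cutoff are returned; otherwise only cross pairs
    between the two sets.  Neighbor search uses a uniform grid with cell
    edge equal to the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms_a = list(atoms_a)
    ca = np.array([a.coords for a in atoms_a], dtype=float).reshape(-1, 3)
    result: list[AtomContact] = []

    if atoms_b is None:
        if len(atoms_a) < 2:
            return ContactSet(cutoff)
        origin = ca.min(axis=0)
        cells = _build_grid(ca, origin, cutoff)
        cut2 = cutoff * cutoff
        for cell, members in cells.items():
            for off in _NEIGHBOR_OFFSETS:
                other = (cell[0] + off[0], cell[1] + off[1], cell[2] + off[2])
                if other < cell:  # each cell pair visited once
                    continue
                others = cells.get(other)
                if others is None:
                    continue
                if other == cell:
                    for ii in range(len(members)):
                        i = members[ii]
                        for jj in range(ii + 1, len(members)):
                            j = members[jj]
                            d2 = float(np.sum((ca[i] - ca[j]) ** 2))
                            if d2 <= cut2:
                                a, b = ((atoms_a[i], atoms_a[j])
                                        if i < j else (atoms_a[j], atoms_a[i]))
                                result.append(AtomContact(a, b, np.sqrt(d2)))
                else:
                    for i in members:
                        for j in others:
                            d2 = float(np.sum((ca[i] - ca[j]) ** 2))
                            if d2 <= cut2:
                                a, b = ((atoms_a[i], atoms_a[j])
                                        if i < j else (atoms_a[j], atoms_a[i]))
                                result.append(AtomContact(a, b, np.sqrt(d2)))
        return ContactSet(cutoff, result)

    atoms_b = list(atoms_b)
    if not atoms_a or not atoms_b:
        return ContactSet(cutoff)
    cb = np.array([b.coords for b in atoms_b], dtype=float).reshape(-1, 3)
    origin = np.minimum(ca.min(axis=0), cb.min(axis=0))
    cells_b = _build_grid(cb, origin, cutoff)
    cut2 = cutoff * cutoff
    for i, idx in enumerate(_grid_index(ca, origin, cutoff)):
        base = tuple(idx)
        for off in _NEIGHBOR_OFFSETS:
            members = cells_b.get((base[0] + off[0], base[1] + off[1],
                                   base[2] + off[2]))
            if members is None:
                continue
            for j in members:
                d2 = float(np.sum((ca[i] - cb[j]) ** 2))
                if d2 <= cut2:
                    result.append(AtomContact(atoms_a[i], atoms_b[j],
                                              np.sqrt(d2)))
    return ContactSet(cutoff, result)


def residue_contacts(cs: ContactSet) -> list[GroupContact]:
    """Aggregate atom contacts to unordered residue (group) pairs.

    One record per group pair with at least one atom contact; contacts
    within a single group are dropped.  Records are ordered by first
    appearance of the pair in the contact list.
    """
    summary: dict[tuple[int, int], GroupContact] = {}
    for c in cs:
        ga, gb = c.atom_a.group, c.atom_b.group
        if ga is None or gb is None:
            raise ValueError("atoms in the contact set lack group back-references")
        if ga is gb:
            continue
        key = (id(ga), id(gb)) if id(ga) < id(gb) else (id(gb), id(ga))
        rec = summary.get(key)
        if rec is None:
            summary[key] = GroupContact(ga, gb, c.distance, 1)
        else:
            rec.n_atom_pairs += 1
            if c.distance < rec.min_distance:
                rec.min_distance = c.distance
    return list(summary.values())


def brute_force_contacts(atoms_a: Sequence[Atom],
                         atoms_b: Optional[Sequence[Atom]] = None,
                         cutoff: float = 5.0) -> ContactSet:
    """Reference O(n^2) double loop; same closed-ball convention.

    Exists so the grid implementation can be checked against the defining
    computation; not intended for large inputs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms_a = list(atoms_a)
    result = []
    if atoms_b is None:
        for i in range(len(atoms_a)):
            for j in range(i + 1, len(atoms_a)):
                d = float(np.linalg.norm(atoms_a[i].coords - atoms_a[j].coords))
                if d <= cutoff:
                    result.append(AtomContact(atoms_a[i], atoms_a[j], d))
    else:
        for a in atoms_a:
            for b in atoms_b:
                d = float(np.linalg.norm(a.coords - b.coords))
                if d <= cutoff:
                    result.append(AtomContact(a, b, d))
    return ContactSet(cutoff, result)
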