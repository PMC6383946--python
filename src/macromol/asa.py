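"""Shrake-Rupley accessible surface area.

Each atom is wrapped in a quasi-uniform shell of test points at radius
``r_vdw + probe`` (golden-section spiral); a point is buried when it falls
strictly inside any neighbor's expanded sphere, and the accessible fraction
of points scales the expanded-sphere area.  Neighbor search reuses the
spatial-hash grid from :mod:`macromol.contacts`.

The default van der Waals radii are the NACCESS/Chothia protein values
with element fallbacks, and relative ASA uses a shipped table of maximum
per-residue areas from Gly-X-Gly tripeptides (Tien et al. 2013,
theoretical), so per-residue reports mimic NACCESS .rsa output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .contacts import atom_contacts
from .model import Atom, Group

__all__ = ["AsaParams", "AsaResult", "sphere_points", "calc_asa",
           "relative_asa", "buried_surface", "atom_radius"]

# Chothia (1976)-lineage protein radii used by NACCESS, keyed on backbone
# role / element; element fallbacks cover hetero atoms.
_PROTEIN_RADII = {
    "N_backbone": 1.65,
    "CA": 1.87,
    "C_carbonyl": 1.76,
    "O": 1.40,
    "C_tetrahedral": 1.87,
    "C_trigonal": 1.76,
    "N_sidechain": 1.65,
    "S": 1.85,
}

_ELEMENT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.20, "D": 1.20, "P": 1.80, "SE": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 1.47, "ZN": 1.39, "MG": 1.73, "CA2": 1.97, "NA": 2.27, "K": 2.75,
}

# side-chain carbons that are trigonal (aromatic or carboxyl/amide C)
_TRIGONAL_CARBONS = {
    "CG": {"ASP", "ASN", "PHE", "TYR", "TRP", "HIS"},
    "CD": {"GLU", "GLN"},
    "CD1": {"PHE", "TYR", "TRP", "HIS"},
    "CD2": {"PHE", "TYR", "TRP", "HIS", "LEU_NOT"},
    "CE1": {"PHE", "TYR", "HIS"},
    "CE2": {"PHE", "TYR", "TRP"},
    "CE3": {"TRP"}, "CZ": {"PHE", "TYR", "ARG"},
    "CZ2": {"TRP"}, "CZ3": {"TRP"}, "CH2": {"TRP"},
}


class UnknownRadiusError(ValueError):
    """Raised when atoms have no resolvable van der Waals radius."""

    def __init__(self, atoms: Sequence[Atom]):
        names = ", ".join(f"{a.name}[{a.element}]" for a in atoms[:10])
        super().__init__(f"no van der Waals radius for atoms: {names}")
        self.atoms = list(atoms)


def atom_radius(atom: Atom, radii_set: str = "protor") -> Optional[float]:
    """Resolve the vdW radius for one atom, or None when unknown.

    ``radii_set="protor"`` applies the NACCESS/Chothia protein rules with
    element fallback; ``"single"`` uses plain per-element radii.
    """
    res = atom.group.res_name.upper() if atom.group is not None else ""
    name = atom.name.upper()
    element = atom.element.upper()
    if radii_set == "protor" and res in _STANDARD_AA:
        if name in ("N",):
            return _PROTEIN_RADII["N_backbone"]
        if name == "CA" and element == "C":
            return _PROTEIN_RADII["CA"]
        if name == "C":
            return _PROTEIN_RADII["C_carbonyl"]
        if element == "O":
            return _PROTEIN_RADII["O"]
        if element == "N":
            return _PROTEIN_RADII["N_sidechain"]
        if element == "S":
            return _PROTEIN_RADII["S"]
        if element == "C":
            allowed = _TRIGONAL_CARBONS.get(name)
            if allowed and res in allowed:
                return _PROTEIN_RADII["C_trigonal"]
            return _PROTEIN_RADII["C_tetrahedral"]
    if element in _ELEMENT_RADII:
        return _ELEMENT_RADII[element]
    return None


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class AsaParams:
    """Parameters of the rolling-ball calculation.

    ``probe_radius`` defaults to the water probe (1.4 Angstrom);
    ``n_sphere_points`` trades accuracy for time (960 reproduces
    single-atom areas to well under a percent); ``radii_set`` selects the
    vdW table; hydrogens are excluded by default (NACCESS convention).
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_set: str = "protor"
    include_hydrogens: bool = False
    max_asa_table: str = "tien2013"

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")


@dataclass
class AsaResult:
    """Per-atom, per-residue and total accessible surface areas (A^2)."""

    per_atom: dict = field(default_factory=dict)       # Atom -> area
    per_residue_abs: dict = field(default_factory=dict)  # Group -> area
    per_residue_rel: dict = field(default_factory=dict)  # Group -> fraction|None
    total: float = 0.0
    params: Optional[AsaParams] = None
    max_asa_table: str = ""


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors from the golden-section spiral.

    Deterministic for a given ``n``; all points have unit norm.
    """
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    k = np.arange(n, dtype=float)
    # z descends uniformly; azimuth advances by the golden angle
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1)[:, None]


def calc_asa(atoms: Sequence[Atom],
             params: Optional[AsaParams] = None) -> AsaResult:
    """Shrake-Rupley ASA for an atom list.

    A test point on atom i's expanded sphere is inaccessible iff it lies
    strictly inside a neighbor's expanded sphere (radius ``r_j + probe``).
    Raises :class:`UnknownRadiusError` when any atom has no radius.
    """
    params = params or AsaParams()
    atoms = [a for a in atoms
             if params.include_hydrogens or a.element not in ("H", "D")]
    result = AsaResult(params=params, max_asa_table=params.max_asa_table)
    if not atoms:
        return result
    radii = []
    unknown = []
    for a in atoms:
        r = atom_radius(a, params.radii_set)
        if r is None:
            unknown.append(a)
        else:
            radii.append(r)
    if unknown:
        raise UnknownRadiusError(unknown)
    radii = np.asarray(radii)
    probe = params.probe_radius
    expanded = radii + probe
    coords = np.array([a.coords for a in atoms])
    unit = sphere_points(params.n_sphere_points)
    # neighbor candidates: any pair whose expanded spheres can intersect
    cutoff = 2.0 * (float(radii.max()) + probe)
    neighbor_idx: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    index_of = {id(a): i for i, a in enumerate(atoms)}
    for c in atom_contacts(atoms, None, cutoff):
        i, j = index_of[id(c.atom_a)], index_of[id(c.atom_b)]
        neighbor_idx[i].append(j)
        neighbor_idx[j].append(i)
    total = 0.0
    for i, atom in enumerate(atoms):
        pts = coords[i] + expanded[i] * unit
        nbrs = [j for j in neighbor_idx[i]
                if np.linalg.norm(coords[j] - coords[i])
                < expanded[i] + expanded[j]]
        accessible = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= expanded[j] ** 2  # strictly inside buries
        area = (accessible.sum() / len(pts)) * 4.0 * np.pi * expanded[i] ** 2
        result.per_atom[atom] = float(area)
        total += area
        if atom.group is not None:
            result.per_residue_abs[atom.group] = \
                result.per_residue_abs.get(atom.group, 0.0) + float(area)
    result.total = float(total)
    result.per_residue_rel = relative_asa(result)
    return result


def _load_max_asa(table: str) -> dict[str, float]:
    with resources.files("macromol.data").joinpath(
            f"max_asa_{table}.json").open() as fh:
        return json.load(fh)


def max_asa_table(table: str = "tien2013") -> dict[str, float]:
    """The shipped per-residue maximum ASA reference table (A^2)."""
    return dict(_load_max_asa(table))


def relative_asa(result: AsaResult) -> dict:
    """Per-residue ASA fractions against the reference maximum table.

    Standard amino acids get ``abs / max``; anything else maps to None.
    """
    table = _load_max_asa(result.max_asa_table or "tien2013")
    out: dict = {}
    for group, area in result.per_residue_abs.items():
        ref = table.get(group.res_name.upper())
        out[group] = (area / ref) if ref else None
    return out


def buried_surface(complex_atoms: Sequence[Atom],
                   component_a_atoms: Sequence[Atom],
                   component_b_atoms: Sequence[Atom],
                   params: Optional[AsaParams] = None
                   ) -> tuple[float, dict]:
    """Buried surface area upon complexation.

    ``BSA = ASA(A) + ASA(B) - ASA(complex)``; the per-residue map carries
    the same difference per group.  The two component lists must partition
    the complex list (same atom objects).
    """
    ids_ab = {id(a) for a in component_a_atoms} | \
             {id(a) for a in component_b_atoms}
    if len(ids_ab) != len(component_a_atoms) + len(component_b_atoms) or \
            ids_ab != {id(a) for a in complex_atoms}:
        raise ValueError("component atom lists must partition the complex")
    params = params or AsaParams()
    asa_a = calc_asa(component_a_atoms, params)
    asa_b = calc_asa(component_b_atoms, params)
    asa_c = calc_asa(complex_atoms, params)
    bsa_total = asa_a.total + asa_b.total - asa_c.total
    per_residue: dict = {}
    for part in (asa_a, asa_b):
        for group, area in part.per_residue_abs.items():
            per_residue[group] = area - asa_c.per_residue_abs.get(group, 0.0)
    return float(bsa_total), per_residue
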