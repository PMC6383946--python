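"""Deterministic synthetic-structure generators.

Every generator builds ideal-geometry structures from internal coordinates
(NeRF-style chain extension), so each module of the toolkit can be tested
without downloading real structures.  All outputs are bit-exact functions
of their arguments; Gaussian coordinate noise is only added when a
``noise_sd > 0`` is requested together with an explicit seed.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .geometry import RigidTransform, apply_transform
from .model import (Atom, Chain, CrystalCell, Entity, Group, Structure)

__all__ = ["make_polyala", "make_strand_pair", "make_ligand_complex",
           "make_assembly", "make_crystal_toy", "place_atom_nerf",
           "add_noise"]

# Idealized backbone internal coordinates (lengths in Angstrom, angles deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0


def place_atom_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                    bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms A-B-C.

    ``bond`` is |C-D|, ``angle`` the B-C-D bond angle and ``torsion`` the
    A-B-C-D dihedral, both in degrees (natural extension reference frame).
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_coords(phis: np.ndarray, psis: np.ndarray) -> list[dict]:
    """Backbone N, CA, C, O positions for given per-residue phi/psi."""
    n = len(phis)
    residues: list[dict] = []
    # first residue in a canonical frame
    N = np.zeros(3)
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        prev = residues[-1]
        Nn = place_atom_nerf(prev["N"], prev["CA"], prev["C"],
                             BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CAn = place_atom_nerf(prev["CA"], prev["C"], Nn,
                              BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        Cn = place_atom_nerf(prev["C"], Nn, CAn,
                             BOND_CA_C, ANGLE_N_CA_C, phis[i])
        residues.append({"N": Nn, "CA": CAn, "C": Cn})
    # carbonyl oxygens: anti-periplanar to the next amide nitrogen
    for i, res in enumerate(residues):
        psi = psis[i]
        res["O"] = place_atom_nerf(res["N"], res["CA"], res["C"],
                                   BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return residues


def _as_per_residue(value: Union[float, Sequence[float]], n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"expected scalar or length-{n} sequence")
    return arr


def _chain_from_backbone(residues: list[dict], auth_id: str = "A",
                         first_serial: int = 1, first_resnum: int = 1,
                         entity_id: int = 1) -> Chain:
    chain = Chain(auth_id, asym_id=auth_id, entity_id=entity_id,
                  chain_type=Chain.POLYMERIC)
    serial = first_serial
    for i, res in enumerate(residues):
        g = Group("ALA", first_resnum + i, seq_id_label=i + 1)
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            g.add_atom(Atom(serial, name, element, res[name]))
            serial += 1
        chain.add_group(g)
    return chain


def make_polyala(n: int, phi: Union[float, Sequence[float]] = -57.0,
                 psi: Union[float, Sequence[float]] = -47.0,
                 auth_id: str = "A", struct_id: str = "POLYALA") -> Structure:
    """Ideal-geometry polyalanine backbone (N, CA, C, O per residue).

    With the default alpha-helical dihedrals (phi -57, psi -47) the chain
    forms the i -> i+4 hydrogen-bond registry of an alpha helix.  ``phi``
    and ``psi`` accept scalars or per-residue sequences so kinked or mixed
    conformations can be built.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    phis = _as_per_residue(phi, n)
    psis = _as_per_residue(psi, n)
    residues = _backbone_coords(phis, psis)
    chain = _chain_from_backbone(residues, auth_id=auth_id)
    entity = Entity(1, "polymer", "synthetic polyalanine",
                    "A" * n, "protein")
    return Structure(struct_id=struct_id, models=[[chain]], entities=[entity])


# Antiparallel two-stranded beta pair: the partner strand is the first
# strand rotated 180 degrees about the sheet normal (the two-fold axis of
# an antiparallel ladder) and offset across the sheet.  The offsets were
# fixed by minimizing the amide H-bond energies of the cross-strand
# N-H...O=C registry on the generated coordinates.
_STRAND_PHI = -139.0
_STRAND_PSI = 135.0
_PAIR_SHIFT_PER_RESIDUE = 3.5   # along the strand axis, times (n - 2)
_PAIR_SEPARATION = 3.4          # across the sheet


def make_strand_pair(n: int = 6, separation: Optional[float] = None,
                     struct_id: str = "BPAIR") -> Structure:
    """Two antiparallel beta strands of length ``n`` with H-bond registry.

    ``separation`` overrides the inter-strand offset (Angstrom, across the
    sheet); larger values break the hydrogen bonds, which is useful for
    building isolated-strand controls.
    """
    if n < 3:
        raise ValueError("strands need at least 3 residues")
    phis = np.full(n, _STRAND_PHI)
    psis = np.full(n, _STRAND_PSI)
    res_a = _backbone_coords(phis, psis)
    chain_a = _chain_from_backbone(res_a, auth_id="A", entity_id=1)
    # align strand axis with x before flipping
    ca = np.array([r["CA"] for r in res_a])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    zref = np.array([0.0, 0.0, 1.0])
    y = np.cross(zref, axis)
    y /= np.linalg.norm(y)
    z = np.cross(axis, y)
    align = np.vstack([axis, y, z])  # rows: new basis
    A = RigidTransform(align, -align @ ca[0])
    flip = np.diag([-1.0, -1.0, 1.0])  # 180 deg about the sheet normal
    sep = _PAIR_SEPARATION if separation is None else float(separation)
    trans = np.array([_PAIR_SHIFT_PER_RESIDUE * (n - 2), sep, 0.0])
    B = RigidTransform(flip, trans)
    T = A.inverse().compose(B.compose(A))
    res_b = [{k: apply_transform(T, v) for k, v in r.items()} for r in res_a]
    chain_b = _chain_from_backbone(res_b, auth_id="B",
                                   first_serial=4 * n + 1, entity_id=1)
    entity = Entity(1, "polymer", "synthetic beta strand", "A" * n, "protein")
    return Structure(struct_id=struct_id, models=[[chain_a, chain_b]],
                     entities=[entity])


def make_ligand_complex(n: int = 12, n_waters: int = 3,
                        struct_id: str = "LIGCPX") -> Structure:
    """A helical chain plus a non-polymeric ligand chain and waters.

    The ligand is a rigid five-atom fragment placed 4 Angstrom off the
    helix surface; waters are scattered on a fixed lattice nearby.
    """
    s = make_polyala(n)
    chain = s.chains[0]
    serial = 4 * n + 1
    center = np.mean([a.coords for a in chain.atoms], axis=0)
    lig_chain = Chain("L", asym_id="L", entity_id=2,
                      chain_type=Chain.NON_POLYMERIC)
    lig = Group("LIG", 1, seq_id_label=None, category="hetero")
    offsets = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0],
                        [0, 0, 1.5], [-1.5, 0, 0]], dtype=float)
    base = center + np.array([0.0, 0.0, 9.0])
    for k, off in enumerate(offsets):
        lig.add_atom(Atom(serial, f"C{k + 1}", "C", base + off))
        serial += 1
    lig_chain.add_group(lig)
    wat_chain = Chain("W", asym_id="W", entity_id=3,
                      chain_type=Chain.NON_POLYMERIC)
    for w in range(n_waters):
        g = Group("HOH", w + 1, category="water")
        g.add_atom(Atom(serial, "O", "O",
                        center + np.array([12.0 + 3.0 * w, 5.0, -4.0])))
        serial += 1
        wat_chain.add_group(g)
    entities = [Entity(1, "polymer", "synthetic polyalanine", "A" * n, "protein"),
                Entity(2, "non-polymer", "synthetic ligand"),
                Entity(3, "water", "water")]
    return Structure(struct_id=struct_id,
                     models=[[chain, lig_chain, wat_chain]], entities=entities)


def _parse_point_group(symbol: str) -> tuple[str, int]:
    symbol = symbol.strip().upper()
    if len(symbol) < 2 or symbol[0] not in "CD" or not symbol[1:].isdigit():
        raise ValueError(f"malformed point-group symbol {symbol!r}")
    fold = int(symbol[1:])
    if fold < 2:
        raise ValueError("point group fold must be >= 2")
    return symbol[0], fold


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def make_assembly(chain: Chain, point_group: str,
                  radius: float = 18.0,
                  struct_id: str = "ASSEMBLY") -> Structure:
    """Symmetric assembly from exact point-group copies of one chain.

    The template chain is centered, displaced ``radius`` Angstrom from the
    symmetry axis (z), and replicated by the exact rotations of the cyclic
    (Cn) or dihedral (Dn) group, so subunits never overlap for any chain
    smaller than the radius.  All copies share one entity.
    """
    family, fold = _parse_point_group(point_group)
    coords = np.array([a.coords for a in chain.atoms])
    centroid = coords.mean(axis=0)
    shift = np.array([radius, 0.0, 0.0]) - centroid
    ops = []
    for k in range(fold):
        ang = 2.0 * np.pi * k / fold
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                       [np.sin(ang), np.cos(ang), 0.0],
                       [0.0, 0.0, 1.0]])
        ops.append(RigidTransform(Rz, np.zeros(3)))
    if family == "D":
        flip = RigidTransform(np.diag([1.0, -1.0, -1.0]), np.zeros(3))
        ops = ops + [op.compose(flip) for op in ops]
    chains = []
    serial = 1
    for k, op in enumerate(ops):
        new = Chain(_CHAIN_IDS[k], asym_id=_CHAIN_IDS[k], entity_id=1,
                    chain_type=Chain.POLYMERIC)
        for g in chain.groups:
            ng = Group(g.res_name, g.seq_id_auth, g.ins_code,
                       g.seq_id_label, g.category)
            for a in g.atoms:
                ng.add_atom(Atom(serial, a.name, a.element,
                                 apply_transform(op, a.coords + shift),
                                 a.alt_loc, a.occupancy, a.b_factor,
                                 a.is_hetero))
                serial += 1
            new.add_group(ng)
        chains.append(new)
    seq = chain.sequence
    entity = Entity(1, "polymer", f"synthetic {point_group} subunit",
                    seq, "protein")
    return Structure(struct_id=struct_id, models=[chains], entities=[entity])


def make_crystal_toy(chain: Chain, space_group: str = "P 1",
                     gap: Union[float, Sequence[float]] = 20.0,
                     struct_id: str = "XTOY") -> Structure:
    """A one-chain asymmetric unit inside an orthorhombic cell.

    Each cell edge is the chain's bounding-box extent along that axis plus
    ``gap`` (scalar or per-axis), so the spacing between periodic images is
    controlled directly: a gap above the contact cutoff isolates the chain
    from every lattice image, while e.g. ``gap=(3, 20, 20)`` puts only the
    x-translates in contact.  The chain is centered in the cell.
    """
    gaps = np.broadcast_to(np.asarray(gap, dtype=float), (3,))
    if np.any(gaps <= 0):
        raise ValueError("gaps must be positive")
    coords = np.array([a.coords for a in chain.atoms])
    extent = coords.max(axis=0) - coords.min(axis=0)
    edges = extent + gaps
    centroid = coords.mean(axis=0)
    cell = CrystalCell(*edges, 90.0, 90.0, 90.0)
    new = Chain(chain.auth_id, asym_id=chain.asym_id, entity_id=1,
                chain_type=chain.chain_type)
    serial = 1
    target = edges / 2.0
    for g in chain.groups:
        ng = Group(g.res_name, g.seq_id_auth, g.ins_code, g.seq_id_label,
                   g.category)
        for a in g.atoms:
            ng.add_atom(Atom(serial, a.name, a.element,
                             a.coords - centroid + target, a.alt_loc,
                             a.occupancy, a.b_factor, a.is_hetero))
            serial += 1
        new.add_group(ng)
    entity = Entity(1, "polymer", "synthetic crystal toy",
                    chain.sequence, "protein")
    return Structure(struct_id=struct_id, models=[[new]], entities=[entity],
                     cell=cell, space_group_name=space_group)


def add_noise(structure: Structure, noise_sd: float, seed: int) -> Structure:
    """Gaussian coordinate noise with an explicit seed, applied in place."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    for model in structure.models:
        for chain in model:
            for atom in chain.atoms:
                atom.coords = atom.coords + rng.normal(0.0, noise_sd, 3)
    return structure
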