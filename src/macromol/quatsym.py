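"""Global quaternary symmetry: subunit clustering and point-group detection.

Identical subunits are clustered by pairwise global sequence identity;
candidate symmetry operations come from superposing the CA trace of one
chain onto each equivalent chain.  An operation is accepted when applying
it maps every chain of the assembly onto some chain within the RMSD
threshold (a chain permutation) and its rotation angle is consistent with
a 360/k-fold axis.  Accepted rotations are classified into C1, Cn or Dn;
cubic point groups (more than one axis of order > 2) are flagged as
unsupported rather than misreported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import RigidTransform, apply_transform, rmsd, superpose
from .model import Chain, Structure, polymer_residues

__all__ = ["PointGroupResult", "cluster_subunits", "detect_point_group",
           "sequence_identity"]


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Identity = matched identical positions / alignment length of a simple
    global (Needleman-Wunsch) alignment.
    """
    if not seq_a or not seq_b:
        return 0.0
    if seq_a == seq_b:
        return 1.0
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / max(len(a), 1)


def cluster_subunits(structure: Structure,
                     min_seq_identity: float = 0.95) -> list[list[Chain]]:
    """Single-linkage clusters of polymeric chains by sequence identity."""
    chains = [c for c in structure.polymer_chains() if c.sequence]
    n = len(chains)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(chains[i].sequence,
                                 chains[j].sequence) >= min_seq_identity:
                parent[find(i)] = find(j)
    clusters: dict[int, list[Chain]] = {}
    for i, c in enumerate(chains):
        clusters.setdefault(find(i), []).append(c)
    return sorted(clusters.values(), key=len, reverse=True)


@dataclass
class AcceptedOp:
    """A symmetry operation that permutes the assembly onto itself."""

    transform: RigidTransform
    permutation: tuple[int, ...]   # chain index mapping i -> perm[i]
    fold: int                      # rotation order k (angle ~ 360/k)
    mean_rmsd: float
    axis: Optional[np.ndarray]


@dataclass
class PointGroupResult:
    """Detected global point group with its supporting evidence."""

    symbol: str                    # "C1", "Cn", "Dn" or "unsupported (...)"
    order: int
    axes: list = field(default_factory=list)  # (unit 3-vector, fold)
    mean_rmsd: float = 0.0
    subunit_clusters: list = field(default_factory=list)
    operations: list = field(default_factory=list)


def _ca_coords(chain: Chain) -> np.ndarray:
    return np.array([g.get_atom("CA").coords for g in polymer_residues(chain)
                     if g.get_atom("CA") is not None])


def _angle_fold(angle_deg: float, tol_deg: float = 8.0) -> Optional[int]:
    """k such that angle ~ 360/k (k up to 12); None when no k fits."""
    if angle_deg < tol_deg:
        return 1
    for k in range(2, 13):
        if abs(angle_deg - 360.0 / k) <= tol_deg:
            return k
    return None


def _assembly_permutation(cas: list[np.ndarray], t: RigidTransform,
                          threshold: Optional[float]
                          ) -> Optional[tuple[tuple[int, ...], float]]:
    """Greedy chain mapping under transform t; None unless a bijection
    (within the threshold, when given) exists."""
    n = len(cas)
    perm = [-1] * n
    used = [False] * n
    rmsds = []
    for i in range(n):
        moved = apply_transform(t, cas[i])
        best, best_r = -1, None
        for j in range(n):
            if used[j] or cas[j].shape != moved.shape:
                continue
            r = rmsd(moved, cas[j])
            if best_r is None or r < best_r:
                best, best_r = j, r
        if best_r is None or (threshold is not None and best_r > threshold):
            return None
        perm[i] = best
        used[best] = True
        rmsds.append(best_r)
    return tuple(perm), float(np.mean(rmsds))


def _refine_over_assembly(cas: list[np.ndarray], perm: tuple[int, ...]
                          ) -> Optional[tuple[RigidTransform, float]]:
    """Optimal single transform mapping every chain i onto chain perm[i],
    fitted over all CA atoms at once (suppresses the lever-arm error of a
    one-chain fit)."""
    try:
        moving = np.vstack([cas[i] for i in range(len(cas))])
        fixed = np.vstack([cas[perm[i]] for i in range(len(cas))])
    except ValueError:
        return None
    if fixed.shape != moving.shape:
        return None
    t, _ = superpose(fixed, moving)
    per_chain = [rmsd(apply_transform(t, cas[i]), cas[perm[i]])
                 for i in range(len(cas))]
    return t, float(np.mean(per_chain))


def detect_point_group(structure: Structure,
                       rmsd_threshold: float = 3.0,
                       min_seq_identity: float = 0.95) -> PointGroupResult:
    """Detect the global point group (C1, Cn or Dn) of an assembly.

    Candidate operations are the CA superpositions of a reference chain
    onto every chain of its sequence cluster; each candidate is accepted
    only if it permutes the whole assembly within ``rmsd_threshold``.
    Chains whose length deviates more than 10% from their cluster's
    reference are excluded (with the cluster kept for reporting).
    """
    clusters = cluster_subunits(structure, min_seq_identity)
    result = PointGroupResult("C1", 1, subunit_clusters=clusters)
    if not clusters:
        return result
    # usable chains: members of clusters, length within 10% of cluster median
    chains: list[Chain] = []
    for cl in clusters:
        lengths = [len(_ca_coords(c)) for c in cl]
        med = float(np.median(lengths))
        for c, ln in zip(cl, lengths):
            if med > 0 and abs(ln - med) / med <= 0.10:
                chains.append(c)
    if len(chains) < 2:
        return result
    cas = [_ca_coords(c) for c in chains]
    seqs = [c.sequence for c in chains]

    accepted: list[AcceptedOp] = []
    seen_perms: set[tuple[int, ...]] = set()
    ref_cluster = [i for i, c in enumerate(chains)
                   if sequence_identity(seqs[0], seqs[i]) >= min_seq_identity
                   and cas[i].shape == cas[0].shape]
    for j in ref_cluster:
        t0, r = superpose(cas[j], cas[0])
        if r > rmsd_threshold:
            continue
        # permutation from the seed transform, then refit the operator
        # over the whole assembly before applying the threshold
        res = _assembly_permutation(cas, t0, None)
        if res is None:
            continue
        perm = res[0]
        refined = _refine_over_assembly(cas, perm)
        if refined is None:
            continue
        t, mean_r = refined
        if mean_r > rmsd_threshold:
            continue
        fold = _angle_fold(t.rotation_angle)
        if fold is None:
            continue
        if perm in seen_perms:
            continue
        seen_perms.add(perm)
        accepted.append(AcceptedOp(t, perm, fold, mean_r, t.rotation_axis))

    non_identity = [op for op in accepted if op.fold > 1]
    if not non_identity:
        return result
    result.operations = accepted
    result.mean_rmsd = float(np.mean([op.mean_rmsd for op in non_identity]))

    # group the accepted rotations by axis
    axes: list[tuple[np.ndarray, list[AcceptedOp]]] = []
    for op in non_identity:
        ax = op.axis
        placed = False
        for known, ops in axes:
            if abs(float(np.dot(known, ax))) > 0.98:
                ops.append(op)
                placed = True
                break
        if not placed:
            axes.append((ax, [op]))
    # order of each axis: highest fold with all powers present
    axis_orders = []
    for ax, ops in axes:
        fold = max(op.fold for op in ops)
        axis_orders.append((ax, fold))
    axis_orders.sort(key=lambda t: -t[1])
    result.axes = [(ax, fold) for ax, fold in axis_orders]

    high = [(ax, f) for ax, f in axis_orders if f > 2]
    if len(high) > 1:
        result.symbol = "unsupported (higher symmetry suspected)"
        result.order = len(seen_perms)
        return result
    main_axis, n_fold = axis_orders[0]
    two_folds_perp = [
        (ax, f) for ax, f in axis_orders[1:]
        if f == 2 and abs(float(np.dot(ax, main_axis))) < 0.2]
    if two_folds_perp:
        result.symbol = f"D{n_fold}"
        result.order = 2 * n_fold
    else:
        result.symbol = f"C{n_fold}"
        result.order = n_fold
    return result
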