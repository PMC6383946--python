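# Methods

This note documents the models, algorithms and numerical choices behind
`macromol`, and what the synthetic test structures do and do not show
about real data.

## Structure model

The in-memory hierarchy mirrors the PDBx/mmCIF dictionary:
`Structure -> models -> Chain -> Group -> Atom`, with `Entity` records
describing unique molecular species.  Chains carry exactly two types:
**polymeric** (polypeptides, nucleic acids) and **non-polymeric**
(ligands, cofactors, ions, waters).  Waters stay in non-polymeric chains
but keep the mmCIF `water` entity type on their `Entity` and
`category="water"` on the group, so no mmCIF fidelity is lost by the
two-type chain split.

Residues are addressed primarily by author numbering
(`seq_id_auth` + insertion code), with mmCIF label numbering carried
alongside; this is what makes PDB-format interoperability lossless.
By default parsers keep only the first-listed alternate location per atom
name (downstream algorithms need one position per atom); a parser option
retains all alt-locs.  Multi-model files keep every model; algorithms
operate on model 1 by default and accept a 0-based model index.

## File I/O

The PDB reader/writer implements the wwPDB v3.3 fixed columns
(coordinates `%8.3f`, occupancy/B `%6.2f`).  The writer never truncates:
chain ids longer than the single chain-id column, residue names over
3 characters, serials over 99999 or coordinates outside `%8.3f` raise an
explicit overflow error.  Elements missing from the input are derived
from the atom name.

The mmCIF side uses a purpose-built minimal CIF tokenizer (key-value
pairs, `loop_` tables, single/double quotes, semicolon text fields,
comments) feeding the categories `atom_site`, `cell`, `symmetry`,
`entity`, `entity_poly` and `struct`; other categories are skipped.
Parse errors carry 1-based line numbers.  When a file has no entity
records, entities are synthesized from chain content (one polymer entity
per unique sequence, one per ligand name, one water entity).

Round-tripping is a fixed point after the first write: the first
parse of a written file quantizes coordinates to 3 decimals (the PDB
column precision, also used in our mmCIF writer), after which
parse -> write -> parse reproduces coordinates bit-exactly.

## Contacts

Neighbor search buckets atoms into a uniform grid with cell edge equal to
the cutoff and inspects the 27 surrounding cells, which makes the
returned pair set *identical* to the O(n^2) definition, not an
approximation.  The boundary convention is a closed ball: a pair at
distance exactly equal to the cutoff counts.  Hydrogens and waters are
included unless the caller excludes them; the default residue-level
cutoff is 5.0 A on any atom pair.  Both conventions are configuration,
since no single choice suits every analysis.

## Accessible surface area

Shrake-Rupley: each atom is surrounded by `n_sphere_points`
(default 960) directions from a golden-section spiral, scaled to
`r_vdw + probe` (probe default 1.4 A, water).  A test point is buried iff
it falls *strictly inside* some neighbor's expanded sphere; the
accessible fraction scales the expanded-sphere area
`4 pi (r_i + probe)^2`.  Neighbor candidates come from the contact grid
at cutoff `2 (r_max + probe)`.

Radii: the default `protor` set applies Chothia-lineage protein radii
(backbone N 1.65, CA 1.87, carbonyl C 1.76, O 1.40, tetrahedral C 1.87,
trigonal/aromatic C 1.76, S 1.85) with per-element fallbacks
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, ...) for hetero atoms.
Hydrogens are excluded by default (NACCESS convention).  Relative
per-residue ASA divides by a shipped Gly-X-Gly maximum-ASA table
(Tien et al. 2013, theoretical values); non-standard residues get a null
fraction.  Buried surface area is `ASA(A) + ASA(B) - ASA(AB)` computed
with identical parameters, which keeps it non-negative to numerical
precision.

Numerical properties worth knowing: the computation is exactly
translation-invariant, but rotating a molecule re-samples the fixed
test-point directions, so totals match only to the discretization error
(about 0.4% at 960 points on an 18-residue helix; shrinking with more
points).  Against an independent Shrake-Rupley implementation at matched
radii, probe and point count, per-residue values agree to well under 1%.

## Secondary structure

A from-scratch implementation of the hydrogen-bond-pattern algorithm
producing the classic 8 states `H G I E B T S -`:

- Amide hydrogens are reconstructed at 1.0 A from N, anti-parallel to
  the preceding carbonyl C->O direction; prolines and chain starts get
  none.
- Bond energy: `E = 0.42 * 0.20 * 332 * (1/rON + 1/rCH - 1/rOH - 1/rCN)`
  kcal/mol (prefactor 27.888), clamped at -9.9; a bond exists iff
  `E < -0.5`.  Donor-acceptor pairs are pre-screened at 9 A CA-CA
  (an optimization, not semantics).
- n-turns (n = 3, 4, 5) from `i -> i+n` bonds; two consecutive n-turns
  make minimal helices G/H/I.  Parallel and antiparallel bridges follow
  the classic two-clause bond patterns; consecutive bridges form ladders
  (E), isolated bridges stay B.  Turn interiors get T; kappa (the
  CA(i-2), CA(i), CA(i+2) virtual angle) above 70 degrees gives S.
- Priority: H > E/B > G > I > T > S.
- Chain breaks: CA-CA above 4.5 A severs the H-bond network; residues
  with incomplete backbones are excluded from bonding.

All constants live in one table (`secstruc.CONSTANTS`).  Ladder bulges
(one-residue insertions joining two ladders) are not merged; on the
idealized fixtures this never matters, and against a reference DSSP
implementation the fixture suite agrees at 100% residue identity (the
contract requires >= 95%, differences confined to segment boundaries).
PPII and other extended-alphabet variants are deliberately out of scope.

## Geometry

Superposition is Kabsch via SVD with the usual determinant correction,
so only proper rotations are returned; mirror-image inputs superpose
with det +1 rather than reflecting.  Collinear point sets still return
a valid minimizer (the SVD picks the free rotation arbitrarily).
RMSD without superposition is provided separately and always bounds the
superposed residual from above.

## Crystal lattices

Operators for the 65 Sohncke space groups (the chiral-compatible groups
available to protein crystals) ship as Jones-faithful triplets in the
standard setting and are parsed with exact rational arithmetic, so group
axioms (identity, closure mod lattice translations) are checked
symbolically, not numerically.  Non-Sohncke names are rejected.
Orthogonalization uses the standard a-along-x crystallographic frame.

Lattice reconstruction enumerates all (operator, shift) images with
shift components in `[-max_shift, max_shift]`; crystal contacts pair the
asymmetric unit's chains against each other and against every image,
using the same contact grid.  Symmetry-equivalent interfaces are
deduplicated by a fingerprint of sorted residue-pair contacts with
distances rounded to 1e-3 A, and results are ordered by atom-contact
count.  Waters are excluded by default; the default cutoff is 5.0 A.

## Quaternary symmetry

Subunits cluster by single-linkage on pairwise global sequence identity
(default threshold 0.95; identity = identical columns / alignment
length).  Candidate operations superpose the CA trace of a reference
chain onto each chain of its cluster; the induced chain permutation is
then refit over *all* CA atoms at once, which suppresses the lever-arm
error a one-chain fit makes about a distant axis — without this, 0.5 A
coordinate noise at a 18 A radius routinely pushed valid operations past
threshold.  An operation is accepted when the refined per-chain RMSD is
at or below the threshold (default 3.0 A) and its rotation angle matches
360/k within 8 degrees.  Accepted axes are grouped (dot product > 0.98);
one k-fold axis gives Ck, a k-fold axis plus perpendicular 2-folds gives
Dk, nothing accepted gives C1, and more than one axis of order > 2 is
reported as `unsupported (higher symmetry suspected)` rather than
guessed at — tetrahedral and higher cubic groups are out of scope.
Chains whose length deviates more than 10% from their cluster median are
excluded from the fit.

## Synthetic fixtures

Backbones are built from internal coordinates (NeRF chain extension)
with ideal geometry (N-CA 1.458, CA-C 1.525, C-N 1.329, C=O 1.231 A;
omega 180).  `(phi, psi) = (-57, -47)` yields the alpha-helical
`i -> i+4` registry (O...N 3.09 A, CA-CA 3.80 A); `(-49, -26)` gives a
3-10 helix, `(-57, -70)` a pi helix, `(-139, 135)` an extended strand.
The antiparallel strand pair places the partner by a two-fold rotation
about the sheet normal with offsets fixed by minimizing the cross-strand
amide bond energies (3.4 A across the sheet); a 4-residue pair leaves a
single isolated bridge, which is how the B state is exercised.
Assemblies replicate a centered chain displaced 18 A from the z axis by
exact Cn/Dn rotations; crystal toys size an orthorhombic cell from the
chain's bounding box plus a per-axis gap, so image contact is controlled
directly by the gap against the cutoff.

All generators are bit-exact deterministic; Gaussian noise is applied
only on request with an explicit seed.

What the fixtures do *not* emulate: side chains (beyond radii defaults),
B-factor/occupancy variation, alternate conformations, missing atoms,
sequence diversity, and the irregular geometry of real proteins.
Passing tests therefore demonstrate algorithmic correctness against
definitions and reference implementations on controlled geometry, not
robustness to experimental artifacts.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems — helices of 8-18 residues, assemblies of 2-6 chains, contact
instances up to a few hundred atoms, 100 randomized grid-vs-brute-force
instances — chosen so every check completes in seconds while still
covering the code paths at full algorithmic strength.
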