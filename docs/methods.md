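# Methods

## Model

`prscan` treats a protein as an anisotropic elastic network over its Cα
atoms. Two residues are *bonded* when their author residue numbers differ by
exactly one within the same chain — the only defensible notion of bondedness
at Cα resolution — and carry a fixed spring constant γ_b = 1. Every other
pair interacts with k_ij = c/r_ij² (c = 8, r_ij in Å), so the network has no
interaction cutoff at all: distance weighting replaces the cutoff radius
whose optimal value is protein-dependent in conventional elastic models.
Residues missing from the coordinate file are simply absent nodes; a
numbering gap therefore never receives a spurious stiff bonded spring.

The stiffness is assembled per pair as the 3×3 block
−(k_ij/r_ij²)·(r_ij ⊗ r_ij), with diagonal blocks equal to minus the sum of
the row's off-diagonal blocks, which enforces translation invariance by
construction. An equivalent factorization H = B·K·Bᵀ (B the 3N×M
directional-cosine matrix over the M interacting pairs, K the diagonal of
spring constants) is kept as an independent assembly path and asserted equal
elementwise in the tests.

Units: distances in Å; spring constants dimensionless; forces are unit
vectors, so displacements are in arbitrary units. Nothing downstream
consumes absolute magnitudes — the response ratio is dimensionless and the
pathway uses directions only — so no force scale needs to be fixed.

## Linear response and the scan

The equilibrium displacement under an external force is ΔR = H⁺ΔF. H⁺ is
computed by symmetric eigendecomposition; eigenvalues below 1e-8 of the
largest are treated as the null space and dropped. A generic 3-D structure
has exactly six null modes (rigid translations and rotations); any other
count raises a degenerate-geometry warning (collinear and planar synthetic
geometries exercise this path deliberately). For a free-free system the
pseudo-inverse projects the applied force onto the range of H; one
consequence worth noting is that a unit axial force on an isolated bonded
pair produces the extension F/(2k), not the fixed-end textbook F/k, because
the projected force is ±F/2 on each node.

Each residue is perturbed along 7 canonical unit directions (the three axes,
three face diagonals and the body diagonal, diagonals normalized). Per
direction d the response matrix stores A_ij = |ΔR_j|², the squared
displacement magnitude of residue j under a push at i ("mean square
fluctuation response"). A flag (`magnitude_mode="rms"`) switches to plain
magnitudes for sensitivity checks; squared is the default and is what the
response ratio is defined on.

The allosteric response ratio per direction is
χ_j^(d) = ⟨A_ij⟩_{i∈pocket} / ⟨A_ij⟩_{i∈all}, self-response included in both
averages, with no row normalization (the ratio is already normalized by
construction: pocket = all residues gives χ ≡ 1 identically, which is run as
a control on every geometry). The per-residue score is the maximum of
χ_j^(d) over directions (`combine="mean"` is available). A direction whose
force lies entirely in the null space — e.g. the out-of-plane axis of a
planar test geometry — returns an identically zero response matrix and is
skipped with a warning rather than producing 0/0. Hot residues are those
with χ_j above 1.0, reported in author numbering in descending χ.

Replacing the 7 canonical directions with 50 random unit directions changes
the hot set only marginally; the suite asserts a Jaccard overlap of at least
0.7 on the synthetic structures.

## Pathways

For each candidate residue k and pocket residue i, the 3×3 block of H⁺
coupling k to i is decomposed by SVD (the off-diagonal block is not
symmetric; the left singular vector of the largest singular value is the
direction k predominantly moves in, and the squared singular values play the
role of the eigenvalue spectrum — one dominant value means motion along a
line). Eigenvector sign is arbitrary, so vectors are canonicalized (first
nonzero component positive) and all comparisons use |cos θ|: antiparallel
motion counts as moving in line.

Candidates are the hot residues expanded by a window of 3 (each hot residue
brings in its immediate sequence neighbors). For a candidate pair the
overlap is the mean over pocket perturbation sites of |cos θ| between the
two dominant directions (`site_combine="max"` available); pairs at or above
the 0.98 cutoff become edges of a DAG ordered by sequence position. Any pair
may link regardless of spatial separation; an optional maximum Cα–Cα
distance filter exists but is off by default.

A pathway is a *maximal* monotone chain: it starts at a node with no
incoming edge and ends at a node with no outgoing edge. Restricting to
maximal chains is what makes the product weighting meaningful — weights are
≤ 1, so without it a single strong link would always outscore the full chain
it belongs to. Among maximal chains, dynamic programming over increasing
residue index finds the maximum product weight exactly (verified against
brute-force enumeration on random DAGs); ties go to the longer chain, then
the smaller start residue. One caveat follows from maximality: deleting a
node can *raise* the best weight by cutting off a forced low-weight
extension; monotonicity under node removal holds over the set of all chains,
not the maximal ones, and the tests state it in that form. If no pair
clears the cutoff the result is a single-node pathway of weight 1 carrying
an explicit warning.

## Ensembles

Conformers displace the Cα model along single-perturbation response fields:
conformer 0 is the unperturbed model, then (site × 7 directions) are swept
deterministically, falling back to seeded random sites/directions once the
sweep is exhausted. Each field is scaled so the largest per-residue
displacement equals the amplitude (default 2.0 Å, n = 50 conformers — free
parameters; the default samples somewhat beyond the sub-Å backbone shifts
seen between bound and unbound PDZ crystal structures). Because the null
modes are dropped, displacement fields carry no net translation. A conformer
bringing any Cα pair below 1.0 Å is rejected with a warning and replaced by
a fresh draw. Output is Cα-only, multi-MODEL PDB; all-atom rebuilding for
docking is delegated to external tools.

## Evaluation

Predicted hot sets are compared to reference residue lists through a 2×2
contingency table over the analyzed chain's resolved residues. Matching is
exact author-number identity by default; a ±1 near-miss mode exists (off by
default) because low-resolution models legitimately hit a neighbor of the
experimentally mutated residue. Fisher's exact p-value is two-sided by the
probability-mass rule and computed with exact rational arithmetic — the
fixed-margin hypergeometric probabilities of a 2×2 table are rationals, so
ties are resolved exactly rather than to floating tolerance; a one-sided
option is exposed. Structural RMSD uses least-squares optimal superposition
(SVD), pairing atoms by author residue number and atom name over residues
common to both structures; backbone = N, CA, C, O.

## Synthetic geometries

The generator produces linear chains (deliberately degenerate: extra null
modes), regular rings (planar: out-of-plane floppiness), ideal α-helices
(3.6 residues/turn, 1.5 Å rise, 2.3 Å radius), seeded random clouds with a
minimum-separation guarantee, and a two-node pair with closed-form response.
These emulate the geometric regimes the method must handle — anisotropic
periodic structure, isotropic disorder, degeneracy — but none of them have
native-like packing, secondary-structure mixtures, or real binding pockets;
passing on them validates the mathematics (assembly identities, spectra,
linear response, normalization, search exactness), not predictive power on
real proteins. The crystal-structure benchmarks carry that burden and
require user-supplied PDB files (data/structures/README.md). An independent
response oracle solves the same spring system as a dense KKT system with an
explicit null-space constraint basis — no eigendecomposition — and must
agree with the compliance route to 1e-8 on small geometries.

## Numerical choices and limitations

- Pseudo-inverse tolerance 1e-8 relative to the largest eigenvalue;
  coincident-node guard 1e-3 Å; altloc policy highest occupancy, ties by
  altloc letter.
- The acceptance script's demo sizes (60-residue geometries, 200 random
  DAGs, 300 random tables) are the package's chosen standard problem sizes;
  all scale linearly to larger runs.
- The constant c = 8 is treated as a bare numeric with Å-based distances.
- Dense algebra throughout: fine for single domains (N ≲ a few hundred);
  no sparse or iterative path is provided.
- Single-chain analysis; mmCIF, nucleic acids and biological-assembly
  expansion are out of scope.
- The method models harmonic response around one structure; it cannot see
  anharmonic transitions, side-chain rearrangements, or entropic effects
  beyond what the network topology encodes.
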