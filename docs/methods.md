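# Methods

This note documents the models, numerical choices and limitations behind
`subsites`. Units are Å for lengths, degrees for angles; energies are in
internal model units and are only ever used comparatively.

## Structure model and alignment

Structures are held in a four-level hierarchy (Atom/Residue/Chain/
Structure) with author residue numbering. Parsing goes through gemmi and
keeps only the first MODEL; alternate locations collapse to the
highest-occupancy conformer (ties: first encountered), which is the
common single-conformer convention for crystal structures. The PDB
writer emits fixed wwPDB v3.3 columns so that a write/parse round trip
preserves identifiers exactly and coordinates to 3 decimals.

Pairwise sequence alignment is global Needleman–Wunsch–style alignment
with BLOSUM62, gap open −10 and gap extension −0.5 (a gap of length L
scores −10 − 0.5·(L−1)), via Bio.Align. The identity fraction counts
identical non-gap, non-X columns over **all** alignment columns,
including gaps; this is the stricter of the common denominators and is
the one used for the >50 % homology-transfer threshold and the 30 %
superposition floor. Both thresholds are configurable.

Rigid superposition is the Kabsch SVD solution constrained to proper
rotations; inputs with fewer than 3 points or rank < 2 (collinear) are
rejected. Tests cross-check the RMSD against an independent quaternion
solver.

## Annotation workflow

*Ligand detection.* Candidate substrates are chains of 3–12 non-water
residues containing at least one residue from a configurable
peptide-like name list (default: the 20 standard residues; extendable
with hetero codes). A residue-name list stands in for a chemical
dictionary classification so the package has no database dependency.
All-UNK chains are excluded.

*Catalytic-site occupancy.* The ligand is accepted as a substrate when
removing its chain strictly increases the summed all-atom accessible
surface of the annotated catalytic residues (threshold 0 Å², strict
inequality). All-atom rather than side-chain-only accessibility is used;
the choice is configurable. Structures without catalytic annotation are
rejected, mirroring the workflow's hard requirement.

*Pocket assignment.* Around a reference substrate whose residues carry
P4–P4′ labels, every protease residue with ≥1 atom within 4.5 Å of ≥1
atom of a peptide residue joins that residue's pocket; membership in
several pockets is allowed and waters are excluded. Peptide
directionality is chain N→C; the scissile bond lies between the S1 and
S1′ residues.

*Projection.* To annotate a homologous complex, the primary protease
chains (longest non-peptide chain on each side) are aligned in sequence;
below 30 % identity the projection refuses. Matched CA pairs give a
Kabsch superposition, and each target peptide residue takes the pocket
of the reference residue with the most of its atoms within 2 Å.
Count ties resolve to the N-terminal-most reference residue — an
arbitrary but fixed rule. Residues with zero atoms in range stay
unassigned. Pocket-forming residues are then recomputed in the target's
own frame with the 4.5 Å rule.

*Gap closing.* When consecutive peptide residues carry non-consecutive
pocket labels (or an unassigned stretch separates two runs), the longer
assigned run is trusted and the shorter run is re-labelled by its
residue offset from the longer run's anchor; equal-length ties keep the
N-terminal run fixed. Labels that would fall outside S4–S4′ become
unassigned.

*Filters.* Capping groups (ACE/ACY/NME/NH2 and diazomethane-like codes)
are removed at the residue level; substrates with fewer than three
pocket-assigned residues are discarded with an explicit reason string.
Both operations are idempotent.

*Homology transfer of catalytic residues.* The annotated library is
scanned in input order and the first entry whose alignment identity
exceeds the floor donates its catalytic positions through the alignment
columns; positions aligned against query gaps are dropped with a
warning. Input order stands in for any better-defined priority since the
procedure is declared order-dependent ("first passing alignment").

## Substrate modelling

*NNAA replacement.* Non-natural residues are compared with the 20
natural amino acids as whole molecules via Morgan fingerprints
(radius 2, 2048 bits, rdkit) and the Tanimoto coefficient. Ties break
alphabetically; below a similarity floor of 0.4 the complex is declared
unreplaceable and discarded. The floor is a package choice — it sits
well below the similarity of conservative pairs (norleucine/leucine
≈ 0.5–0.7) and above unrelated scaffolds. A heavy-atom element-count
profile similarity is available as a dependency-free fallback
fingerprinter.

*Mutation.* Side chains are rebuilt from ideal residue templates (the
chemical-component definitions bundled with biotite) superposed on the
target N/CA/C frame; the crystallographic backbone is never touched.
Chi angles are copied from the original residue wherever the torsion
definition (atom quadruplet) carries over, otherwise set from a compact
single-conformer rotamer table (chi1 ≈ −65°, extended distal angles,
with the usual exceptions for Ser/Thr/Val/Ile). Proline keeps its
template ring. Chi rotations move only atoms distal to the rotation
bond, never backbone atoms — the intra-residue bond graph is inferred
from distances and may contain spurious short contacts, so the backbone
is excluded from the traversal by construction. A clash is any
protease–peptide heavy-atom pair under 2.0 Å; mutation reports the
count. An adapter hook allows an external packing engine to replace the
internal one.

*Internal relaxation.* After each threading mutation, the mutated side
chain scans chi1 (30° grid) × chi2 (60° grid) and keeps the orientation
with the lowest Lennard-Jones interaction with the rest of the complex.
This is deliberately a torsion-grid minimisation, not a full repacking.

*Reconstruction of missing positions.* Partial substrates (≥3 contiguous
pockets) are extended residue by residue to the full 8-mer with ideal
trans-peptide geometry (C–N 1.329, ω = 180°). For each new residue a
φ/ψ grid (the extended-strand pair −139°/135° first, then 30° steps) is
scanned and the minimum-clash conformer kept; if no grid point is
clash-free the complex raises an "unmodellable" signal — there are no
partial successes. New residues are built as glycine and then mutated to
the target sequence.

*Libraries.* Random libraries (default 480 peptides of length 8) draw
i.i.d. uniformly from the 20 amino acids at every position from a
seeded generator; threading substitutes positions in P4→P4′ order.

## Energy model and sampling

The energy is a weighted sum of three non-bonded terms over atom pairs
excluding 1-2 and 1-3 neighbours (bonds inferred from distances):
a 12-6 Lennard-Jones with element radii (r_min = r_i + r_j,
ε = √(ε_i ε_j)), Coulomb with distance-dependent dielectric ε(r) = 4r
and fixed small charges on backbone N/C/O and polar side-chain atoms,
and a short-range bonus for polar N/O cross-residue pairs ramping
linearly from 0 at 3.5 Å to −1 at 2.8 Å as a proxy for hydrogen bonding.
The non-bonded cutoff is 10 Å with no long-range correction. Units are
internal; no correspondence to kcal/mol is claimed, which is why every
downstream quantity is an average or a rank.

Backbone moves follow the backrub geometry: a randomly chosen segment of
2–12 consecutive flexible residues rotates rigidly about the axis
through its flanking CA atoms by a uniform angle up to ±11°. Because
both pivots lie on the axis, all bond lengths are preserved exactly;
only the bond angles at the pivots strain, and the Metropolis criterion
(accept with min(1, exp(−ΔE/kT))) handles the penalty. Side-chain moves
perturb one chi angle of one flexible residue by a Gaussian step
(σ = 20°). The flexible region defaults to the peptide plus the
pocket-forming residues; the rest of the enzyme is frozen for
tractability, consistent with the interface focus of the observables.

Defaults: 5000 steps, kT = 1.2, frame recorded every 10 steps (accepted
or not) → 500 frames, equal backbone/side-chain move probability. kT is
a dimensionless temperature factor of the internal energy scale; the
numeric value 1.2 is kept as the familiar default label and is
configurable. Trajectories are reproducible per seed and export as
multi-MODEL PDB.

## Observables

*Accessibility.* Shrake–Rupley quadrature with probe 1.4 Å and 960
points per atom by default. The point set is a golden-spiral layout
symmetrised antipodally, which makes mirror-image environments bury
identical point counts and tightens convergence. Doubling the point
count changes well-exposed residue ASA by <1 %; nearly-buried residues
(a few Å² of exposed cap) keep an irreducible few-percent quadrature
noise at any practical point count — the independent implementation in
biotite shows the same behaviour on the same geometry. Unknown elements
without a configured radius raise an error naming the atom. Relative ASA
divides the residue total by theoretical Gly-X-Gly maxima (Tien-style
values); slightly exceeding 1 for distorted geometry is allowed.

*Contacts.* Hydrogen bonds use HBPLUS-flavoured geometric defaults:
donor–acceptor ≤ 3.9 Å, hydrogen–acceptor ≤ 2.5 Å, D–H–A angle ≥ 90°,
all configurable. Crystal structures lack hydrogens, so backbone amide
hydrogens are placed geometrically (N–H 1.01 Å opposite the
C(prev)/CA bisector); rotatable side-chain donors without a placeable
hydrogen fall back to the donor-antecedent angle criterion. Non-bonded
contacts are cross-partition heavy-atom pairs within 3.9 Å not already
counted as hydrogen bonds. Main/side classification: N, CA, C, O (and
their hydrogens) are main chain; CB and beyond are side chain. Agreement
with HBPLUS/NACCESS is property-level, not numeric.

*Averaging.* O_ij = (1/N_f) Σ_α Σ_f o_ij^{αf}, where N_f counts the
frames in which amino acid i actually occupies position j (random
libraries place each amino acid at each position in a subset of runs).
Per-position summaries average O_ij over amino acids; "normalized"
values are min–max scaled per observable across the eight positions,
with raw averages always retained. In-complex accessibility only is
used; no isolated-peptide reference state is subtracted.

*Correlation.* Per structure, Spearman's rho (average ranks on ties)
between an observable's eight per-position averages and the entropy
profile H(j); the reported number is the mean over structures.
Structures with a constant profile have undefined rho and are dropped
with a warning rather than zero-filled.

## Cleavage entropy

H(j) = −Σ_i n_ij log₂₀ n_ij with 0·log 0 := 0 by continuity;
H_cleavage = Σ_j H(j) ∈ [0, 8]. Matrix input is a delimited 20 × 8 table
(rows = one-letter amino acids, columns P4…P4′); counts are converted to
fractions by column totals, with counts-vs-fractions auto-detected from
column sums (≈1 ⇒ fractions) and overridable. Ambiguous letters (B, Z,
X) are rejected; zero-total columns are an error.

## Fixtures

The toy complex is an ideal-geometry β-groove: an extended peptide
(φ = −139°, ψ = 135°) flanked by two parallel copies of the same strand
offset ±5 Å perpendicular to the chain axis, shifted one residue so
strand residue i+1 faces peptide residue i. Catalytic residues are the
strand residues facing P1 and P1′ (closest atoms ≈ 4.7–5 Å from the
scissile bond midpoint). A "deep S1" option adds an open-ended cage of
carbon atoms around the P1 side-chain direction — rings wide enough
(radius 5.2 Å) to admit any natural side chain — plus two
oxyanion-hole-like carbonyl-carbon probes 3.2 Å from the P1 backbone N
and O, placed in open groove space. Together these make P1 the most
buried position and give it a sequence-independent favourable interface
energy, emulating the burial signature of a real S1 pocket. A
blocked-prime-side option fills the prime-side extension region with a
dense atom grid so reconstruction must fail. Ground-truth pocket
membership is computed at construction by a brute-force double loop,
independent of the annotation module's KD-tree path. Fixtures are
bit-identical per seed.

What fixtures do *not* model: real protease folds, solvent, metal sites,
realistic B-factors or crystal contacts. Passing tests on them
demonstrates that the contracts (filters, cutoffs, projections, samplers,
averages) behave as specified, not that the energy model reproduces
experimental energetics on real complexes.

## Problem sizes and determinism

The shipped tests and the acceptance script run at desk scale: the
fixture groove (~200 atoms), libraries of 2–8 peptides for threading
checks (20 000 sequences for the uniformity statistics, where only
strings are generated), 100–5000 Monte Carlo steps, and single-structure
pipelines with libraries of 2–4 and 200 steps. These sizes were chosen
so each property is measured where it is statistically meaningful while
the whole suite stays interactive. Every stochastic component takes an
explicit seed; pipeline outputs are byte-identical across reruns of the
same configuration.

## Known limitations

- The energy model is a minimal comparative score; absolute values and
  acceptance rates do not transfer to Rosetta-like scales.
- Homology projection assumes a single dominant protease chain per
  complex; multi-chain catalytic machinery (e.g. heterodimeric sites)
  is approximated by the longest chain.
- Side-chain construction uses one rotamer per residue plus grid
  relaxation, not a rotamer library; buried mutations in real, tightly
  packed proteins will occasionally keep small residual clashes, which
  the clash report surfaces.
- Metalloproteases are out of scope (no metal-aware energetics or
  annotation), as are explicit solvent and external refinement engines;
  hooks exist for plugging the latter in.
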