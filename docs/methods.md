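# Methods

This note documents the models, conventions and numerical choices behind
`p4ring`, what the synthetic generators do and do not emulate, and the
known limitations.

## Structure model

Structures are held as a plain chain → residue → atom hierarchy parsed
with gemmi (PDB, and mmCIF read-only). Author residue numbering is
authoritative and never renumbered, because functional residues in this
protein family are cited by author numbers (catalytic lysines, arginine
fingers, C-terminal serines); residue ranges are inclusive. Of
alternate-location duplicates only the highest-occupancy conformer is
kept, with ties broken alphabetically by altloc — a deterministic rule
that never drops a residue and never increases the atom count. Waters and
non-polymer heteroatoms are retained but flagged so each stage can exclude
them by policy; hydrogens are kept when present. Only model 1 of
multi-model files is read, and no biological-assembly generation from
symmetry operators is attempted: the pipeline measures whatever chains the
file contains. PDB writing is fixed-column; coordinates round-trip within
the 10⁻³ Å column precision, and the B-factor writer refuses values that
do not fit the 6-character field.

## Superposition and core trimming

The engine is the Kabsch SVD solution for the weighted least-squares
proper rotation (reflections corrected by flipping the smallest singular
direction). Inputs with fewer than 3 points, or whose second singular
value vanishes (collinear/coincident points), are rejected because the
rotation is not unique.

Core refinement starts from a seed alignment — rank-order pairing for
synthetic fixtures, or global sequence alignment (BLOSUM62, gap open −11 /
extend −1, non-gap columns kept) for real proteins — and iterates
superposition with trimming. The equivalence rule is a hard CA–CA distance
cutoff, default 3.8 Å (one CA–CA bond length): deterministic and directly
testable, in contrast to probabilistic-weighting schemes whose parameters
are not reproducible from the literature we target. Because a hard cutoff
applied from a poor all-pair start can empty the core on a compromise
transform, refinement runs in two regimes: while the worst core pair
exceeds the cutoff, the worst decile of core pairs is dropped per
iteration (standard outlier rejection); once all core pairs fit, any pair
of the full alignment within the cutoff is re-admitted. The fixed point is
exactly "core = pairs within the cutoff under the core superposition".
Iteration is capped at 50 (convergence is typically < 10); a core below 3
pairs raises "no structurally conserved core".

Reported quantities: core RMSD; all-pair RMSD; n_eq; the fraction
equivalenced n_eq / n_min (n_min = size of the smaller input); and percent
identity computed over core pairs only — this is *structure-based*
identity, the statistic that stays meaningful at ~10% sequence identity.
Side-chain measurements (e.g. how far an arginine finger sits from its
equivalent) apply the core transform to the named atom and report the
Euclidean distance.

## Distance matrix and tree

The default structural distance is d = RMSD_core · n_min / n_eq, an
SAS-like penalized RMSD: zero iff the structures are identical and fully
equivalenced, and growing both with divergence of the core and with loss
of alignable residues. The historical evolutionary-distance functional
used with older superposition programs is not published in a reproducible
form, so the metric here is pluggable (`metric=` argument, name recorded
in output metadata) and comparisons to published trees are made at clade
level only, never branch-for-branch. Both directions of each pair are
computed and averaged, which symmetrizes the small direction dependence of
core trimming (empirically < 10⁻⁶ on noise-perturbed pairs, but not
guaranteed).

Neighbor joining is implemented in the package to pin two behaviours the
surrounding tests rely on: ties in the Q-criterion break deterministically
by label order, and negative branch-length estimates are clamped to zero
with the clamped total recorded on the tree (`clamped_deficit`) and
logged. NJ is exact on additive matrices; that exactness — against
matrices generated from known random trees — is the main oracle, and an
independent library implementation is used as a cross-check in the tests.
The triangle inequality is *not* asserted for the penalized-RMSD metric
(it does not hold in general). Trees are unrooted (degree-3 root node);
Newick serialization uses 6 significant digits.

## Interfaces and polar-contact density

SASA is Shrake–Rupley: per atom, quasi-uniform sphere points (golden
spiral, default 960) at radius r_vdW + probe (probe 1.4 Å, a water) are
tested against all neighbouring expanded spheres. Radii are the Bondi
(1964) set, shipped with the package; the table name travels in every
result because area numbers are meaningless without the radius
convention. Hydrogens and waters are excluded from surface and occlusion.
The sampler reproduces the closed-form isolated sphere to < 1% and the
analytic two-sphere case to < 2% at 960 points, and doubling the point
count changes ring totals by < 1%.

Buried area is BSA = (SASA(A) + SASA(B) − SASA(AB)) / 2, per-side average,
with all other chains removed first. Halving makes the value read as "the
size of the interface"; the unhalved variant is available via `halved=False`
since published conventions vary and are often unstated.

Contacts are heavy-atom only with inclusive cutoffs — crystal structures
at working resolution carry no hydrogens, so no donor–H–acceptor angle
term is used. Hydrogen bond: donor heavy atom to acceptor heavy atom
≤ 3.5 Å, with donor/acceptor typing from standard amino-acid chemistry
(backbone N always donor, backbone O always acceptor). Salt bridge:
Lys NZ / Arg NE,NH* / His ND1,NE2 to Asp OD* / Glu OE* ≤ 4.0 Å.
Hydrophobic: apolar carbon to apolar carbon ≤ 4.5 Å, where carbons bonded
to N/O/S (and backbone C/CA) are excluded from the apolar set. Each atom
pair is reported once per kind; a pair meeting both polar criteria counts
in both inventories but once in the polar numerator.

The stability statistic is polar-contact density = (unique H-bond ∪
salt-bridge pairs) / BSA, per Å². For rings, all adjacent chain pairs are
reported individually and as a mean. Published densities for this protein
family span an order of magnitude (0.016–0.15 per Å²) and the counting
convention behind them is not stated; all conventions here (halved or full
BSA, per-pair or per-ring) are explicit and configurable, and any
comparison must quote them.

## Channel geometry

The symmetry axis is the principal CA-inertia eigenvector most separated
from the other two; a flat ring has two nearly equal in-plane moments and
one distinct axial moment. When the inertia spread is below 10% of the
mean eigenvalue the structure is near-spherical, no unique axis exists,
and the caller must supply one. The axis sign is fixed toward +z of the
file frame for reproducibility.

The pore profile samples heights z along the axis (step 1 Å) and takes,
over atoms within a ±2 Å slab, the minimum of (distance from axis −
r_vdW), clamped at zero. This deterministic min-distance convention — the
vdW surface at the constriction — is the most conservative reading of a
channel "size"; atom-centre conventions give larger numbers, so the
convention string is attached to every profile and metric. Channel
diameter = 2 × minimum valid pore radius; external diameter = 2 × max of
(axis distance + r_vdW). Waters and heteroatoms are excluded (the channel
is defined by protein); empty slabs report a flagged ceiling, never a
silent zero. Deleting atoms can only widen the profile — the mechanism by
which truncating a channel-plugging C-terminal arm more than doubles a
pore — and this monotonicity is asserted as a property test.

## HDX mapping

Each residue covered by at least one peptide receives the arithmetic mean
of the covering peptides' rates, with inclusive peptide boundaries.
Uncovered residues are absent from the map — never defaulted to zero,
because a zero is a valid (slow-exchange) measurement. Two deliberate
simplifications are exposed as such: the mean is not length-weighted, and
the N-terminal residue of each peptide is included although common HDX
practice excludes it (no back-exchange model is applied; upstream
rate-fitting is out of scope). Ordinal classes are equal-width bins
between observed extremes on a linear or log scale, class 0 slowest; with
all rates equal everything is class 0. Condition differences (b − a) are
defined only where both conditions cover a residue, with the smaller
coverage count. Maps can be painted into the PDB B-factor column, which
round-trips at the 0.01 column precision.

## Synthetic data: what it does and does not show

Generators are deterministic under a fixed seed and emit their ground
truth alongside the fixture. Rings place a subunit template every 360°/n
about an arbitrary axis at a chosen radius; templates are single-radius
carbon pseudo-atoms (vdW 1.7 Å) so geometry oracles are closed-form. CA
traces use α-helix geometry (~3.8 Å spacing) with 1 Å Gaussian jitter —
the jitter breaks the helix's screw self-similarity so superpositions have
a unique optimum. The planted two-domain fixture moves its second domain
rigidly (90° rotation about the domain centroid plus a 20 Å shift);
translation alone would leave the displaced domain an exact alternative
superposition target and make the recovery test ambiguous. Perturbation
noise is i.i.d. Gaussian per Cartesian coordinate, the simplest model with
a known expectation (post-superposition RMSD → σ√3), verified by Monte
Carlo over 20 seeds within 10%.

None of this simulates real protein stereochemistry, packing or
Ramachandran validity. Passing tests therefore demonstrate the
*correctness of the measurements* (superposition optimality, exact tree
recovery, analytic areas and radii, averaging rules), not the biological
accuracy of any particular published number. The replication workflow in
`p4ring.replicate` runs the same measurements on the deposited P4 crystal
structures when those files are available locally (they are ~1 MB each and
are not shipped); its checks — N-terminal core RMSD ≈ 2.1 Å, core
identities in the 9–21% band, interface areas ~1500–1900 Å², the polar
density stability ordering, channel diameters of 13 vs 30 Å, external
diameter ~100 Å, and family monophyly against RecA-type relatives — are
tolerant to the stated convention choices and residue-span defaults, which
are configurable because the original spans are only partially published.

## Problem sizes and defaults

Test and acceptance runs use deliberately small problems — 40–100-residue
CA traces, 6-subunit rings of ≤ 70 pseudo-atoms, 5–10-leaf trees, 960
sphere points — chosen so every oracle is exact or analytic and the whole
suite completes in seconds on one CPU. Defaults elsewhere: trim cutoff
3.8 Å, max 50 iterations; probe 1.4 Å, 960 points; channel step 1 Å, slab
half-width 2 Å; 5 HDX classes, linear scale.

## Known limitations

- No flexible alignment, TM-score, or circular-permutation detection; the
  core model is purely rigid.
- The structural distance is not guaranteed metric (no triangle
  inequality); trees built from it are descriptive, not statistically
  supported (no bootstrap — there is no resampling unit for a single
  structure pair).
- Contact typing is table-driven on standard residues; modified residues
  other than MSE are treated as generic (backbone-only polarity).
- SASA is O(atoms × neighbours × points) in pure numpy; adequate for
  hexamers, not for very large assemblies.
- HDX handling starts from peptide-level rates; uptake-curve fitting,
  back-exchange correction and mass-spectral processing are out of scope.
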