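# Methods

This note records the models, parameter choices and known limits of the
package, in the order of the pipeline. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Structural data model and I/O

Structures are held as Assembly → Chain → Residue → heavy Atom, in Å, in
the right-handed frame as stored. On reading PDB files only ATOM records
of one model are kept; waters, hydrogens and losing altlocs (ties go to
the first in file) are dropped, and residues are renumbered 1..N per
chain with the author numbering retained in a provenance map. All scores
are defined over heavy atoms. The writers round-trip chain ids, residue
numbers/names, atom names and coordinates at the PDB's 3-decimal
precision, and the B-factor column is used to carry per-residue quality
scores on output. mmCIF, ligands, nucleic acids and symmetry expansion
are out of scope.

## Template store

Templates are user-supplied assemblies annotated with oligomeric state
(monomer / homo- / hetero-oligomer from exact sequence identity of the
chains) and a distinct-sequence stoichiometry string (A2, A1B1, …).
Target–template alignment is global Needleman–Wunsch with affine gaps
(BLOSUM62, open −11, extend −1), delegated to Biopython's
`PairwiseAligner`; determinism comes from always taking its first
optimal traceback, and a property test checks score optimality against
exhaustive alignment enumeration on short sequences. Identity is counted
over aligned non-gap columns; coverage over the full target length.

GMQE is a transparent surrogate with the monotone form

    gmqe_pre = mean over target chains of coverage · (0.2 + 0.8 · identity),

blended 50/50 with the normalised statistical-potential score after
model building and clamped to [0, 1]. The coefficients are configuration
values, chosen so that identity 1/coverage 1 maps to 1 and so that
coverage dominates at low identity; the estimate's role is ranking, not
calibration against any external accuracy scale. Chain mapping for
oligomers is greedy on alignment score in two phases (every target
claims one chain before any target claims a second), each template chain
used at most once; a target below 30 % identity to every chain is a
hard mapping failure.

## Modelling engine

**Transfer.** For every aligned column the backbone N/CA/C/O is copied;
CB is copied or rebuilt from ideal internal coordinates (τ(C-N-CA-CB) =
122.5°, matching the L-configuration) unless the target residue is
glycine; the full side chain is copied only when the identity is
conserved, otherwise the position joins the rebuild set. Template
positions lacking a complete backbone are demoted to unaligned with a
log message. Unaligned target runs become gap records; a pure deletion
(adjacent targets mapping to non-adjacent template residues) is a span-0
record.

**Fragment database.** Sliding windows of span + 2×3 backbone-complete
residues with peptide C–N in [1.1, 1.6] Å, indexed by span (1–12). A
36×36 φ/ψ frequency table is estimated from the database itself
(pseudocount 1); without a database a built-in table with helical,
extended and left-handed basins is used.

**Gap closure.** Fragment candidates must superpose their 2×3-residue
stems onto the model anchors within 0.7 Å RMSD and are scored by
1.0·stem_RMSD + 0.2·clash_count + 0.1·torsion_neg_log; the best span
backbone is grafted and the junction peptide bonds checked. On failure,
Monte-Carlo closure rebuilds the span residue by residue with ideal bond
geometry from φ/ψ proposals drawn from the Ramachandran table,
Metropolis-accepted on closure deviation (anchor C–N length plus 0.01
per degree of approach-angle mismatch) plus 0.5 per clash, 2000
iterations, T₀ = 2.0, cooling 0.995; success means the anchor C–N falls
in 1.33 ± 0.25 Å. Insertions whose anchors are nearly bonded in the
template (no room for the span) are retried once with the gap widened by
two residues per side. Terminal spans are built by ideal-geometry
extension. Deletions are rejoined as widened span-2 gaps. The stem
length, RMSD cutoff and candidate count have no external reference
values; they were fixed once for determinism and desk-scale speed and
are configuration-exposed.

**Side-chain packing.** Rotamer self-energy −3·ln p(r|φ,ψ) plus a
repulsive overlap with fixed atoms; pairwise energy is the same overlap
between rotamer atom sets: 0 beyond the vdW-radius sum, ramping linearly
to 10 at 0.8× the sum. Atoms of the same residue and backbone atoms of
sequence-adjacent residues are excluded from the clash terms (they are
constrained by bonded terms instead). The solver runs Goldstein-singles
dead-end elimination, then exact branch-and-bound (admissible bound:
assigned cost + per-position minima against the assigned set + minimum
pair energies among the unassigned) when the residual space is ≤ 10⁶
states, else seeded simulated annealing with a logged non-exact flag.
Side-chain geometry beyond CB comes from a per-residue-type internal-
coordinate table with canonical bond lengths/angles; rings are placed
with fixed torsions and proline with a fixed approximate pucker. The
shipped rotamer library is a toy generator (staggered −60/60/180 chis
with seeded jitter, probabilities normalised per bin); the TSV format
(restype, phi_bin, psi_bin, chi1..chi4, prob) lets users load a real
backbone-dependent library instead.

**Relaxation.** Steepest descent with a backtracking line search
(energy provably non-increasing) on bond-length harmonics (ideal values,
k = 100), backbone bond-angle harmonics (k = 20) and the repulsion
above, uncapped below 0.8·Rsum so a restoring gradient exists at any
overlap. The repulsion onset is scaled by 0.85 so that hydrogen-bond-
range backbone N–O contacts (≈ 2.9 Å in an α-helix) are not penalised —
without this allowance the potential, which has no attractive term,
would inflate regular secondary structure. Termination at 200 steps or
gradient ∞-norm < 10⁻³. The ideal-geometry helix fixture sits at the
minimum of this potential by construction, which is what makes the
self-modelling round trip exact to < 0.05 Å.

**Determinism.** One integer seed drives every stochastic stage
(per-gap Monte-Carlo seeds are derived arithmetically from it); the same
inputs, configuration and seed reproduce models and reports
byte-identically.

## Quality estimation

**lDDT** follows the standard definition: reference heavy-atom pairs
within R₀ = 15 Å, excluding intra-residue pairs, checked at thresholds
0.5/1/2/4 Å; the global score (0–100) averages the preserved fraction
over thresholds, per-residue scores restrict to pairs involving the
residue, and atoms missing from the model count as non-preserved — an
explicit choice that penalises incompleteness. Model/reference residue
correspondence is by (chain, number) after normalisation, with a
sequence-alignment-based matcher for mismatched constructs.

**QS-score** defaults to the Jaccard overlap of inter-chain residue
contact sets (minimum heavy-atom distance < 5 Å) under a supplied chain
mapping or the best over all chain bijections (≤ 6 chains); a
distance-weighted variant (weight 1 below 5 Å decaying linearly to 0 at
12 Å, min-weight intersection over sum of max weights) is available by
flag. The plain contact-overlap reading is the package's default
because it is exactly testable by set arithmetic.

**Statistical potential.** CB–CB (CA for glycine) distances in 0.5 Å
bins over 3–15 Å; score −ln((obs + 1)/(exp + 1)) with the expectation
from the type-marginalised distance distribution. The global "raw"
score of a model is the mean over scored pairs; qmean_norm squashes it
through a logistic centred on the reference-set mean, and the Z-score is
(expected_raw(length) − raw)/sd(length) over 20-residue length bins, so
better-than-expected models score positive. The reference set is
whatever the user trains on; the fixtures provide a synthetic family of
helices with a periodic sequence pattern, which gives the potential a
learnable type-pair/distance signal — passing the decoy tests shows the
machinery discriminates, not that the toy potential transfers to real
proteins.

**DisCo.** For each residue pair mapped into at least one template with
a reference distance < 15 Å, the constraint is the mean ± spread of
template distances; pair agreement is max(0, 1 − |d_model − mean| /
max(4·spread, 2 Å)) and a residue's score averages its constrained
pairs. Residues with no constraints are absent from the result (flagged
by omission), never scored zero. The functional form is this package's
own declared choice; the 2 Å floor keeps single-template ensembles
(spread 0) usable.

## Interface analysis

Residue classes: interface = any heavy atom within 5 Å of another
chain; otherwise surface if the relative accessibility of the isolated
chain (Shrake–Rupley via biotite, probe 1.4 Å, 960 points, normalised by
Gly-X-Gly theoretical maxima) is ≥ 0.25, else core. Column entropy is
Shannon entropy in bits over the 20 standard residues, gaps excluded,
all-gap columns undefined. The fingerprint bins homologues by global
pairwise identity to the target (edges 20/30/40/50/60/70/80/100 %, a bin
needs ≥ 5 sequences), computes mean interface and surface entropy per
bin on the bin's sub-alignment (target row always included) and reports
r = ln(H_int + 0.05) − ln(H_surf + 0.05); the ε-regularised log-ratio
makes "below zero" literal and division by zero impossible. The
interface call uses the mean r over populated bins below 40 % identity:
below −0.1 → biological, otherwise crystal-contact, no populated remote
bins → indeterminate; confidence is tanh(|mean r|/0.1). QSQE is a
logistic in (−mean remote r, ln(1 + contacts), interface identity,
coverage) with default coefficients (−2.0, 1.5, 0.3, 2.0, 1.0) and an
optional logistic-regression fit against user-labelled examples — a
deliberately transparent stand-in for a trained classifier, carrying the
same monotonicities (more conservation, more contacts, higher identity
and coverage never lower the estimate).

Two readings the analysis fixes where the concept allows several: the
entropy comparison is mean-per-class (not a distribution test), and
evolutionary distance is global identity to the target (not
alignment-local identity).

## Synthetic data: what it does and does not show

The fixtures emulate the *contracts* of the pipeline, not real proteins:
ideal-geometry helices (φ = −57°, ψ = −47°, standard bond values), toy
dimers whose interface is planted by a pose search and verified by an
independent distance scan, MSAs generated by per-row exact mutation
counts with the interface mutation rate solved (by bisection on the
column-entropy model) to sit `delta` bits below the surface rate, and
packing problems with enumerated optima. Fixture sizes in the tests
(10–30 residues, 50 loop problems, 50 MSAs of 120 columns × 61 rows,
200 packing instances) were chosen as the smallest instances that make
the statistical assertions stable across seeds. Passing tests
demonstrate correctness of the algorithms on inputs with known ground
truth; they say nothing about accuracy on PDB-scale data, remote
homology, or real rotamer/contact statistics — those would require a
real template library, a published rotamer library and trained scoring
functions, all of which the formats here can accept but do not ship.

## Known limitations

- No attractive non-bonded term: the relaxation only removes clashes
  and restores ideal covalent geometry; it cannot repack or refine.
- Fragment and Monte-Carlo closure keep the anchors rigid; very tight
  insertions rely on the widening retry and may still fail (reported,
  never silent).
- The aligner is a plain global aligner; remote-homology sensitivity of
  profile methods is deliberately out of scope.
- The statistical potential is a single distance term; torsion and
  solvation terms of composite scoring functions are not implemented.
- Ring closure bonds (e.g. proline CD–N) are approximate: side-chain
  construction is tree-structured and rings are placed with fixed
  torsions.
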