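# Methods

This note documents the models, parameters and numerical choices behind
`hybridloop`, and what its synthetic-data tests do and do not demonstrate.

## Model overview and assumptions

The package predicts the backbone conformation of a single protein loop
given a fixed framework. Its central assumption is that loops of a
*different* (shorter) length than the target can carry transferable
structural information: a shorter fragment whose anchor geometry and
sequence context resemble the target's supplies internal coordinates for
the aligned residues, and the remaining residues are sampled ab initio.
The backbone is reduced to N, CA, C, O and Cβ heavy atoms; hydrogens,
side chains beyond Cβ, alternate conformations (beyond highest-occupancy
selection) and cis peptide bonds are not modelled. The peptide ω torsion
is fixed at 180° unless copied from a fragment.

## Coordinate machinery

Atoms are placed by natural-extension-reference-frame (NeRF) construction
from three predecessors plus (bond, angle, dihedral); dihedrals follow the
IUPAC sign convention in degrees, canonicalized to [−180, 180). A chain
break is declared where C(i)–N(i+1) exceeds 2.0 Å. Superposition uses the
Kabsch SVD solution with a determinant correction; loop RMSD superposes
framework N/CA/C atoms only and measures loop atoms (N, CA, C, O for the
backbone convention; C, O for the carbonyl convention used in antibody
assessment, optionally restricted to the 95–100x sub-span).

Each fragment stores, per residue, the nine internal coordinates needed to
regrow it in either direction (φ, ψ, ω and the six junction/intra-residue
bonds and angles), plus the ψ of the preceding and φ of the following
source residue. Reconstruction from these values reproduces the source
Cartesian backbone to well under 0.01 Å, which the tests verify; windows
at a record's edge lack some of these values and the builder falls back to
sampling for exactly those fields.

## Secondary structure and loop extraction

To keep the artifact self-contained the DSSP step is replaced by a
dihedral-window assignment: H for φ ∈ [−100, −30], ψ ∈ [−80, −5]; E for
φ ∈ [−170, −70], ψ ∈ [90, 180) ∪ [−180, −170); C otherwise, with H/E runs
shorter than three residues smoothed to C. Loops are maximal coil runs of
at least three residues connecting H/E elements of at least three
residues, stored with three flanking residues per side. A fragment's
anchor signature (four Cα–Cα cross distances) needs two residues of
context on each side within the record; edge windows therefore carry no
signature and are only retrievable with an infinite anchor tolerance.
The anchor-match statistic is the RMS of the four distance differences,
default tolerance 1.0 Å.

## ESS tables and alignment

The original environment-specific substitution tables are not
reproducible here, so the mechanism is preserved with transparent
provenance: from a corpus, residue frequencies are estimated per
Ramachandran region (α, β, αL, other), and the score for substituting
fragment residue *a* for target residue *b* in environment *e* is
ln [P(a|e)P(b|e) / (P(a)P(b))] with add-one pseudocounts plus a fixed
identity bonus (default 2.0) on the diagonal. Alignment is global
Needleman–Wunsch with a linear gap penalty (default 2.0 score units, end
gaps included) and a deterministic match > gap-in-fragment > gap-in-target
traceback. Candidates of all permitted lengths are pooled before
truncation to the budget, with ties broken by (score desc, length desc,
source id, offset).

## Ramachandran distributions

Residue-specific 36×36 histograms (10° bins) are estimated from the loop
residues of the corpus, with a pooled `ALL` fallback for unseen residue
types. Small corpora produce histograms whose support is a handful of
isolated bins, which starves both sampling and the CCD "allowed region"
constraint; histograms are therefore smoothed with a wrapped Gaussian
kernel of one bin's width, truncated at 2σ so the allowed support stays
tight to the data (a wider truncation was observed to legitimize φ ≈ 0
conformations that generate systematic O(i)···N(i+2) clashes). Sampling
draws a bin by probability and returns its center. The H3 variant blends
sparse H3 histograms with general-loop histograms as the mixture
(1−w)·H3 + w·general, default w = 0.2, which fills in empty bins while
keeping H3 preferences dominant; the original resampling procedure is not
published in detail, so this mixture is an explicit substitute.

## Building and closure

Decoys grow residue-by-residue from one anchor; a mobile copy of the far
anchor's N/CA/C (built with that anchor's own internal geometry) trails
the chain as the closure target. The dihedral that attaches the first
loop residue to the build anchor (the anchor's ψ, or φ when building from
the C side) is initialized from the anchor's carbonyl O, which fixes the
amide plane; when the anchor O is re-used after closure it is re-placed
in the plane of the realized anchor–loop peptide bond (anchor N/CA/C
never move). The carbonyl O of each loop residue is placed from ψ + 180°
after closure; Cβ is placed with ideal L-chirality geometry
(1.530 Å, 110.5°, improper C–N–CA–Cβ = −122.6°).

Closure is cyclic coordinate descent over the loop's φ/ψ torsions plus
the entry and terminal anchor torsions (framework-residue torsions, so no
Ramachandran constraint applies to those two). Each update computes the
closed-form optimal rotation, clips it to 30°, and applies it only if the
residue's new (φ, ψ) falls in a bin of probability > 10⁻⁶ in its own
distribution; because the objective decreases monotonically from zero
toward the optimal angle, half- and quarter-steps are tried when the full
step leaves the allowed region, preserving the invariant that accepted
updates never increase the objective. Success is ≤ 0.25 Å RMSD over the
three overlap atoms; runs stop at 500 sweeps, or earlier after 15
consecutive sweeps improving the objective by less than 10⁻⁷ Å² (a run
improving that slowly cannot reach tolerance in any realistic budget).
Anchors further apart than 3.8 Å × (n+1) fail immediately. The inner loop
has two interchangeable implementations — a numpy reference and a numba
kernel — verified update-for-update identical by a test; the kernel is
used when numba is importable.

Clashes are any non-exempt pair of heavy atoms (backbone + Cβ) closer
than 2.5 Å, between a loop atom and any framework or non-adjacent loop
atom; pairs within two covalent bonds are exempt. Closure failures and
clash failures count against the same per-fragment cut-off of 3000, and
each failure flips the build anchor for the next attempt.

## Decoy selection

The potential types atoms as pooled backbone N/CA/C/O plus Cβ split by
residue chemical class (hydrophobic AVLIMF, polar STNQYCW, charged DEKRH,
other P); a fully residue-specific alphabet is available by
configuration. Counts are accumulated over pairs with at least one loop
atom and distance < 8 Å, excluding pairs within two bonds, into six bins
([0,3) plus five 1 Å bins), smoothed with one pseudocount per bin. A
decoy's energy is −Σ ln [P(bin|pair)/P(bin)]; pairs with atom types
absent from the table contribute zero and are logged. Selection sorts
ascending by energy with decoy-id tie-breaks (deterministic and
idempotent) and truncates to 500. Glycine contributes no Cβ and no
virtual atom is constructed. External stages (side-chain addition,
minimization, final ranking) are command-template hooks that default to
identity; a failed command logs a warning and passes the set through.

## Orchestration and reproducibility

A master seed drives everything; each fragment's decoy generation uses a
child generator derived from (seed, fragment index), so per-fragment
results do not depend on processing order, and end-to-end runs with the
same seed, database and configuration produce byte-identical output
files. When selection returns no fragments — or no fragment yields a
single decoy — the pure ab initio branch generates the configured total
(by default the budget formula's fragment count × 100) so a prediction is
always returned. Structured per-stage counters (attempts, closure
failures, clash failures) make the 3000-cut-off behaviour auditable in
the run report.

## Synthetic data: what it shows and what it does not

The fixture generator builds ideal-geometry helix–loop–helix proteins:
canonical helices, Engh–Huber mean bonds/angles, trans ω, and loop
dihedrals drawn from four coil basins with ±15° jitter,
rejection-sampled until the whole protein is clash-free. Corpora of such
fixtures feed the database, distribution, ESS and potential builders in
tests and in the acceptance script. These fixtures exercise every code
path with a known ground truth, but they are idealized: real loops have
heterogeneous bond geometry, cis prolines, non-canonical flanks, solvent
and crystal contacts, and far more diverse (φ, ψ) usage. Passing the
synthetic recovery tests therefore demonstrates the machinery —
fragment-guided sampling concentrates decoys near a known native and the
ranking recovers it — not benchmark-level accuracy on experimental
structures, which additionally depends on the size and curation of the
fragment database and on external refinement stages that are out of
scope here.

Problem sizes in the tests and the acceptance script (12-protein corpora,
8-residue targets, 30 decoys per branch, 10 seeds, 300–500 closure
trials) are chosen as the smallest sets that give stable statistics for
the properties being checked.

## Known limitations

* Backbone-only modelling; no side-chain packing or refinement is
  performed internally (hooks exist for external tools).
* The ESS tables and Ramachandran distributions are only as good as the
  corpus they are estimated from; the shipped builders assume a corpus of
  single-model PDB files.
* CCD with Ramachandran constraints can stall on highly extended targets
  (span near the theoretical maximum), where most closed conformations
  also clash; such targets consume their failure budget and may return
  few decoys.
* The H3 mixture weight and the identity bonus in the ESS estimate are
  pragmatic defaults, not fitted quantities.
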