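# Methods

`idpcircuit` analyses conformational ensembles of intrinsically disordered
protein (IDP) chains and two-chain docking pose sets.  It was built around a
concrete system — the androgen receptor N-terminal transactivation domain
(AR-NTD, 538 residues) in its wild-type (23-glutamine) and disease-associated
expanded (45-glutamine) forms — but every operation is generic over chains,
ensembles and pose sets.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do not
establish.

## Sequence frames and the numbering lift

The wild-type NTD numbering coincides with the UniProt frame.  Expanding the
polyglutamine (pQ) tract from 23 to 45 residues shifts everything C-terminal
of the tract by +22.  The lift between frames is the identity up to the tract
insertion point and adds the tract-length difference beyond it; indices
strictly inside the expanded tract interior have no unambiguous preimage and
raise an error rather than guess.  The canonical anchor is the ANTS motif
(KELCKAVSVSM): residues 233–246 in the wild-type/UniProt frame, 255–268 in
the 45Q frame.

The tract's own coordinates are configuration, not hard-coded knowledge: the
default (58, 80) follows the UniProt P10275 polyQ annotation.  Motif defaults
(FQNLF 23–27, Tau-5 361–490, P-box 577–581 on the partner DBD chain) are
likewise config-only.  Whether extra glutamines insert mid-tract or at the
tract C-terminus is observationally equivalent for every residue outside the
tract; the choice is exposed as a switch (`insert_at`) and defaults to the
C-terminus.

The bundled reference construct (`wt_synthetic_construct`) is a synthetic
stand-in: an alanine background with the Q tract planted at the annotated
coordinates.  All downstream analyses consume only numbering and tract
layout, so no result in this package depends on the real side-chain
chemistry of the sequence.

## Residue contacts

Two residues are in contact when at least `min_atom_pairs` (default 5)
atom–atom pairs lie within `cutoff` (default 4.5 Å) and the pair is farther
apart in sequence than the exclusion window (|i−j| > 3 by default).  The
default reading counts atom *pairs* across the residue pair; a stricter
reading (≥5 distinct atoms participating on *each* side) is available as
`strict_per_side` and is off by default.  Distances are Euclidean over all
heavy atoms; hydrogens participate only if present in the input.  Single-bead
(Cα-only) input cannot satisfy a multi-pair criterion and raises an explicit
incompatibility error instead of silently returning nothing — callers lower
`min_atom_pairs` for coarse-grained data.

Inter-region contact time (e.g. NR 1–224 vs CR 225–538) is the fraction of
frames with at least one cross-group contact, computed per replicate; the
headline value is the mean with the population standard deviation over
replicates (appropriate for the typical n = 3 independent simulations).

## Circuit topology

Circuit topology classifies every unordered pair of contacts by interval
arithmetic on their sequence spans: series (disjoint), parallel (nested; the
enclosed member is *inverse parallel* to the enclosing one), cross
(interleaved).  Contacts sharing a residue need deterministic tie rules to
keep the three counts a partition of C(m, 2); we use closed-interval
containment: nesting with a shared boundary counts as parallel, and
intervals touching end-to-start count as series.

Three observables are derived per frame:

* the census (n_S, n_P, n_X), with n_P counted once per unordered pair;
* the per-residue inverse-parallel profile: for each residue, the sum over
  its incident contacts of the number of contacts enclosing them (an
  alternative mean-per-incident-contact aggregation is selectable); the
  profile is reported as mean ± SEM over sampled frames, pooled across
  replicates before the SEM.  The SEM uses the population standard
  deviation, which keeps the frame-duplication invariant (SEM scales by
  1/√2) exact;
* the configuration-space density: a normalised 2-D histogram of
  (n_S, n_P + n_X), one point per sampled frame, aggregated over replicates.

Frames are sampled at a configurable time stride (25 ns in the motivating
analyses); requesting a stride finer than the frame spacing is an error.
Energy/length filtering of contacts and circuit decomposition are known
extension points in the literature but are deliberately not implemented:
no defensible default parameters exist, and a wrong silent filter is worse
than none.

## Ensemble metrics

**Superposition** is least-squares rigid alignment over proper rotations
(Kabsch, via `scipy`'s `Rotation.align_vectors`); mirror images are not
matched.  RMSD/RMSF are reported in nm while coordinates are handled in Å
(the PDB unit).

**RMSF** superposes every frame onto an iteratively refined mean structure
(Cα selection by default) and reports the root-mean-square deviation about
the mean.  On synthetic ensembles whose per-residue displacements are
isotropic Gaussian with per-axis scale σ, the expected RMSF is σ√3; recovery
within 5 % requires enough residues that removing six rigid-body degrees of
freedom is negligible (the verification uses 100 residues × 2000 frames).

**Secondary structure** is assigned by an explicit dihedral criterion rather
than an external assigner: a residue qualifies when its defined backbone
dihedrals fall in the α-basin (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]) and
helices are maximal runs of ≥4 qualifying residues; chain termini join a run
through their single defined dihedral.  A Cα-only fallback uses P-SEA-style
distance windows (d(i,i+3) ∈ [4.8, 5.6] Å, d(i,i+4) ∈ [5.9, 6.9] Å, runs of
≥5).  Absolute helical contents are method-dependent; comparisons should
hold the assigner fixed.  Overall helical content is the mean helix
indicator over residues and frames, in percent, computed per replicate, with
population-STD dispersion; residues with helix probability > 0.30 form the
"stably helical" set.

**Clustering** is the iterative neighbor-count (GROMOS) algorithm under a
pairwise Cα RMSD cutoff (default 0.9 nm): the frame with the most neighbors
within the cutoff becomes a center, it and its neighbors are removed, and
the procedure repeats.  Ties break toward the lowest frame index, making the
result deterministic; mass-weighting is off.  Representatives are the
centers of the smallest size-ordered cluster prefix whose cumulative
membership reaches the coverage fraction (default 50 %).

## Pose analysis

Poses are single-frame, two-chain structures.  Interface residues reuse the
contact engine across chains (sequence exclusion does not apply).
Interaction typing uses standard fingerprinting geometry, all configurable:
hydrogen bond — donor/acceptor heavy atoms ≤ 3.5 Å (D–H⋯A ≥ 120° when
hydrogens exist); salt bridge — cationic N (Lys NZ, Arg NE/NH*, protonated
His N) to anionic O (Asp OD*, Glu OE*, OXT) ≤ 4.0 Å; π-cation — ring
centroid to cationic N ≤ 6.0 Å within 45° of the ring normal; π-stacking —
centroids ≤ 5.5 Å with inter-plane angle ≤ 30° (parallel) or ≥ 60°
(T-shaped).  A residue pair yields one record per satisfied type, so a
close Lys–Glu pair can legitimately be both salt bridge and hydrogen bond.

A pose binds through region NR (resp. CR) when at least a dominance fraction
(default 0.8) of its NTD-side interface residues lie in that region, else it
is dual; fractions are over poses with non-empty interfaces.  A motif is
*blocked* when at least `blocked_fraction` (default 0.5) of its residues are
interface residues (an any-contact mode exists for very short motifs such as
the 5-residue P-box), *partially involved* when at least one but fewer, and
*exposed* when none are and the motif's mean relative SASA in the complex
reaches 0.25 — a stated operational proxy; a motif with no interface overlap
but low SASA is reported as buried within its own chain rather than
miscalled exposed.

**SASA** is classic Shrake–Rupley sphere sampling (probe 1.4 Å, 960 points
per atom on a golden-spiral lattice), with van der Waals radii C 1.70 /
N 1.55 / O 1.52 / S 1.80 / H 1.20 Å and a configurable fallback for exotic
elements.  Relative SASA normalises each residue by its Gly-X-Gly maximum
(theoretical values of Tien et al. 2013).  Complexation can only remove
accessible area, and that monotonicity is asserted in tests per chain.

## Synthetic fixtures: what they establish

Generators plant a known property, then re-check it with the package's own
analysis before returning (verify-and-retry, at most 20 fresh seeds, then a
hard error; exact distance-geometry embedding is deliberately not attempted).
Fixture families:

* torsion-built backbones (ideal α-helix at φ=−57°, ψ=−47°; extended chains;
  labelled helix/coil segments) from ideal internal coordinates via NeRF
  chain extension;
* planted-contact scaffolds: one center bead plus five pseudo side-chain
  atoms per residue (so the ≥5-pair criterion is exercised realistically),
  spring-relaxed so planted pairs sit at ~3 Å center distance and everything
  else far apart.  Residue pairs that share a planted partner cannot be
  pushed beyond twice the contact distance, so they get a weaker repulsion
  target just outside the contact window; the final contact set is verified
  to equal the planted set exactly;
* fluctuation ensembles: per-residue rigid Gaussian displacements with
  optional per-frame contact schedules (the moved residue is placed at
  contact distance in "on" frames; the schedule is verified frame by frame);
* designed dimer poses: each planted interaction occupies its own interface
  site meeting exactly its geometric window, with all non-designed
  cross-chain distances above 8 Å, verified via the interface engine.

These fixtures are geometric, not thermodynamic.  Passing tests establish
that the analysis operations are correct on inputs with known ground truth;
they do not establish anything about force fields, sampling convergence, or
the biology of any particular system.  Quantities that in the motivating
study derive from multi-microsecond trajectories and ~400-pose docking sets
(absolute helical contents, region-binding and blockade percentages of real
ensembles) are outside what desk-scale synthetic data can reproduce, and the
package makes no claim to them.

## Problem sizes and determinism

Verification workloads are sized for a single CPU: censuses are checked
against a brute-force oracle on hundreds to a thousand random maps (m ≤ 100),
contact recovery on 10–20 scaffolds of 100–300 residues, RMSF on 2000-frame
ensembles of 100 residues, SASA cross-checks at 480–960 sphere points.
Every generator is a deterministic function of its spec and seed; reports
round floats to six decimals and serialise with sorted keys, so a rerun with
the same config and seed is byte-identical.
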