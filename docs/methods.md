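# Methods

## Scope and model

apehkit analyses two-domain serine proteases of the POP family (clan SC,
family S9): an N-terminal β-propeller covering the catalytic triad of a
C-terminal α/β-hydrolase domain, joined by a ~10-residue linker. The
package treats four aspects of this architecture quantitatively —
sequence-level domain electrostatics, geometric inter-domain interactions,
a rigid-hinge model of the open/closed transition, and efficiency-corrected
transcript quantification — and couples each to a synthetic-data generator
with exact ground truth.

All residue numbering is author numbering (1-based), all region bounds are
inclusive, and all distances are in Ångström. Structures are read and
written in PDB format through gemmi; only one chain is analysed (the single
chain of a monomer, chain A otherwise, or an explicit `chain=`), altloc
'A'/blank is kept and HETATM/waters are dropped — homology models of
monomeric enzymes are the intended input.

## Charge profiles

A residue is negative if D or E, positive if H, K or R, neutral otherwise.
Histidine is counted as positive deliberately — the convention of the
comparative isoform tables this mirrors — with no pKa modelling. The net
charge of a region is positives − negatives in elementary charge units.
The protein total is summed over the N- and C-terminal domains only,
because published domain tables delimit their regions that way; a flag
(`include_linker=True`) adds the linker. Masses use average residue masses
plus one water (Bio.SeqUtils); reported at one decimal in kDa. Whether an
initiator methionine is included is the caller's choice of input sequence:
the packaged length checks use the deduced translations as given.

## Interaction detection

**Salt bridges.** A residue pair is bridged iff the minimum distance
between any acidic carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2) and any
basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) is ≤ 4.0 Å
(configurable). Granularity is one record per residue pair (the closest
atom pair), matching how totals of order 10–20 per ~700-residue protein
are tallied. His participates by default (`include_his=False` to drop).
Terminal amine/carboxylate charges are not considered: the sequence-level
tallies count side chains only.

**Hydrogen bonds.** Homology models carry no hydrogens, so the default
criterion is heavy-atom: donor–acceptor distance ≤ 3.5 Å between configured
donors (backbone N except proline; Ser/Thr/Tyr/Cys hydroxyl-or-thiol;
Asn/Gln/Lys/Arg/His/Trp side-chain N) and acceptors (backbone O/OXT;
Asp/Glu/Asn/Gln side-chain O; Ser/Thr/Tyr O; His N). Where an ideal
backbone amide H can be placed (1.0 Å from N, opposite the bisector of
C(i−1)→N and Cα→N), a D–H···A angle ≥ 90° is also required; side-chain
donors are accepted on distance alone because their H positions are
rotamer-dependent. Same-residue pairs and sequence-adjacent
backbone–backbone pairs (covalently constrained) are excluded. Each
donor–acceptor *atom* pair is reported once; a salt bridge at H-bond range
is therefore also an H-bond, which is chemically the case. A stricter
`"hbplus"` preset (D···A ≤ 3.9 Å, H···A ≤ 2.5 Å, angle ≥ 90°) mirrors the
classic defaults of that program.

Both detectors use a KD-tree; correctness is established by exact
agreement with an independent all-pairs brute-force scan on 100+ seeded
random structures (a dual-route check kept in the tests and the acceptance
script).

**Inter-domain classification.** Against a partition, an interaction is
`inter` iff one residue lies in the N-ter region and the other in the
C-ter region; anything touching the linker is `linker` and excluded from
both intra and inter tallies. Uncovered residues are an error, not a
silent skip.

## Catalytic-site environment

"Side chain" is Cβ-inclusive (glycine contributes nothing) — the common
practice where the boundary is otherwise unstated. The environment of a
triad is every side-chain atom of a non-triad residue within the cutoff
(default 3 Å) of any triad side-chain atom, reported with its minimum
distance; ties for the closest triad atom break by atom-name order.
Atom-level charge classes: carboxylate O negative, Lys/Arg/His side-chain
N positive. The summary compares the two counts; ties are `balanced`.

## Hinge rotation

The opening move is purely geometric: all atoms sequence-C-terminal to a
chosen backbone bond (N–Cα: the hinge residue from Cα onward plus all later
residues; Cα–C: the hinge carbonyl plus all later residues) rotate rigidly
about the bond axis. No energetics, no clash resolution — clashes
(inter-segment atom pairs < 2 Å, hinge-residue-internal pairs excluded) are
counted and reported only. Rotations are exact rigid motions: intra-segment
distances are preserved to < 1e−6 Å, θ then −θ is the identity, rotations
about the same bond compose additively and 360° is the identity (all
asserted in tests).

Openness metrics: (a) distance between the N-ter and C-ter region atom
centroids; (b) minimum inter-domain atom distance; (c) a site-occlusion
proxy — the count of N-ter-domain atoms within a shell (default 8 Å,
configurable) of any triad side-chain atom, lower meaning a more exposed
site; (d) the clash count. The shell radius is an artifact choice: on the
package's compact toys a wider shell (18 Å) is used in tests/examples
because the toy domains are far smaller than a real β-propeller.

**Opening propensity.** The score s = q(N-ter) × q(C-ter) formalises the
verbal electrostatic argument: like-charged domains (s > 0) repel and
favour opening, opposite charges (s < 0) attract and favour the closed
state. Proteins are ranked ascending by s, ties broken by total net
charge. The score is explicitly heuristic; with the reported isoform
charges it reproduces the closed-prone outlier (APEH-1_Ch, s = −2, ranked
lowest) and places all like-charged isoforms above it, but it does not
order APEH-2_Tb (s = 63) below APEH-2_Ch (s = 49) as the qualitative
account does — the score is reported, not forced.

## Expression analysis

Pfaffl efficiency-corrected ratio:

    R = (1 + e_target)^ΔCt_target / (1 + e_ref)^ΔCt_ref,
    ΔCt = Ct(control) − Ct(sample) per gene.

Instrument-quoted efficiencies are fractions (0 < e ≤ 1.2; e = 1 is perfect
doubling), so the amplification base is 1 + e — the classic Pfaffl E ≈ 2.
This interpretation is stated prominently because the symbol E is often
written directly as the exponent base. Replicate Cts are averaged per
(tissue, gene) *before* ΔCt is formed (the aggregation order is an
assumption; fold-of-means and mean-of-folds coincide in the noise-free
case). The fold table reports every target gene per tissue relative to a
caller-chosen control tissue, plus an optional gene/gene ratio column
(e.g. apeh-2/apeh-1). No standard-curve fitting and no differential-
expression testing are attempted.

## Synthetic data: what it emulates, what it does not

Peptides are built by sequential natural-extension (NeRF) placement from
ideal internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
standard angles; ω defaults to 180°), so re-measured dihedrals equal the
requested values to < 1e−3°. Side chains use one idealised extended
pseudo-rotamer per residue type — enough to carry the charged-group and
donor/acceptor atoms at roughly correct distances from Cα, with no rotamer
library and no claim of packing realism.

Two-domain toys are poly-alanine helices joined by a linker (extended by
default; helical for the compact, closed-state regime used in hinge
studies, selected via `linker_conformation`), the second domain rigidly
offset by `gap`. Designed contacts are realised by placing the two
qualifying side-chain atoms on the line between the carrier residues' Cβ
atoms at exactly the target distance; a built-in all-pairs feasibility scan
verifies that exactly the designed inter-domain contacts (and no
accidental ones) exist, else construction fails. Ct tables are generated
by inverting the Pfaffl relation from true folds with the reference gene
flat across tissues, plus Gaussian cycle noise; generators are
deterministic under a fixed seed and return their truth.

Consequently, passing tests demonstrate correctness of the *measurements*
(detection, classification, rotation, ratio bookkeeping) — not that the
package reproduces interaction counts of real ~700-residue propeller
folds, which depend on the specific (undeposited) models and detector
settings used to produce any published tally. The packaged reference
tables carry those reported counts as context only.

## Numerical choices and edge cases

- Dihedral sign follows the IUPAC convention, atan2((n1×n2)·b̂2, n1·n2),
  range (−180°, 180°]; coincident or collinear points raise a geometry
  error. A torsion keeps its value and sign when the four points are
  reversed, and flips sign under mirror reflection — both are asserted as
  properties.
- Ramachandran QC uses a deliberately simple, user-overridable
  rectangle-union map of core+allowed regions (broad β box, α-R box,
  bridging band, α-L box), since contour-based maps differ between tools;
  termini and chain-break flanks have no complete (φ, ψ) and are excluded
  from the fraction; fewer than one complete pair yields NaN with a
  warning.
- PDB round trips preserve coordinates to the format's 1e−3 Å precision;
  duplicate atoms within a residue keep the first occurrence with a
  warning.
- Detector boundary: criteria are ≤ comparisons; the toy generator refuses
  target distances below 2.2 Å (unphysical near-clashes that would create
  double-counted atom pairs).
- Problem sizes: the oracle-equivalence suites use 100 random structures of
  20–60 residues and the Monte-Carlo fold recovery uses 100 triplicate
  tables at 0.1-cycle noise — sizes chosen so the whole validation battery
  re-runs in seconds while exercising hundreds of contacts per class.

## Known limitations

- No mmCIF, no multi-model ensembles, no symmetry/assembly handling.
- No electrostatic energies, π-cation/aromatic interactions or
  water-mediated bonds; the propensity score is a sign-level heuristic.
- Hinge conformers are not energy-minimised and may clash; they model
  accessibility, not a feasible trajectory.
- The Ramachandran map is a QC summary, not a PROCHECK replacement.
- Efficiencies are taken as given; estimating them from dilution series is
  out of scope.
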