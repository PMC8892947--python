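# Methods

This note documents the models behind each `rnpkit` stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Sequence and structure handling

Residue and sequence numbering is 1-based (PDB convention); frame indices
are 0-based. FASTA/FASTQ parsing goes through Biopython; multi-model PDB is
the canonical ensemble format (self-contained, text, round-trippable to the
format's 0.001 Å precision) read and written through biotite, with DCD
supported as a convenience via mdtraj. Atoms are classified into exactly one
polymer class from their residue name (standard amino acids → protein;
A/C/G/U → RNA; HOH/WAT → water; MG/K/NA/CL/CA → ion; anything else → other,
with a warning). Chains are never merged.

Translation uses the standard genetic code. An IUPAC-ambiguous codon
translates to a residue only when *every* expansion encodes that residue
(GGN → G); otherwise it yields X. This avoids silently inventing residues
from ambiguous reads; peptides containing X are excluded from logos.

## Degenerate codon design

A degenerate codon is three IUPAC symbols standing for a mixture of plain
codons. `design_codon` searches all 15³ = 3,375 candidates and keeps the
feasible ones (encode every required residue; in exact mode nothing else and
no stop), minimizing, in order: number of off-target residue species, number
of stop codons in the expansion, degeneracy, and finally the IUPAC string
itself. Off-target species dominate the objective because a reduced-alphabet
library is only meaningful if positions stay inside the designed alphabet;
the lexicographic tail makes the optimum unique and the function
deterministic. When no exact cover exists the error names the best
near-miss, and `relax=True` reruns with off-targets permitted.

Library diversity multiplies per-position pool sizes (protein level) and
codon degeneracies (DNA level); `randomized_fraction` counts non-fixed
positions. `pools_from_alignment` thresholds gap-excluded column
frequencies, intersects with the design alphabet, and when the intersection
is empty fixes the position at the alphabet residue scoring highest against
the wild type under a substitution table (any 20×20 TSV; BLOSUM62 by
default). Note the fallback residue need not be the wild-type residue
itself — by construction the wild type may lie outside the design alphabet.

`data/example_scheme_synthetic.json` is a generated example (see
`synthetic_data.example_scheme`): 69 positions, 18 randomized (26%) with
size-3/4 exact-cover pools from the early alphabet, ~1.2×10¹⁰ protein
variants. It is synthetic — a realistically shaped stand-in, not any
published construct's actual randomization scheme.

## Selection analysis

Reads are processed by exact flank matching (first 5′-flank occurrence, then
the first 3′-flank occurrence after it), frame-0 translation of the excised
insert, and rejection of reads missing a flank or encoding a stop. No
quality trimming or clustering is performed; the default abundance floor is
1 (no floor). Rank-abundance ties break lexicographically so output is
deterministic.

Logos use per-position information content IC = log₂20 − H bits (H the
Shannon entropy of residue frequencies) and letter height = frequency × IC,
without small-sample correction. The default logo input is the top-100
peptides weighted uniformly; a count-weighted mode exists because read-count
weighting is equally defensible for deep rounds. Consensus calls the modal
residue where its frequency reaches the threshold, else `x`.

## Binding kinetics

The 1:1 Langmuir surface-binding model in closed form:

- association (t ≤ t_switch): R(t) = R_eq(1 − e^{−(k_on C + k_off)t}),
  R_eq = R_max C/(C + K_D);
- dissociation: R(t) = R(t_switch) e^{−k_off (t − t_switch)};
- K_D = k_off/k_on.

The closed form is verified in the tests against direct numerical
integration of dR/dt = k_on C (R_max − R) − k_off R.

Fitting is global nonlinear least squares over all curves jointly with one
shared (k_on, k_off, R_max) — the standard treatment of a dilution series.
Parameters are optimized in log space (positivity without constraints,
well-scaled steps across the ~10⁷ dynamic range between k_on and k_off) with
Levenberg–Marquardt at tight tolerances. Initialization is feature-based:
R_max ≈ 1.2× the peak response, k_off from a log-linear fit of the
dissociation tails, k_on from the apparent association rate of the
highest-concentration curve. Uncertainties come from the residual-scaled
Gauss–Newton covariance, propagated from log space by the delta method; the
K_D uncertainty combines the k_on and k_off terms (correlation neglected).
Mass-transport limitation, drift and bulk refractive-index terms are out of
scope. `round_sig` performs half-to-even significant-figure rounding after
stripping float noise, so an analytically exact half (2.25×10⁻⁹ at 2 s.f.)
rounds predictably to 2.2×10⁻⁹.

Default simulated series: three 2-fold dilutions from the top of each
variant's measured concentration range, 1 Hz sampling, 300 s association +
600 s dissociation. The dilution factor is a choice (instrument series
spacings vary); parameter recovery is insensitive to it for noise-free data.

## Interface analysis

Hydrogen bonds use donor/acceptor heavy-atom tables for the 20 amino acids
(side chains plus backbone N donor / O acceptor), the 4 ribonucleotides
(sugar O2′ both roles, phosphate and ring oxygens as acceptors, exocyclic
amines and ring NH as donors) and water. The geometric criterion is
donor–acceptor distance ≤ 3.0 Å plus, when explicit hydrogens are present, a
D–H–A angle ≥ 135° — common trajectory-analysis defaults, both configurable.
On hydrogen-free ensembles the angle test is skipped with a warning. Bridge
contacts (water/ion to partner) use the distance criterion only.

Occupancy is the fraction of analyzed frames in which an interaction is
present, aggregated by (donor, acceptor) pair for H-bonds. Water bridges
default to "site" aggregation — exchanging waters merged by (protein atom,
RNA atom) partner pair, matching the conserved-site view of interfacial
water — with a per-water mode available. Ion bridges are per ion, requiring
simultaneous coordination (Mg²⁺ ≤ 3.0 Å, K⁺ ≤ 3.5 Å) of at least one protein
and one RNA O/N atom, and report per-partner coordination occupancies. The
reporting threshold defaults to 10% occupancy. The default analysis window
is the final 25% of frames — the stable tail of an equilibrated trajectory —
and every detector accepts an explicit frame range.

Occupancy grids count, per voxel, the fraction of frames with ≥1 selected
atom inside; frames must be superposed first. Grids export to OpenDX for
isovalue rendering (typical isovalues: 0.2 for ions, 0.25 for water).

RMSD uses Kabsch superposition (via scipy's `Rotation.align_vectors`) on the
N/CA/C/O atoms of the given secondary-structure elements, then RMSD over the
same atoms; the reference defaults to frame 0. Missing backbone atoms in the
selection are reported explicitly.

## Synthetic generators and their limits

`sample_library` draws each position's codon uniformly from its degenerate
expansion — ideal synthesis with no base-composition bias. Selection is
modeled as multinomial resampling of a finite founding pool with
probabilities ∝ previous frequency × retention weight, where a peptide's
weight is the product of weights of the motifs it contains; stop-containing
variants are never retained. This is the simplest model producing realistic
enrichment; it omits PCR amplification bias, chemistry-dependent display
efficiency, and binding-site competition. An optional per-base error rate
adds polymerase-style substitutions to emitted reads. Consequently, passing
tests demonstrate correct counting, ranking, logo and enrichment arithmetic
under multinomial sampling noise — not robustness to real sequencing
artifacts (quality loss, indels, chimeras).

`build_planted_ensemble` places each planted interaction at its own spatial
site (a serine, a uridine fragment, plus a water or ion as needed) ~30 Å
from the others; in a Bernoulli(occupancy) subset of frames the mobile
partner sits at bonded geometry (2.7 Å H-bond, 2.2 Å ion coordination),
otherwise displaced 8 Å; 0.05 Å Gaussian jitter is added everywhere. The
generator returns the realized per-frame masks, so detectors can be scored
against exact ground truth. These toys validate detection and occupancy
bookkeeping; they do not emulate real MD features (correlated motion,
competing partners, crowded solvation), so real-trajectory interaction
counts remain sensitive to the chosen cutoffs and occupancy threshold.

## Problem sizes

Default test and acceptance workloads are desk-scale: 10,000 reads/round
over ≤ 8 selection rounds, 1,000-frame planted ensembles, 2,700-point
kinetic fits, 500 random required-sets for the codon-optimizer
cross-validation. All complete in seconds to a few minutes.

## Known limitations

- Exact flank matching only; a single sequencing error in a flank drops the
  read.
- The H-bond donor/acceptor tables cover standard residues only; modified
  nucleotides or nonstandard amino acids are ignored by the detectors.
- The kinetic fitter assumes a shared R_max across concentrations; surfaces
  with concentration-dependent capacity need per-curve extensions.
- Ion-bridge detection requires a distance cutoff per element and
  deliberately errors on ions without one rather than guessing.
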