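# Methods

This note documents the models, conventions and design choices behind
graftkit, and what its synthetic-data validation does and does not
demonstrate.

## Kabat numbering

Numbering is template based. Each chain kind has one built-in consensus
V-domain template (heavy: 113 positions H1–H113; kappa light: 107 positions
L1–L107) carrying the conserved anchors Cys H22/H92, Trp H36, Trp H103 and
Cys L23/L88, Trp L35, Phe L98. The query is globally aligned to the template
(Biopython pairwise aligner, BLOSUM62, gap open −11 / extend −1); the
anchors are located through the alignment and must carry their expected
residue, otherwise numbering fails naming the first unmatched anchor.
Framework segments between anchors are taken at canonical length; CDR
segments absorb all loop-length variation: surplus residues become insertion
letters at the canonical sites (L27, L95, H35, H52, H82, H100 — e.g. a
15-residue CDR-L1 yields L27A–L27D), deficits omit the labels immediately
after the site. Residues before H1/L1 or after H113/L107 are considered
outside the V region and dropped, which keeps interior labels invariant
under terminal extensions.

This anchor-pinned scheme is deterministic and robust to point mutations
anywhere except the anchors themselves. Its assumptions — canonical-length
frameworks, loop variation confined to CDRs — hold for the vast majority of
natural antibodies but would mislabel genuinely indel-containing frameworks.

The default region partition uses the grafting masks (frameworks L1–23,
L35–49, L57–88, L98–107, H1–25, H36–49, H66–94, H103–111; CDRs L24–34,
L50–56, L89–97, H26–35, H50–65, H95–102). Note CDR-H1 here is H26–35, wider
than strict Kabat H31–35, matching the transfer span used in grafting
practice. The heavy positions H112–H113 fall after the H103–111 framework
mask; for partition-completeness they are assigned to the final framework
region, while superposition masks use the spans as stated. The optional
Chothia-style CDR-L1 extension unions L26–L30 into the CDR-L1 transfer span
(a no-op under the default masks, which already contain them).

## Acceptor search

Correspondence between two Fv structures is by identical Kabat label — not a
3D structural alignment — which makes the screen deterministic and exactly
reproducible. The rigid transform is a Kabsch least-squares fit on the
C-alpha atoms of shared framework-mask positions (minimum 20); reflections
are corrected so the rotation determinant is +1. Ranking uses

  Q = N_align² / [(1 + (rmsd/r₀)²) · N_query · N_target]

with r₀ = 3.0 Å, the constant used by secondary-structure-matching servers.
By default the reported rmsd and N_align cover the shared CDR positions as
well, evaluated under the framework-fitted transform ("full-Fv mode"),
mirroring whole-Fv match statistics where N_align ≈ 220 for an Fv pair;
framework-only statistics are available by flag. Q = 1 requires a complete
self-match: if the masks exclude some residues (e.g. H112–H113), a
self-match tops the ranking with Q slightly below 1, by construction of the
length weighting. Ties are broken by ascending rmsd, then lexicographic
identifier. Sequence identity is exact matches over aligned positions × 100.

The bundled 20-row acceptor-screen table is used as printed input for a
consistency check: with n_query = 227 the closed form reproduces every
printed Q value from that row's rmsd/N_align/N_residue to within ±0.01
(observed maximum deviation ≈ 0.0085, i.e. printed-precision rounding).

## CDR grafting and the back-mutation ledger

A graft replaces the CDR spans wholesale with donor residues — the donor's
loop lengths and insertion codes are inherited — and keeps acceptor residues
everywhere else. Back-mutations are the only sanctioned way to deviate:

* **vernier** — candidates are proposed at every Foote–Winter vernier
  position (built-in table, user-overridable) where donor and acceptor
  differ. Proposal is mechanical; *selection* is the designer's judgment,
  which in the original workflow came from structural inspection.
* **n_terminal** — mismatches in the windows H1–H3 and L1–L4, proposed only
  where the residues actually differ.
* **refinement** — positions such as H46 or L4 found in a second round of
  rational analysis; these are never auto-proposed and must be configured
  explicitly, reflecting that they came from affinity data, not from the
  vernier table.

The ledger is sorted heavy-first then by Kabat position; applying a
back-mutation is idempotent, reverting restores the acceptor residue, and
`diff_frameworks(final, acceptor)` always equals the ledger — an invariant
the tests assert.

## Interface analysis

SASA uses the Shrake–Rupley construction with a deterministic
golden-section-spiral point set (960 points/atom by default; two-sphere
systems agree with the closed-form spherical-cap area to < 1%, and doubling
the point count moves totals by < 0.5%). Radii are NACCESS-style united-atom
values by element (C 1.87, N 1.65, O 1.40, S 1.85, P 1.80 Å); hydrogens are
excluded, the probe is 1.4 Å. Buried area per residue is SASA of its own
selection alone minus SASA in the complex; waters never contribute to SASA
but are consulted for water-mediated hydrogen bonds. These defaults make
results comparable to interface servers up to their (unpublished) radii
choices; per-residue agreement should be expected only within tens of
percent, totals within a few percent.

Hydrogen bonds use a heavy-atom criterion — N/O pairs across the interface
within 3.5 Å, no angle term — appropriate for crystal structures around
1.9 Å resolution where hydrogens are absent. A water oxygen within 3.5 Å of
polar atoms on both sides mediates an indirect bond. Contact tables list
selection-A residues with buried area above 1 Å², classed hydrophobic
(A,V,L,I,P,F,M,W,G side chains) or polar.

Backbone geometry: omega is the CA–C–N–CA torsion (IUPAC sign convention),
computed for consecutive residue pairs with C–N distance < 2.0 Å; cis means
|ω| < 30°. Disulfides are SG–SG pairs within 2.3 Å, greedily nearest-paired
so each cysteine joins at most one bridge. The counts are invariant under
rigid motion and chain reordering. The cis and disulfide cutoffs are
standard stereochemical conventions; the source analyses state counts but
no cutoffs.

## Epitope mapping

The SPOT model: spot k of a window-w, step-s tiling starts at antigen
residue `start + (k−1)·s` (1-based inclusive coordinates throughout). Full
coverage of a 112-residue region at w=8, s=2 yields 53 spots; a
`max_spots` option supports truncated historical layouts (a 45-spot array
covers only residues 1–96 — the discrepancy is surfaced, not hidden).
Positive spots are those with max-normalized intensity ≥ 0.5 (configurable;
the underlying measurements report "prominent" signals without a numeric
cutoff). The epitope motif is the longest substring common to all positive
peptides — ties resolved to the earliest occurrence in the lowest-index
peptide — verified against an exhaustive substring-intersection oracle on
random instances. Occurrence counting on the antigen allows overlaps.

## Assay models

* **ELISA**: y = background + a_max·c/(K_D + c), plate-immobilized antigen,
  ligand depletion ignored. Damped least squares with positivity bounds;
  K_D initialized at the concentration nearest half-maximal signal. A curve
  whose top concentration is below 3·K_D is flagged as lacking a plateau.
* **SPR single-cycle kinetics**: dR/dt = k_on·C(t)·(R_max − R) − k_off·R
  with piecewise-constant analyte concentration per injection segment and a
  continuous response, integrated by fixed-step RK4 (step ≤ 0.1 s; matches
  the single-association closed form to 1e−6 relative). Global fit in
  log-parameter space (positivity by construction, trust-region reflective);
  K_D = k_off/k_on holds exactly. Mass transport and bulk shifts are
  omitted (1:1 model). A fitted k_off below the trace's resolvable scale is
  flagged non-identifiable.
* **Saturation binding**: B = B_max·c/(K_D + c), same fitting machinery.
* **Lindmo**: total/bound regressed on 1/[cells] after averaging replicate
  cell concentrations; immunoreactive fraction = 1/intercept, flagged above
  1.05. The simulator models bound fraction f·A/(A + K_D) with antigen
  concentration from cells × antigens-per-cell (default 1e6/cell, typical
  for an overexpressed surface antigen and chosen so that 1e9–1e11 cells/L
  brackets a ~15 nM K_D — the regime where the double-inverse plot is
  stable). Noisy studies use triplicate measurements, the protocol stated
  for the cell assays.

Noise models are multiplicative Gaussian for plate/cell assays and additive
Gaussian for SPR, all seeded. Simulation parameters default to the case
study's scales (ELISA K_D 1.3 nM, SPR 0.34 nM, saturation 15 nM,
immunoreactive fraction 0.73).

## Tracer arithmetic

Average (not monoisotopic) residue masses with one water per chain and
−2.016 Da per disulfide — appropriate for ESI-MS of a 65 kDa protein. The
adduct table ships the case study's three species (N-acetylcysteine
methylester 177 Da; Cy7- and Dfo-maleimide deltas derived from its printed
calculated conjugate masses). Extinction coefficients follow the ProtParam
convention (5500·W + 1490·Y + 125·cystine). Decay correction is
2^(−t/t½) with t½ = 78.41 h for ⁸⁹Zr. %ID/g = 100·(activity/injected)/weight
with optional decay correction to a common reference time; group comparison
is the unpaired two-sided Student's t test at α = 0.05 (zero-variance groups
are flagged rather than declared significant).

## Synthetic data: what it shows and what it does not

Generators are pure functions of (spec, seed). Decoy Fvs place C-alpha atoms
on a canonical helical layout indexed by Kabat label (so frameworks
superpose exactly across templates), then apply a uniform random rigid
transform followed by isotropic Gaussian coordinate noise; the expected
post-fit rmsd is σ√3, which the superposition tests recover. The toy
Fab·peptide complex builds ideal-geometry backbones with planted cis bonds,
disulfides, a direct hydrogen bond and a single bridging water.

Passing these tests demonstrates that the *measurement machinery* —
superposition, SASA, geometry, bond detection, motif extraction, fitting —
is correct against analytic and brute-force oracles and recovers planted
truth. It does not demonstrate performance on real crystal structures: the
decoys sample no torsion space, the toy complex has no side chains beyond
Cys SG, and the bundled V-region sequences are constraint-faithful
reconstructions, not database entries. Analyses of deposited structures
(e.g. a real Fab·peptide complex in PDB/mmCIF form) run through exactly the
same code paths via `graftkit interface`, `graftkit geometry` and
`graftkit search-acceptors`.

## Numerical and reproducibility choices

All randomness flows through explicit integer seeds into numpy's default
PCG64 generator. The pipeline writes sorted-key JSON artifacts stamped with
a SHA-256 hash of the scientific config (output location excluded); reruns
with the same config and seed are byte-identical. Problem sizes in tests and
the acceptance script (10–100 seeds per Monte-Carlo study, 480–960 sphere
points, ~260-atom toy complexes, 1200-second SPR traces at 2 s sampling)
were chosen to make each estimate's sampling error comfortably smaller than
the tolerance it is checked against while keeping the default suite fast.

## Known limitations

* Only Kabat numbering for kappa-type light chains is modelled; lambda
  templates, IMGT/Chothia full schemes and constant domains are out of scope
  (heavy-chain constant-region labels such as H230 in deposited structures
  are preserved as author numbering, not regenerated).
* The acceptor screen does not re-implement secondary-structure-graph
  matching; label-based correspondence requires both structures to be
  Kabat-keyed (pre-numbered or renumbered from sequence).
* PISA-style ΔG and interface classification, electrostatics and aromatic
  stacking metrics are not computed.
* ELISA fitting ignores ligand depletion; SPR fitting ignores mass
  transport; both are flagged assumptions, not options.
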