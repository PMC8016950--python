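# graftkit

A toolkit for **structure-guided antibody humanization** and the
quantifications used to validate the result. It is aimed at antibody
engineers and structural biologists who want the whole workflow — from
epitope mapping through acceptor-scaffold selection, CDR grafting and
interface analysis to binding-assay fitting and radiotracer bookkeeping — as
reproducible, scriptable code rather than a chain of web servers.

## What it does

**Kabat numbering and masks** (`graftkit.kabat`). V-region sequences are
aligned to built-in consensus templates and labelled with Kabat positions
(insertion letters at the canonical loop sites, e.g. `H52A`, `L27D`). The
default partition uses the grafting masks: frameworks L1–23, L35–49, L57–88,
L98–107, H1–25, H36–49, H66–94, H103–111 and CDRs L24–34, L50–56, L89–97,
H26–35, H50–65, H95–102, with an optional Chothia-style CDR-L1 extension
covering L26–L30.

**Acceptor search** (`graftkit.superpose`). Candidate human acceptor Fv
structures are superposed on the donor Fv by least-squares (Kabsch) fitting
of C-alpha atoms matched by identical Kabat label within the framework
masks, and ranked by the length-weighted similarity score

    Q = N_align² / [(1 + (rmsd/r₀)²) · N_query · N_target],   r₀ = 3.0 Å

which rewards both low deviation and large shared coverage.

**CDR grafting** (`graftkit.humanize`). Donor CDRs (loop lengths included)
replace the acceptor's; every framework deviation from the plain graft is a
`BackMutation` in an auditable ledger — vernier-zone candidates
(Foote–Winter positions where donor and acceptor differ), N-terminal
adaptations (H1–H3, L1–L4), and user-selected refinement positions.

**Interface analysis** (`graftkit.interface`). Shrake–Rupley
solvent-accessible surface area (deterministic 960-point spheres,
NACCESS-style united-atom radii, 1.4 Å probe), per-residue buried areas
(SASA alone minus SASA in complex), contact tables, and direct plus
water-mediated hydrogen bonds (N/O heavy-atom distance ≤ 3.5 Å). Backbone
geometry: peptide-bond omega torsions with cis detection (|ω| < 30°) and
disulfide bridges (SG–SG ≤ 2.3 Å).

**Epitope mapping** (`graftkit.epitope`). Overlapping-peptide SPOT array
design (8-mers, 2-residue step by default), intensity-threshold spot
calling, longest-common-substring motif extraction and antigen localization.

**Assay fitting** (`graftkit.assays`). ELISA equilibrium isotherms, SPR
single-cycle kinetics (1:1 Langmuir model integrated across injection
segments, K_D = k_off/k_on), cell-surface saturation binding, and the Lindmo
double-inverse extrapolation for the immunoreactive fraction — each with a
seeded simulator recording ground truth.

**Tracer arithmetic** (`graftkit.tracer`). Average chain masses and ESI-MS
adduct annotation, ProtParam extinction coefficients, ⁸⁹Zr decay correction
(t½ = 78.41 h), specific activity, radiochemical purity and %ID/g
biodistribution tables with unpaired two-sided Student's t comparison.

**Synthetic data** (`graftkit.synth`) generates every input the pipeline
consumes with known ground truth: rigid-body-perturbed Fv decoy libraries,
sphere systems with closed-form SASA, Fab-like peptide complexes with
planted cis bonds/disulfides/hydrogen bonds, and motif-planted SPOT arrays.

The bundled donor ("M3/38") and acceptor ("4NRY", "3KYM", "4KQ3", "5I8C")
V-region sequences are synthetic reconstructions of an anti-galectin-3
humanization case study, built to satisfy its published position-level
constraints (see `graftkit/refdata.py`); swap in real sequences via FASTA
for production use.

## Worked example

Humanize the bundled anti-galectin-3 donor against the m66-derived acceptor
framework and map its epitope:

```python
import numpy as np
from graftkit import (kabat_number_sequence, graft_cdrs, apply_back_mutations,
                      diff_frameworks, propose_vernier_backmutations,
                      propose_nterminal_backmutations, map_epitope)
from graftkit.refdata import V_REGION_LIBRARY, FINAL_BACKMUTATIONS, HGAL3_ND, EPITOPE_MOTIF
from graftkit.synth import make_spot_array

pairs = {n: (kabat_number_sequence(vh, "H", n), kabat_number_sequence(vl, "L", n))
         for n, (vh, vl) in V_REGION_LIBRARY.items()}
donor, acceptor = pairs["M3/38"], pairs["4NRY"]

proposals = {str(b.position): b
             for b in propose_vernier_backmutations(donor, acceptor)
             + propose_nterminal_backmutations(donor, acceptor)}
print(sorted(proposals))
# ['H2', 'H71', 'L2', 'L3', 'L36', 'L4', 'L46', 'L68']

design = graft_cdrs(donor, acceptor, donor_id="M3/38", acceptor_id="4NRY")
# H46 is a second-round refinement, not auto-proposed: build it explicitly
from graftkit import BackMutation, parse_kabat_position
h46 = parse_kabat_position("H46")
refine = BackMutation(h46, donor[0].get("H46"), acceptor[0].get("H46"), "refinement")
selected = [proposals[l] for l in FINAL_BACKMUTATIONS if l in proposals] + [refine]
final = apply_back_mutations(design, selected)

diff = diff_frameworks((final.heavy, final.light), acceptor)
print([str(p) for p, _, _ in diff["framework"]])
# ['H2', 'H46', 'H71', 'L2', 'L3', 'L4', 'L36', 'L46', 'L68']  (the 9 back-mutations)

array, planted = make_spot_array(HGAL3_ND, EPITOPE_MOTIF, noise=0.05, seed=1)
result = map_epitope(HGAL3_ND, array)
print(result.sequence, result.support, result.occurrences)
# APPGAY (24, 25, 29) (49, 58)
```

The epitope scan finds the spots 24, 25 and 29 positive, their longest
common substring `APPGAY`, and its two occurrences (residues 49 and 58) in
the repeat region of the galectin-3 N-terminal domain — the two 9-residue
repeats that carry the linear epitope.

The same steps are available from the shell:

```bash
graftkit graft donor.fasta acceptor.fasta \
    --backmutate H2 --backmutate H46 --backmutate H71 \
    --backmutate L2 --backmutate L3 --backmutate L4 \
    --backmutate L36 --backmutate L46 --backmutate L68 --out design.json
graftkit spotmap motif antigen.fasta intensities.csv
graftkit fit elisa elisa.csv
graftkit run pipeline.yaml     # end-to-end with JSON artifacts + provenance
```

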