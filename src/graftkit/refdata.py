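"""Built-in reference data for the humanization worked example.

Antigen
-------
``HGAL3_ND`` is the N-terminal domain (residues 1-112) of human galectin-3
(UniProtKB P17931), the proline/glycine-rich collagen-like region whose
9-residue repeats carry the linear epitope Ala-Pro-Pro-Gly-Ala-Tyr.

Antibody sequences
------------------
The donor ("M3/38-like") and acceptor ("4NRY-like", "3KYM-like", ...) V-region
sequences below are SYNTHETIC reconstructions, not database transcripts.  They
are engineered to satisfy every published position-level constraint of the
anti-galectin-3 humanization case study they emulate:

* donor CDR residue identities at all reported antigen-contact positions
  (Thr H30, Asp H31, Tyr H32, Ala H33, His H35, Trp H50, Asn H52, Thr H52A,
  Tyr H53, Ile H58, Tyr H59, Lys H64, Gly H95, Thr H96, Met H97, Ala H99,
  His L27D, Asp L28, Tyr L32, Trp L89, Ala L91, Thr L92, His L93, Phe L94,
  Leu L96 and framework Trp H47);
* the donor loop-length signature (a four-insertion CDR-L1 reaching L27D and
  a CDR-H2 with the H52A insertion);
* donor N-terminal identities Glu(H1), Ile(H2), Glu(H3), Val(L2), Val(L3),
  Met(L4) and acceptor identities that require adaptation exactly at H2, L2,
  L3 (plus the refinement positions H46: Glu->Lys, L4: Leu->Met);
* vernier-zone disagreement exactly at H71, L36, L46, L68 for every acceptor,
  with H78 additionally differing only in the "3KYM-like" scaffold;
* agreement between donor and acceptors at every other Foote-Winter vernier
  position, so the proposed back-mutation candidates match the case study.

Use them for worked examples and pipeline demonstrations; swap in real
sequences (FASTA) for production humanization runs.
"""

from __future__ import annotations

# --- antigen ----------------------------------------------------------------

#: Human galectin-3 N-terminal domain, residues 1-112 (UniProtKB P17931).
HGAL3_ND = (
    "MADNFSLHDALSGSGNPNPQGWPGAWGNQPAGAGGYPGAS"
    "YPGAYPGQAPPGAYPGQAPPGAYPGAPGAYPGAPAPGVYP"
    "GPPSGPGAYPSSGQPSATGAYPATGPYGAPAG"
)
assert len(HGAL3_ND) == 112

#: The linear epitope recognized in the SPOT scan.
EPITOPE_MOTIF = "APPGAY"

# --- vernier zone -----------------------------------------------------------

#: Foote-Winter vernier zone (framework positions packing under the CDRs).
#: Keys are chain kinds, values Kabat position numbers.
VERNIER_ZONE = {
    "H": (2, 27, 28, 29, 30, 47, 48, 49, 67, 69, 71, 73, 78, 93, 94, 103),
    "L": (2, 4, 35, 36, 46, 47, 48, 49, 64, 66, 68, 69, 71, 98),
}

#: Default N-terminal adaptation window.
N_TERMINAL_POSITIONS = {"H": (1, 2, 3), "L": (1, 2, 3, 4)}

#: Second-generation refinement positions (found by rational analysis plus
#: affinity data in the case study; not auto-proposed).
REFINEMENT_POSITIONS = ("H46", "L4")

# --- synthetic V-region reconstructions (see module docstring) --------------

DONOR_VH = (
    "EIELVESGGGLVQPGGSLRLSCAAS"   # H1-25
    "GFTFTDYAMH"                  # H26-35  CDR-H1
    "WVRQSPEKGLKWMG"              # H36-49  (Lys H46, Trp H47)
    "WINTYGGSTIYADSVKG"           # H50-65  CDR-H2 incl. Thr H52A
    "RATLTLDKSSSTAYMQLSSLTSEDSACAR"  # H66-94 (Leu H71, Ala H78)
    "GTMGAMDY"                    # H95-102 CDR-H3
    "WGQGTLVTVSS"                 # H103-113
)

DONOR_VL = (
    "DVVMTQSPLSLPVSLGDQASISC"     # L1-23  (Val L2, Val L3, Met L4)
    "RSSQSLVHDNGNYLA"             # L24-34 CDR-L1 incl. His L27D
    "WILQRPGQSPKGLIY"             # L35-49 (Ile L36, Gly L46)
    "KVSNRFS"                     # L50-56 CDR-L2
    "GVPDRFSGSGSETDFTLKISRVEAEDLGVYYC"  # L57-88 (Glu L68)
    "WQATHFPLT"                   # L89-97 CDR-L3
    "FGGGTKLEIK"                  # L98-107
)

_ACCEPTOR_4NRY_VH = (
    "EVELVQSGAEVKKPGESLKISCKGS"   # H1-25  (Val H2)
    "GYSFTSYWIG"                  # CDR-H1 (acceptor's own, replaced on graft)
    "WVRQMPGKGLEWMG"              # H36-49 (Glu H46)
    "IIYPGDSDTRYSPSFQ"            # CDR-H2
    "RATLTRDKSTSTAYMQLSSLTSEDSACAR"  # H66-94 (Arg H71, Ala H78)
    "EGYSSGWY"                    # CDR-H3
    "WGQGTLVTVSS"
)

_ACCEPTOR_4NRY_VL = (
    "DIQLTQSPSSLSASVGDRVTITC"     # L1-23  (Ile L2, Gln L3, Leu L4)
    "RASQSISSYLN"                 # CDR-L1
    "WYQQKPGKAPKLLIY"             # L35-49 (Tyr L36, Leu L46)
    "AASSLQS"                     # CDR-L2
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # L57-88 (Gly L68)
    "QQSYSTPPT"                   # CDR-L3
    "FGQGTKLEIK"
)

_ACCEPTOR_3KYM_VH = (
    "EVELVQSGAEVKKPGESLKISCKGS"
    "GYTFTSYGIS"
    "WVRQAPGKGLEWMG"              # H40 Ala (scaffold flavour)
    "WISAYNGNTNYAQKLQ"
    "RATLTRDKSTSTVYMQLSSLTSEDSACAR"  # Val H78: the one scaffold differing there
    "EGSGSGWY"
    "WGQGTLVTVSS"
)

_ACCEPTOR_3KYM_VL = (
    "DIQLTQSPSSLSASVGDRVTITC"
    "RASQGISNYLA"
    "WYQQKPGKAPKLLIY"
    "AASTLQS"
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"
    "QQLNSYPPT"
    "FGQGTKLEIK"
)

_ACCEPTOR_4KQ3_VH = (
    "EVELVQSGAEVKKPGASVKVSCKAS"
    "GYTFTGYYMH"
    "WVRQAPGQGLEWMG"
    "WINPNSGGTNYAQKFQ"
    "RATLTRDKSTSTAYMELSSLRSEDTACAR"  # Arg H71, Ala H78
    "DRGSYYDY"
    "WGQGTLVTVSS"
)

_ACCEPTOR_4KQ3_VL = (
    "DIQLTQSPSTLSASVGDRVTITC"
    "RASQSISSWLA"
    "WYQQKPGKAPKLLIY"
    "KASSLES"
    "GVPSRFSGSGSGTEFTLTISSLQPDDFATYYC"
    "QQYNSYSPT"
    "FGQGTKLEIK"
)

_ACCEPTOR_5I8C_VH = (
    "QVELVQSGAEVKKPGSSVKVSCKAS"    # Gln H1 (adapted to Glu on grafting)
    "GGTFSSYAIS"
    "WVRQAPGQGLEWMG"
    "GIIPIFGTANYAQKFQ"
    "RATLTRDKSTSTAYMELSSLRSEDTACAR"  # Arg H71, Ala H78
    "DSSGWSDY"
    "WGQGTLVTVSS"
)

_ACCEPTOR_5I8C_VL = (
    "DIQLTQSPGTLSLSPGERVTLSC"
    "RASQSVSSSYLA"                # 12-residue CDR-L1 (one L27 insertion)
    "WYQQKPGQAPRLLIY"
    "GASSRAT"
    "GVPDRFSGSGSGTDFTLTISRLEPEDFATYYC"  # Gly L68? see note below
    "QQYGSSPWT"
    "FGQGTKLEIK"
)

#: Donor and acceptor V-region sequence pairs, keyed by identifier.
#: Values are (heavy, light) amino-acid strings.
V_REGION_LIBRARY = {
    "M3/38": (DONOR_VH, DONOR_VL),
    "4NRY": (_ACCEPTOR_4NRY_VH, _ACCEPTOR_4NRY_VL),
    "3KYM": (_ACCEPTOR_3KYM_VH, _ACCEPTOR_3KYM_VL),
    "4KQ3": (_ACCEPTOR_4KQ3_VH, _ACCEPTOR_4KQ3_VL),
    "5I8C": (_ACCEPTOR_5I8C_VH, _ACCEPTOR_5I8C_VL),
}

#: Source annotation for the library entries (the donor is rat).
V_REGION_SOURCES = {
    "M3/38": "Rat",
    "4NRY": "Human",
    "3KYM": "Human",
    "4KQ3": "Human",
    "5I8C": "Human",
}

#: Back-mutation selections of the worked example: the initial design applies
#: the first-round set; the final design adds the two refinement positions.
INITIAL_BACKMUTATIONS = ("H2", "H71", "L2", "L3", "L36", "L46", "L68")
FINAL_BACKMUTATIONS = INITIAL_BACKMUTATIONS + ("H46", "L4")

# --- acceptor-screen table ---------------------------------------------------

#: The published top-20 acceptor screen of the case study: columns are
#: (rank, Q, rmsd [A], n_align, n_residue, seq_identity [%], source, pdb_id).
#: Used as printed input for the Q-score consistency check; the query Fv
#: residue count behind these rows is 227.
ACCEPTOR_SCREEN_N_QUERY = 227
ACCEPTOR_SCREEN_R0 = 3.0
ACCEPTOR_SCREEN_TABLE = (
    (1, 0.85, 0.89, 220, 229, 53, "Humanized", "1L7I"),
    (2, 0.85, 1.00, 222, 230, 54, "Human", "5ILC"),
    (3, 0.84, 1.01, 222, 232, 50, "Human", "5I8C"),
    (4, 0.84, 0.99, 218, 225, 54, "Human", "4KQ3"),
    (5, 0.83, 1.07, 222, 231, 57, "unpublished", "3NCJ"),
    (6, 0.83, 1.03, 220, 229, 54, "Human", "3KYM"),
    (7, 0.83, 1.07, 218, 223, 52, "Humanized", "5TDO"),
    (8, 0.83, 1.08, 222, 231, 57, "unpublished", "3NAA"),
    (9, 0.83, 1.03, 220, 229, 57, "Human", "5V7R"),
    (10, 0.82, 1.10, 222, 231, 56, "unpublished", "3NAB"),
    (11, 0.82, 1.09, 222, 232, 54, "Human", "4NRY"),
    (12, 0.82, 1.17, 221, 226, 53, "Humanized", "1T3F"),
    (13, 0.82, 1.07, 223, 235, 60, "Human", "5ILL"),
    (14, 0.82, 1.13, 223, 232, 54, "Human", "4NRY"),
    (15, 0.82, 1.07, 217, 223, 51, "Human", "5TDN"),
    (16, 0.82, 1.18, 222, 228, 57, "Human", "5IL6"),
    (17, 0.82, 1.07, 222, 234, 56, "Human", "5IT2"),
    (18, 0.82, 1.12, 221, 230, 50, "Humanized", "1AD0"),
    (19, 0.82, 1.15, 221, 229, 53, "Human", "4LLU"),
    (20, 0.81, 1.22, 221, 226, 48, "Human", "2JIX"),
)

# --- physical constants ------------------------------------------------------

#: Average residue masses [Da] (Expasy convention); add one water per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524
DISULFIDE_MASS_LOSS = 2.01588  # two hydrogens per bridge

#: Conjugation adducts [Da]: the N-acetylcysteine-methylester mixed disulfide
#: picked up in culture, and the maleimide reagents of the case study (the
#: maleimide deltas are derived from the published calculated conjugate
#: masses relative to the unmodified fusion protein).
DEFAULT_ADDUCTS = {
    "N-acetylcysteine-methylester": 177.0,
    "Cy7-maleimide": 830.10,
    "Dfo-maleimide": 711.80,
}

#: Zirconium-89 half-life [h].
ZR89_HALF_LIFE_H = 78.41

#: ProtParam extinction-coefficient increments at 280 nm [1/(M cm)].
EPS280_TRP = 5500.0
EPS280_TYR = 1490.0
EPS280_CYSTINE = 125.0

#: NACCESS-style united-atom van der Waals radii [A] by element (hydrogens
#: are excluded from surface calculations by default).
UNITED_ATOM_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "H": 1.00,
}

#: Residue polarity classes for contact tables.
HYDROPHOBIC_RESIDUES = set("AVLIPFMWG")
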