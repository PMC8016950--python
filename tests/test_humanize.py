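"""CDR grafting, back-mutation proposals and the design ledger."""

import pytest

from graftkit.humanize import (BackMutation, GraftError, apply_back_mutations,
                               diff_frameworks, graft_cdrs,
                               propose_nterminal_backmutations,
                               propose_vernier_backmutations,
                               revert_back_mutation)
from graftkit.kabat import NumberedVRegion, parse_kabat_position as P
from graftkit.refdata import FINAL_BACKMUTATIONS, INITIAL_BACKMUTATIONS


def _select(donor, acceptor, labels, partition=None):
    """Build the BackMutation list for a set of position labels."""
    proposals = {str(bm.position): bm for bm in
                 propose_vernier_backmutations(donor, acceptor, partition=partition)
                 + propose_nterminal_backmutations(donor, acceptor, partition=partition)}
    out = []
    dh, dl = donor[0].as_dict(), donor[1].as_dict()
    ah, al = acceptor[0].as_dict(), acceptor[1].as_dict()
    for lbl in labels:
        if lbl in proposals:
            out.append(proposals[lbl])
        else:
            pos = P(lbl)
            d = dh if pos.chain_kind == "H" else dl
            a = ah if pos.chain_kind == "H" else al
            out.append(BackMutation(pos, d[pos], a[pos], "refinement"))
    return out


def test_self_graft_is_identity(donor):
    design = graft_cdrs(donor, donor)
    assert design.heavy.sequence == donor[0].sequence
    assert design.light.sequence == donor[1].sequence
    assert diff_frameworks((design.heavy, design.light), donor)["framework"] == []
    assert design.back_mutations == []


def test_graft_takes_cdrs_from_donor_and_frameworks_from_acceptor(
        donor, acceptor_4nry, partition):
    design = graft_cdrs(donor, acceptor_4nry)
    dh = donor[0].as_dict()
    ah = acceptor_4nry[0].as_dict()
    gh = design.heavy.as_dict()
    for pos, aa in gh.items():
        if partition.is_cdr(pos):
            assert aa == dh[pos], f"CDR position {pos} must carry donor residue"
        else:
            assert aa == ah[pos], f"framework position {pos} must carry acceptor residue"


def test_graft_inherits_donor_loop_lengths(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    # donor CDR-L1 is 15 residues (4 insertions), acceptor's only 11
    l1 = [p for p in design.light.as_dict() if 24 <= p.number <= 34]
    assert len(l1) == 15
    assert design.light.get("L27D") == "H"
    # donor CDR-H2 carries the H52A insertion
    assert design.heavy.get("H52A") == "T"


def test_graft_with_longer_donor_cdr_h3(donor, acceptor_4nry, partition):
    """A donor CDR-H3 two residues longer than the acceptor's is inherited."""
    pairs = []
    for pos, aa in donor[0]:
        pairs.append((str(pos), aa))
        if str(pos) == "H100":
            pairs.extend([("H100A", "Y"), ("H100B", "W")])
    longer_h = NumberedVRegion.from_pairs("H", pairs, "donor+2")
    design = graft_cdrs((longer_h, donor[1]), acceptor_4nry)
    h3 = [p for p in design.heavy.as_dict() if partition.is_cdr(p) and p.number >= 95]
    donor_h3 = [p for p in longer_h.as_dict()
                if partition.is_cdr(p) and p.number >= 95]
    assert len(h3) == len(donor_h3) == 10  # brute-force span substitution


def test_missing_donor_cdr_raises(donor, acceptor_4nry):
    truncated_h = NumberedVRegion(
        "H", tuple((p, aa) for p, aa in donor[0] if p.number < 95), "broken")
    with pytest.raises(GraftError, match="CDR-H3"):
        graft_cdrs((truncated_h, donor[1]), acceptor_4nry)


def test_vernier_proposal_for_4nry(donor, acceptor_4nry):
    got = {str(bm.position) for bm in
           propose_vernier_backmutations(donor, acceptor_4nry)}
    assert {"H71", "L36", "L46", "L68"} <= got
    assert "H78" not in got


def test_vernier_proposal_for_3kym_adds_h78(donor, numbered_library):
    got = {str(bm.position) for bm in
           propose_vernier_backmutations(donor, numbered_library["3KYM"])}
    assert {"H71", "H78", "L36", "L46", "L68"} <= got


def test_vernier_proposal_empty_for_identical_pair(donor):
    assert propose_vernier_backmutations(donor, donor) == []


def test_nterminal_proposal(donor, acceptor_4nry):
    got = {str(bm.position) for bm in
           propose_nterminal_backmutations(donor, acceptor_4nry)}
    assert {"H2", "L2", "L3"} <= got
    assert "H1" not in got and "H3" not in got  # already matching
    # L4 (the Met refinement position) appears when included in the window
    assert "L4" in got
    for bm in propose_nterminal_backmutations(donor, acceptor_4nry):
        if str(bm.position) == "L4":
            assert bm.donor_aa == "M"


def test_initial_design_has_seven_framework_differences(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    design = apply_back_mutations(
        design, _select(donor, acceptor_4nry, INITIAL_BACKMUTATIONS))
    diff = diff_frameworks((design.heavy, design.light), acceptor_4nry)
    assert len(diff["framework"]) == 7


def test_final_design_has_exactly_the_nine_positions(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    design = apply_back_mutations(
        design, _select(donor, acceptor_4nry, FINAL_BACKMUTATIONS))
    diff = diff_frameworks((design.heavy, design.light), acceptor_4nry)
    got = {str(p) for p, _, _ in diff["framework"]}
    assert got == {"H2", "H46", "H71", "L2", "L3", "L4", "L36", "L46", "L68"}
    # ledger soundness: |diff| == |ledger|
    assert len(diff["framework"]) == len(design.back_mutations)


def test_final_design_keeps_donor_paratope(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    design = apply_back_mutations(
        design, _select(donor, acceptor_4nry, FINAL_BACKMUTATIONS))
    diff = diff_frameworks((design.heavy, design.light), donor)
    assert diff["cdr"] == []  # humanized vs chimeric: no CDR differences


def test_apply_empty_list_is_noop(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    after = apply_back_mutations(design, [])
    assert after.heavy.sequence == design.heavy.sequence
    assert after.back_mutations == []


def test_reapplication_is_idempotent(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    sel = _select(donor, acceptor_4nry, ("H46",))
    once = apply_back_mutations(design, sel)
    twice = apply_back_mutations(once, sel)
    assert twice.heavy.sequence == once.heavy.sequence
    assert len(twice.back_mutations) == 1


def test_apply_then_revert_restores_sequence(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    sel = _select(donor, acceptor_4nry, ("L4",))
    mutated = apply_back_mutations(design, sel)
    assert mutated.light.sequence != design.light.sequence
    restored = revert_back_mutation(mutated, "L4")
    assert restored.light.sequence == design.light.sequence
    assert restored.back_mutations == []


def test_cdr_position_rejected(donor, acceptor_4nry):
    design = graft_cdrs(donor, acceptor_4nry)
    bogus = BackMutation(P("H97"), "M", "A", "refinement")
    with pytest.raises(GraftError, match="CDR"):
        apply_back_mutations(design, [bogus])


def test_diff_frameworks_of_identical_pair_is_empty(donor):
    diff = diff_frameworks(donor, donor)
    assert diff["framework"] == [] and diff["cdr"] == []
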