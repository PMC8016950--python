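"""CDR grafting with an auditable back-mutation ledger.

Humanization by CDR grafting transplants the donor antibody's hypervariable
loops onto a human acceptor framework.  The resulting design keeps acceptor
residues at every framework position and donor residues at every CDR
position; affinity is then typically recovered by a small number of
back-mutations — framework positions restored to the donor residue, chiefly
in the vernier zone (framework positions that pack underneath the CDRs), at
the chain N-termini, or found in a second round of rational refinement.

Every deviation from the plain graft is recorded as a :class:`BackMutation`
in the design ledger, so the final sequences are fully auditable:
``diff_frameworks(final, acceptor)`` always equals the ledger.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

from .kabat import (KabatPosition, NumberedVRegion, RegionPartition,
                    parse_kabat_position)
from .refdata import N_TERMINAL_POSITIONS, VERNIER_ZONE


class GraftError(ValueError):
    pass


@dataclass(frozen=True)
class BackMutation:
    """A framework position restored from acceptor to donor residue."""

    position: KabatPosition
    donor_aa: str
    acceptor_aa: str
    category: str = "vernier"  # vernier | n_terminal | refinement
    rationale: str = ""

    def __post_init__(self):
        if self.donor_aa == self.acceptor_aa:
            raise ValueError(f"{self.position}: donor and acceptor residues are equal")
        if self.category not in ("vernier", "n_terminal", "refinement"):
            raise ValueError(f"unknown back-mutation category {self.category!r}")

    def __str__(self) -> str:
        return f"{self.acceptor_aa}{self.position}{self.donor_aa} [{self.category}]"


def _ledger_sort_key(bm: BackMutation):
    # heavy before light, then Kabat order
    return (0 if bm.position.chain_kind == "H" else 1,
            bm.position.number, bm.position.insertion)


@dataclass
class GraftDesign:
    """A humanized V-region pair plus the decisions that produced it."""

    donor_id: str
    acceptor_id: str
    partition: RegionPartition
    heavy: NumberedVRegion
    light: NumberedVRegion
    back_mutations: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def domain(self, chain_kind: str) -> NumberedVRegion:
        return self.heavy if chain_kind == "H" else self.light

    def ledger_positions(self) -> set:
        return {bm.position for bm in self.back_mutations}

    def to_json_obj(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "acceptor_id": self.acceptor_id,
            "heavy": self.heavy.to_json_obj(),
            "light": self.light.to_json_obj(),
            "back_mutations": [
                {"position": str(bm.position), "donor_aa": bm.donor_aa,
                 "acceptor_aa": bm.acceptor_aa, "category": bm.category,
                 "rationale": bm.rationale}
                for bm in self.back_mutations
            ],
            "log": list(self.log),
        }


PairedVRegion = tuple  # (NumberedVRegion heavy, NumberedVRegion light)


def _check_pair(pair: PairedVRegion, who: str) -> PairedVRegion:
    h, l = pair
    if h.chain_kind != "H" or l.chain_kind != "L":
        raise GraftError(f"{who}: expected (heavy, light) pair, got "
                         f"({h.chain_kind}, {l.chain_kind})")
    return pair


def graft_cdrs(donor: PairedVRegion, acceptor: PairedVRegion,
               partition: RegionPartition | None = None,
               donor_id: str = "donor", acceptor_id: str = "acceptor") -> GraftDesign:
    """Transplant donor CDRs onto the acceptor frameworks.

    CDR spans (including the Chothia L26-L30 extension when the partition
    enables it) are replaced wholesale by the donor residues — loop-length
    differences, including insertion codes, are inherited from the donor.
    Framework positions come from the acceptor.  The returned design has an
    empty back-mutation ledger.
    """
    partition = partition or RegionPartition.default()
    donor = _check_pair(donor, "donor")
    acceptor = _check_pair(acceptor, "acceptor")

    chains = {}
    log = []
    for kind, don, acc in (("H", donor[0], acceptor[0]), ("L", donor[1], acceptor[1])):
        cdr_names = [name for name, span, k in partition.regions_for_chain(kind) if k == "cdr"]
        donor_by_region: dict = {name: [] for name in cdr_names}
        for pos, aa in don:
            region = partition.region_of(pos)
            if region in donor_by_region:
                donor_by_region[region].append((pos, aa))
        for name in cdr_names:
            if not donor_by_region[name]:
                raise GraftError(f"donor is missing CDR span {name}")
        residues = []
        for pos, aa in acc:
            if not partition.is_cdr(pos):
                residues.append((pos, aa))
        for name in cdr_names:
            residues.extend(donor_by_region[name])
            log.append(f"graft {name}: {''.join(a for _, a in donor_by_region[name])} "
                       f"({len(donor_by_region[name])} residues) from {donor_id}")
        residues.sort(key=lambda t: (t[0].number, t[0].insertion))
        chains[kind] = NumberedVRegion(kind, tuple(residues),
                                       f"{acceptor_id}+{donor_id}-CDRs")
    return GraftDesign(donor_id=donor_id, acceptor_id=acceptor_id,
                       partition=partition, heavy=chains["H"], light=chains["L"],
                       back_mutations=[], log=log)


def _mismatches(donor: PairedVRegion, acceptor: PairedVRegion, positions,
                partition: RegionPartition, category: str, rationale: str) -> list:
    out = []
    for kind, don, acc in (("H", donor[0], acceptor[0]), ("L", donor[1], acceptor[1])):
        d, a = don.as_dict(), acc.as_dict()
        for num in positions.get(kind, ()):
            pos = KabatPosition(kind, num)
            if not partition.is_framework(pos):
                continue  # grafted anyway
            if pos in d and pos in a and d[pos] != a[pos]:
                out.append(BackMutation(pos, d[pos], a[pos], category, rationale))
    out.sort(key=_ledger_sort_key)
    return out


def propose_vernier_backmutations(donor: PairedVRegion, acceptor: PairedVRegion,
                                  vernier: dict | None = None,
                                  partition: RegionPartition | None = None) -> list:
    """Candidate back-mutations at vernier-zone framework positions.

    Every configured vernier position (default: the Foote-Winter zone) where
    donor and acceptor residues differ yields a candidate, ordered heavy
    before light then by Kabat position.  Selection among candidates is the
    designer's call — structural inspection in the original workflow.
    """
    return _mismatches(_check_pair(donor, "donor"), _check_pair(acceptor, "acceptor"),
                       vernier or VERNIER_ZONE, partition or RegionPartition.default(),
                       "vernier", "vernier-zone packing under the CDRs")


def propose_nterminal_backmutations(donor: PairedVRegion, acceptor: PairedVRegion,
                                    n_positions: dict | None = None,
                                    partition: RegionPartition | None = None) -> list:
    """Candidate back-mutations at the chain N-termini (default H1-H3, L1-L4).

    Positions already matching the donor are omitted ("to the extent
    necessary").
    """
    return _mismatches(_check_pair(donor, "donor"), _check_pair(acceptor, "acceptor"),
                       n_positions or N_TERMINAL_POSITIONS,
                       partition or RegionPartition.default(),
                       "n_terminal", "N-terminal influence on antigen affinity")


def apply_back_mutations(design: GraftDesign, selected: list) -> GraftDesign:
    """Apply selected back-mutations, returning a new design with an extended ledger.

    Each selected position must be a framework position currently carrying
    the acceptor residue; re-applying a mutation already in the ledger is a
    warning-level no-op (idempotent).  Positions inside CDRs raise.
    """
    new = GraftDesign(design.donor_id, design.acceptor_id, design.partition,
                      design.heavy, design.light,
                      list(design.back_mutations), list(design.log))
    for bm in selected:
        if new.partition.is_cdr(bm.position):
            raise GraftError(f"{bm.position} lies inside a CDR; grafting already "
                             f"carries the donor residue there")
        dom = new.domain(bm.position.chain_kind)
        table = dom.as_dict()
        current = table.get(bm.position)
        if current is None:
            raise GraftError(f"{bm.position} not present in the design")
        if current == bm.donor_aa:
            new.log.append(f"skip {bm}: donor residue already present")
            continue
        if current != bm.acceptor_aa:
            raise GraftError(f"{bm.position}: design carries {current}, expected "
                             f"acceptor residue {bm.acceptor_aa}")
        residues = tuple((p, bm.donor_aa if p == bm.position else aa) for p, aa in dom)
        updated = NumberedVRegion(dom.chain_kind, residues, dom.source_id)
        if bm.position.chain_kind == "H":
            new.heavy = updated
        else:
            new.light = updated
        new.back_mutations.append(bm)
        new.log.append(f"apply {bm}")
    new.back_mutations.sort(key=_ledger_sort_key)
    return new


def revert_back_mutation(design: GraftDesign, position) -> GraftDesign:
    """Undo one ledger entry, restoring the acceptor residue."""
    if isinstance(position, str):
        position = parse_kabat_position(position)
    entry = next((bm for bm in design.back_mutations if bm.position == position), None)
    if entry is None:
        raise GraftError(f"{position} is not in the ledger")
    dom = design.domain(position.chain_kind)
    residues = tuple((p, entry.acceptor_aa if p == position else aa) for p, aa in dom)
    updated = NumberedVRegion(dom.chain_kind, residues, dom.source_id)
    new = GraftDesign(design.donor_id, design.acceptor_id, design.partition,
                      updated if position.chain_kind == "H" else design.heavy,
                      updated if position.chain_kind == "L" else design.light,
                      [bm for bm in design.back_mutations if bm.position != position],
                      design.log + [f"revert {entry}"])
    return new


def diff_frameworks(a: PairedVRegion, b: PairedVRegion,
                    partition: RegionPartition | None = None) -> dict:
    """Position-wise differences between two numbered pairs.

    Returns ``{"framework": [(pos, aa_a, aa_b), ...], "cdr": [...]}`` over
    the positions present in both; framework and CDR differences are listed
    separately, each in chain-then-position order.
    """
    partition = partition or RegionPartition.default()
    out = {"framework": [], "cdr": []}
    for kind, ra, rb in (("H", a[0], b[0]), ("L", a[1], b[1])):
        da, db = ra.as_dict(), rb.as_dict()
        for pos in sorted(set(da) & set(db)):
            if da[pos] != db[pos]:
                bucket = "cdr" if partition.is_cdr(pos) else "framework"
                out[bucket].append((pos, da[pos], db[pos]))
    for bucket in out.values():
        bucket.sort(key=lambda t: (0 if t[0].chain_kind == "H" else 1,
                                   t[0].number, t[0].insertion))
    return out
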