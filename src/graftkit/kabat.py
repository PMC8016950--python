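"""Kabat numbering of antibody V regions.

The Kabat scheme assigns every residue of an immunoglobulin variable domain a
chain-qualified position label such as ``H52A`` or ``L27D``: an integer plus an
optional insertion letter.  Because the labels are conserved across antibodies,
they make residues comparable between a rodent donor and a human acceptor — the
basic currency of CDR grafting.

Numbering here is template based: the input sequence is globally aligned
against a built-in consensus V domain (one per chain kind) and the template's
labels are transferred.  Length differences relative to the consensus are
absorbed at canonical insertion sites inside the hypervariable loops
(after L27 and L95 for kappa light chains; after H35, H52, H82 and H100 for
heavy chains), which is where natural antibody loops vary.  A canonical-length
domain with no loop-length variation therefore receives the contiguous labels
H1..H113 or L1..L107 with no insertion codes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

_LABEL_RE = re.compile(r"^([HL])(\d+)([A-Z]?)$")


class NumberingError(ValueError):
    """Raised when a sequence cannot be assigned consistent Kabat labels."""


class LengthError(NumberingError):
    """Sequence length outside the plausible V-region range."""


class PartitionError(ValueError):
    """Raised when a residue falls outside every span of a partition."""


@total_ordering
@dataclass(frozen=True)
class KabatPosition:
    """A single Kabat label, e.g. H52A = (chain 'H', number 52, insertion 'A').

    Ordering is (number, insertion) with the uninserted position sorting before
    its lettered insertions: H52 < H52A < H53.
    """

    chain_kind: str
    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.chain_kind not in ("H", "L"):
            raise ValueError(f"chain_kind must be 'H' or 'L', got {self.chain_kind!r}")
        if self.number <= 0:
            raise ValueError("Kabat position number must be positive")
        if self.insertion and (len(self.insertion) != 1 or not self.insertion.isalpha()):
            raise ValueError(f"insertion code must be a single letter, got {self.insertion!r}")

    def _key(self):
        # "" < "A" < "B" ... so the bare position precedes its insertions.
        return (self.chain_kind, self.number, self.insertion)

    def __lt__(self, other: "KabatPosition") -> bool:
        # heavy-chain positions sort before light-chain ones so mixed
        # collections (whole-Fv masks) have a stable order
        if not isinstance(other, KabatPosition):
            return NotImplemented
        return self._key() < other._key()

    def __str__(self) -> str:
        return f"{self.chain_kind}{self.number}{self.insertion}"

    def __repr__(self) -> str:
        return f"KabatPosition({str(self)!r})"


def parse_kabat_position(label: str) -> KabatPosition:
    """Parse a label like ``"H52A"`` into a :class:`KabatPosition`.

    Round-trips with ``str()``: ``str(parse_kabat_position(s)) == s``.
    """
    m = _LABEL_RE.match(label.strip().upper())
    if not m:
        raise ValueError(f"malformed Kabat label: {label!r}")
    chain, num, ins = m.groups()
    return KabatPosition(chain, int(num), ins)


@dataclass(frozen=True)
class NumberedVRegion:
    """A V-domain sequence with one Kabat label per residue.

    Residue order must be strictly increasing in Kabat order; amino acids are
    one-letter codes from the standard 20-letter alphabet.
    """

    chain_kind: str
    residues: tuple  # tuple of (KabatPosition, str)
    source_id: str = ""

    def __post_init__(self) -> None:
        last = None
        for pos, aa in self.residues:
            if pos.chain_kind != self.chain_kind:
                raise ValueError(f"position {pos} does not match chain kind {self.chain_kind}")
            if aa not in AA20:
                raise ValueError(f"non-standard amino acid {aa!r} at {pos}")
            if last is not None and not last < pos:
                raise ValueError(f"positions not strictly increasing at {pos}")
            last = pos

    @classmethod
    def from_pairs(cls, chain_kind: str, pairs: Iterable[tuple], source_id: str = "") -> "NumberedVRegion":
        out = []
        for pos, aa in pairs:
            if isinstance(pos, str):
                pos = parse_kabat_position(pos)
            out.append((pos, aa))
        return cls(chain_kind, tuple(out), source_id)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    @property
    def positions(self) -> tuple:
        return tuple(pos for pos, _ in self.residues)

    def as_dict(self) -> dict:
        return {pos: aa for pos, aa in self.residues}

    def get(self, label) -> str | None:
        if isinstance(label, str):
            label = parse_kabat_position(label)
        return self.as_dict().get(label)

    def to_json_obj(self) -> list:
        return [[str(pos), aa] for pos, aa in self.residues]

    @classmethod
    def from_json_obj(cls, chain_kind: str, obj: Sequence, source_id: str = "") -> "NumberedVRegion":
        return cls.from_pairs(chain_kind, [(lbl, aa) for lbl, aa in obj], source_id)


# --- region partition -------------------------------------------------------

@dataclass(frozen=True)
class Span:
    """Inclusive Kabat position range on one chain."""

    start: KabatPosition
    end: KabatPosition

    def __contains__(self, pos: KabatPosition) -> bool:
        if pos.chain_kind != self.start.chain_kind:
            return False
        return self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def _span(chain: str, a: int, b: int) -> Span:
    return Span(KabatPosition(chain, a), KabatPosition(chain, b))


@dataclass(frozen=True)
class RegionPartition:
    """Named CDR and framework spans that jointly cover a V domain.

    The default masks are the grafting masks used throughout this package:
    frameworks L1-23, L35-49, L57-88, L98-107, H1-25, H36-49, H66-94,
    H103-111 and CDRs L24-34, L50-56, L89-97, H26-35, H50-65, H95-102.
    With ``chothia_l1`` set, the CDR-L1 transfer span additionally claims
    L26-L30 (a no-op under the default masks, where L24-34 already contains
    them, but meaningful for user-supplied narrower L1 definitions).
    """

    cdr_spans: Mapping[str, Span]
    framework_spans: Mapping[str, Span]
    chothia_l1: bool = False

    @classmethod
    def default(cls, chothia_l1: bool = False) -> "RegionPartition":
        cdr = {
            "CDR-L1": _span("L", 24, 34),
            "CDR-L2": _span("L", 50, 56),
            "CDR-L3": _span("L", 89, 97),
            "CDR-H1": _span("H", 26, 35),
            "CDR-H2": _span("H", 50, 65),
            "CDR-H3": _span("H", 95, 102),
        }
        fw = {
            "FR-L1": _span("L", 1, 23),
            "FR-L2": _span("L", 35, 49),
            "FR-L3": _span("L", 57, 88),
            "FR-L4": _span("L", 98, 107),
            "FR-H1": _span("H", 1, 25),
            "FR-H2": _span("H", 36, 49),
            "FR-H3": _span("H", 66, 94),
            "FR-H4": _span("H", 103, 111),
        }
        if chothia_l1:
            ext = _span("L", 26, 30)
            lo = min(cdr["CDR-L1"].start, ext.start)
            hi = max(cdr["CDR-L1"].end, ext.end)
            cdr = dict(cdr)
            cdr["CDR-L1"] = Span(lo, hi)
        return cls(cdr, fw, chothia_l1)

    def region_of(self, pos: KabatPosition) -> str | None:
        # CDR spans win over framework spans (relevant for the Chothia-L1
        # extension, where the transfer span may overlap framework L1).
        for name, span in self.cdr_spans.items():
            if pos in span:
                return name
        last_name, last_span = None, None
        for name, span in self.framework_spans.items():
            if pos in span:
                return name
            if span.start.chain_kind == pos.chain_kind and (
                    last_span is None or last_span.end < span.end):
                last_name, last_span = name, span
        # V-region tail: the Kabat heavy domain runs to H113 while the
        # superposition mask ends at H111; those trailing positions are
        # framework and belong to the final framework region.
        if last_span is not None and pos > last_span.end and pos.number <= 113:
            return last_name
        return None

    def is_cdr(self, pos: KabatPosition) -> bool:
        return any(pos in s for s in self.cdr_spans.values())

    def is_framework(self, pos: KabatPosition) -> bool:
        return (not self.is_cdr(pos)) and any(pos in s for s in self.framework_spans.values())

    def regions_for_chain(self, chain_kind: str) -> list:
        """All (name, span, kind) for one chain, in position order."""
        items = []
        for name, span in self.cdr_spans.items():
            if span.start.chain_kind == chain_kind:
                items.append((name, span, "cdr"))
        for name, span in self.framework_spans.items():
            if span.start.chain_kind == chain_kind:
                items.append((name, span, "framework"))
        items.sort(key=lambda t: (t[1].start.number, t[1].start.insertion))
        return items


def extract_regions(region: NumberedVRegion, partition: RegionPartition) -> dict:
    """Split a numbered domain into named region subsequences.

    Every residue must fall in exactly one region (CDR spans take precedence
    where the Chothia-extended CDR-L1 overlaps framework L1); a residue outside
    all spans raises :class:`PartitionError`.  Concatenating the returned
    subsequences in position order reproduces the input sequence.
    """
    out: dict = {name: [] for name, _, _ in partition.regions_for_chain(region.chain_kind)}
    for pos, aa in region:
        name = partition.region_of(pos)
        if name is None:
            raise PartitionError(f"residue {pos} lies outside every partition span")
        out[name].append((pos, aa))
    return {name: "".join(aa for _, aa in pairs) for name, pairs in out.items()}


# --- consensus templates ----------------------------------------------------

# Built-in consensus V-domain templates.  The heavy template covers Kabat
# H1-H113 (113 residues), the kappa light template L1-L107 (107 residues); the
# conserved anchors sit at their canonical labels (Cys H22/H92, Trp H36,
# Cys L23/L88, Trp L35).
_VH_TEMPLATE = (
    "EVQLVESGGGLVQPGGSLRLSCAAS"   # H1-25    framework 1
    "GFTFSSYAMS"                  # H26-35   CDR-H1 (grafting mask)
    "WVRQAPGKGLEWVS"              # H36-49   framework 2
    "AISGSGGSTYYADSVK"            # H50-65   CDR-H2
    "GRFTISRDNSKNTLYLQMNSLRAEDTCAR"  # H66-94 framework 3 (Cys at H92)
    "DRGYYFDY"                    # H95-102  CDR-H3
    "WGQGTLVTVSS"                 # H103-113 framework 4
)
_VL_TEMPLATE = (
    "DIQMTQSPSSLSASVGDRVTITC"     # L1-23    framework 1
    "RASQSISSYLN"                 # L24-34   CDR-L1
    "WYQQKPGKAPKLLIY"             # L35-49   framework 2
    "AASSLQS"                     # L50-56   CDR-L2
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # L57-88 framework 3
    "QQSYSTPPT"                   # L89-97   CDR-L3
    "FGQGTKLEIK"                  # L98-107  framework 4
)
assert len(_VH_TEMPLATE) == 113
assert len(_VL_TEMPLATE) == 107

# Canonical insertion sites: extra residues relative to the consensus are
# lettered after these positions.
_INSERTION_SITES = {"H": (35, 52, 82, 100), "L": (27, 95)}

# Conserved anchors (Kabat number -> expected amino acid), located through the
# template alignment and used to pin the framework segments.
_ANCHORS = {
    "H": {22: "C", 36: "W", 92: "C", 103: "W"},
    "L": {23: "C", 35: "W", 88: "C", 98: "F"},
}

# Segment layout per chain: (name, first Kabat number, last Kabat number).
# Framework segments have fixed canonical length; CDR segments absorb all
# loop-length variation at their canonical insertion site.
_SEGMENTS = {
    "H": (
        ("FR-H1", 1, 25), ("CDR-H1", 26, 35), ("FR-H2", 36, 49),
        ("CDR-H2", 50, 65), ("FR-H3", 66, 94), ("CDR-H3", 95, 102),
        ("FR-H4", 103, 113),
    ),
    "L": (
        ("FR-L1", 1, 23), ("CDR-L1", 24, 34), ("FR-L2", 35, 49),
        ("CDR-L2", 50, 56), ("FR-L3", 57, 88), ("CDR-L3", 89, 97),
        ("FR-L4", 98, 107),
    ),
}


def _template(chain_kind: str) -> str:
    return _VH_TEMPLATE if chain_kind == "H" else _VL_TEMPLATE


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    al.mode = "global"
    return al


def kabat_number_sequence(seq: str, chain_kind: str, source_id: str = "") -> NumberedVRegion:
    """Assign Kabat labels to a V-region sequence.

    The sequence is globally aligned to the built-in consensus template; each
    inter-anchor segment then receives labels positionally, with any length
    surplus attached as insertion letters at the segment's canonical insertion
    site (e.g. His at L27D for a 15-residue CDR-L1) and any deficit absorbed
    by omitting the labels immediately after that site.

    Raises :class:`LengthError` for sequences outside 60-140 residues and
    :class:`NumberingError` when no consistent anchor mapping exists.
    """
    seq = seq.strip().upper()
    if chain_kind not in ("H", "L"):
        raise ValueError("chain_kind must be 'H' or 'L'")
    if not (60 <= len(seq) <= 140):
        raise LengthError(f"sequence length {len(seq)} outside plausible V-region range 60-140")
    bad = set(seq) - AA20
    if bad:
        raise NumberingError(f"non-standard amino acids in input: {sorted(bad)}")

    template = _template(chain_kind)
    aln = _aligner().align(template, seq)[0]
    t_blocks, q_blocks = aln.aligned  # paired (start, end) index ranges

    # template index -> matched query index
    t2q: dict = {}
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for k in range(te - ts):
            t2q[ts + k] = qs + k

    # Locate the conserved anchors through the alignment and verify identity.
    anchors = _ANCHORS[chain_kind]
    anchor_q: dict = {}
    for num, expected in sorted(anchors.items()):
        qi = t2q.get(num - 1)
        if qi is None or seq[qi] != expected:
            found = seq[qi] if qi is not None else None
            raise NumberingError(
                f"no consistent anchor mapping: expected {expected} at "
                f"{chain_kind}{num}, found {found!r}"
            )
        anchor_q[num] = qi

    # Pin each segment's query index range off the anchors; framework segments
    # are canonical length, CDR segments take whatever lies between.
    segs = _SEGMENTS[chain_kind]
    if chain_kind == "H":
        c1, w, c2, w2 = anchor_q[22], anchor_q[36], anchor_q[92], anchor_q[103]
        spans = {
            "FR-H1": (c1 - 21, c1 + 3),
            "CDR-H1": (c1 + 4, w - 1),
            "FR-H2": (w, w + 13),
            "CDR-H2": (w + 14, c2 - 27),
            "FR-H3": (c2 - 26, c2 + 2),
            "CDR-H3": (c2 + 3, w2 - 1),
            "FR-H4": (w2, min(len(seq) - 1, w2 + 10)),
        }
    else:
        c1, w, c2, f = anchor_q[23], anchor_q[35], anchor_q[88], anchor_q[98]
        spans = {
            "FR-L1": (c1 - 22, c1),
            "CDR-L1": (c1 + 1, w - 1),
            "FR-L2": (w, w + 14),
            "CDR-L2": (w + 15, c2 - 32),
            "FR-L3": (c2 - 31, c2),
            "CDR-L3": (c2 + 1, f - 1),
            "FR-L4": (f, min(len(seq) - 1, f + 9)),
        }

    prev_end = None
    for name, _, _ in segs:
        lo, hi = spans[name]
        if hi < lo - 1:
            raise NumberingError(f"segment {name} collapsed (anchors inconsistent)")
        if prev_end is not None and lo != prev_end + 1:
            raise NumberingError(f"segment {name} does not abut its predecessor")
        prev_end = hi
    # Residues before FR-1 or after FR-4 lie beyond the V region and are
    # dropped, which keeps interior labels stable under terminal extensions.

    sites = _INSERTION_SITES[chain_kind]
    residues = []
    for name, a, b in segs:
        lo, hi = spans[name]
        lo = max(lo, 0)
        if hi < lo:
            continue
        q_idx = list(range(lo, hi + 1))
        labels = list(range(a, b + 1))
        if len(q_idx) < len(labels) and name.startswith("FR-") and name.endswith("1"):
            # N-terminally truncated domain: keep the trailing labels.
            labels = labels[len(labels) - len(q_idx):]
        delta = len(q_idx) - len(labels)
        site = next((s for s in sites if a <= s <= b), None)
        if delta > 0:
            if site is None:
                raise NumberingError(
                    f"{delta} surplus residues in {name} but no canonical "
                    f"insertion site in that segment"
                )
            if delta > 26:
                raise NumberingError(f"too many insertions in {name}")
            head = [n for n in labels if n <= site]
            tail = [n for n in labels if n > site]
            lab_seq = [KabatPosition(chain_kind, n) for n in head]
            lab_seq += [KabatPosition(chain_kind, site, chr(ord("A") + k)) for k in range(delta)]
            lab_seq += [KabatPosition(chain_kind, n) for n in tail]
        elif delta < 0:
            # omit the labels immediately after the canonical site
            # (or from the segment end when the segment has no site)
            if site is not None:
                omitted = set([n for n in labels if n > site][:-delta])
            else:
                omitted = set(labels[delta:])
            keep = [n for n in labels if n not in omitted]
            lab_seq = [KabatPosition(chain_kind, n) for n in keep]
        else:
            lab_seq = [KabatPosition(chain_kind, n) for n in labels]
        for qi, lab in zip(q_idx, lab_seq):
            residues.append((lab, seq[qi]))

    return NumberedVRegion(chain_kind, tuple(residues), source_id or "query")
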