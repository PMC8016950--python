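"""Macromolecular structure handling for antibody Fv analysis.

Structures are read with gemmi (PDB and mmCIF) into a small in-memory model
that keeps exactly what the downstream geometry and interface calculations
need: chains of residues with author numbering, atom names, elements and
coordinates.  Alternate locations are resolved to the highest-occupancy
conformer (ties keep the first encountered).

The Fv extraction step re-keys heavy/light chain residues by Kabat position,
either trusting author numbering (AbDb-style pre-numbered files, where author
residue numbers plus insertion codes already encode Kabat labels) or by
renumbering the extracted sequence through :mod:`graftkit.kabat`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import gemmi

from .kabat import KabatPosition, kabat_number_sequence

WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    name: str             # three-letter code (or HET name)
    number: int           # author residue number
    icode: str = ""       # insertion code
    atoms: dict = field(default_factory=dict)  # atom name -> Atom

    @property
    def seqid(self) -> str:
        return f"{self.number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        return self.atoms.get(name)

    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    def coords(self, include_h: bool = False) -> np.ndarray:
        pts = [a.xyz for a in self.atoms.values() if include_h or a.element != "H"]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class StructureModel:
    """Chains of residues with author numbering, in file order."""

    chains: list = field(default_factory=list)  # list of (chain_id, [Residue])
    name: str = ""

    def chain(self, chain_id: str) -> list:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not present (have {[c for c, _ in self.chains]})")

    def chain_ids(self) -> list:
        return [cid for cid, _ in self.chains]

    def iter_residues(self) -> Iterable:
        for cid, residues in self.chains:
            for res in residues:
                yield cid, res

    def atoms_array(self, chain_ids: Sequence[str] | None = None,
                    include_waters: bool = False, include_h: bool = False):
        """Flat (labels, coords, elements) arrays for selected chains."""
        labels, coords, elements = [], [], []
        for cid, residues in self.chains:
            if chain_ids is not None and cid not in chain_ids:
                continue
            for res in residues:
                if not include_waters and res.name in WATER_NAMES:
                    continue
                for at in res.atoms.values():
                    if not include_h and at.element == "H":
                        continue
                    labels.append((cid, res.seqid, res.name, at.name))
                    coords.append(at.xyz)
                    elements.append(at.element)
        return labels, np.array(coords) if coords else np.empty((0, 3)), elements


@dataclass
class FvStructure:
    """Paired variable domains with Kabat-keyed residues.

    ``heavy`` and ``light`` map :class:`KabatPosition` to :class:`Residue`;
    ``ligands`` holds any additional entities (antigen peptide, waters).
    """

    heavy: dict
    light: dict
    ligands: list = field(default_factory=list)  # list of (chain_id, [Residue])
    source_id: str = ""

    def domain(self, chain_kind: str) -> dict:
        return self.heavy if chain_kind == "H" else self.light

    def ca_coords(self, positions: Iterable[KabatPosition]) -> np.ndarray:
        pts = []
        for pos in positions:
            res = self.domain(pos.chain_kind).get(pos)
            if res is None or res.atom("CA") is None:
                raise KeyError(f"no CA atom at {pos}")
            pts.append(res.atom("CA").xyz)
        return np.array(pts)

    def positions(self, chain_kind: str) -> list:
        return sorted(self.domain(chain_kind).keys())

    def sequence(self, chain_kind: str) -> str:
        dom = self.domain(chain_kind)
        return "".join(dom[p].one_letter() or "X" for p in self.positions(chain_kind))

    def n_residues(self) -> int:
        return len(self.heavy) + len(self.light)


# --- reading / writing ------------------------------------------------------

def _from_gemmi(st: gemmi.Structure, name: str) -> StructureModel:
    st.setup_entities()
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            r = Residue(res.name.strip(), res.seqid.num, (res.seqid.icode or " ").strip())
            for at in res:
                # resolve altlocs: keep highest occupancy, first wins ties
                prev = r.atoms.get(at.name)
                if prev is not None:
                    if at.occ <= prev._occ:  # type: ignore[attr-defined]
                        continue
                atom = Atom(at.name, at.element.name.upper() or "C", np.array([at.pos.x, at.pos.y, at.pos.z]))
                atom._occ = at.occ  # type: ignore[attr-defined]
                r.atoms[at.name] = atom
            if r.atoms:
                residues.append(r)
        if residues:
            chains.append((ch.name, residues))
    return StructureModel(chains=chains, name=name)


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; by default it is inferred from
    the file extension.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")
    return _from_gemmi(st, name=path.stem)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM/HETATM records, %8.3f coordinates)."""
    serial = 0
    lines = []
    known = set(THREE_TO_ONE)
    for cid, residues in model.chains:
        for res in residues:
            record = "ATOM  " if res.name in known else "HETATM"
            for at in res.atoms.values():
                serial += 1
                x, y, z = at.xyz
                name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
                lines.append(
                    f"{record}{serial:5d} {name:<4.4s} {res.name:<3.3s} {cid[:1]}"
                    f"{res.number:4d}{(res.icode or ' '):1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{at.element:>2.2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --- Fv extraction ----------------------------------------------------------

V_REGION_LAST = {"H": 113, "L": 107}


def extract_fv(model: StructureModel, chain_map: Mapping[str, str],
               numbering: str = "abdb", ligand_chains: Sequence[str] | None = None,
               source_id: str = "") -> FvStructure:
    """Extract the Kabat-keyed Fv portion of a structure.

    ``chain_map`` names the heavy and light chains, e.g. ``{"H": "H", "L": "A"}``.
    With ``numbering="abdb"`` the author residue numbers and insertion codes
    are taken as Kabat labels directly (AbDb-style pre-numbered files); with
    ``numbering="sequence"`` the chain sequence is renumbered through the
    template aligner.  Residues past the V-region boundary (H113/L107) are
    dropped.  Remaining chains, waters included, are kept as ligand entities.
    """
    domains = {}
    for kind in ("H", "L"):
        if kind not in chain_map:
            raise KeyError(f"chain map must name the {kind} chain")
        residues = model.chain(chain_map[kind])
        keyed: dict = {}
        if numbering == "abdb":
            for res in residues:
                if res.name in WATER_NAMES or res.one_letter() is None:
                    continue
                if res.number > V_REGION_LAST[kind]:
                    continue
                pos = KabatPosition(kind, res.number, res.icode)
                if pos in keyed:
                    raise ValueError(f"duplicate Kabat position {pos} in chain {chain_map[kind]}")
                keyed[pos] = res
        elif numbering == "sequence":
            poly = [r for r in residues if r.one_letter() is not None]
            seq = "".join(r.one_letter() for r in poly)
            numbered = kabat_number_sequence(seq, kind, source_id)
            start = seq.find(numbered.sequence)
            for (pos, _), res in zip(numbered, poly[start:]):
                keyed[pos] = res
        else:
            raise ValueError(f"unknown numbering mode {numbering!r}")
        domains[kind] = keyed

    used = {chain_map["H"], chain_map["L"]}
    ligands = [(cid, residues) for cid, residues in model.chains if cid not in used]
    if ligand_chains is not None:
        ligands = [(cid, residues) for cid, residues in ligands if cid in ligand_chains]
    return FvStructure(heavy=domains["H"], light=domains["L"], ligands=ligands,
                       source_id=source_id or model.name)


# --- backbone geometry ------------------------------------------------------

@dataclass
class GeometryReport:
    omega_angles: list   # [((cid, seqid_i, name_i, seqid_j, name_j), omega_deg)]
    cis_bonds: list      # subset with |omega| < cutoff
    disulfides: list     # [((cid_i, seqid_i), (cid_j, seqid_j), distance)]
    skipped: list = field(default_factory=list)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle in degrees, IUPAC sign convention, in (-180, 180]."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def peptide_omega_and_cis(model: StructureModel, cis_cutoff_deg: float = 30.0,
                          bond_cutoff: float = 2.0) -> GeometryReport:
    """Peptide-bond omega torsions and the cis subset.

    Two consecutive residues are bonded when their C-N distance is below
    ``bond_cutoff`` (2.0 A default); omega = CA(i)-C(i)-N(i+1)-CA(i+1); a bond
    is cis when ``|omega| < cis_cutoff_deg``.  Pairs with missing backbone
    atoms are skipped and reported.
    """
    omegas, cis, skipped = [], [], []
    for cid, residues in model.chains:
        poly = [r for r in residues if r.one_letter() is not None]
        for ri, rj in zip(poly, poly[1:]):
            need = (ri.atom("CA"), ri.atom("C"), rj.atom("N"), rj.atom("CA"))
            if any(a is None for a in need):
                skipped.append((cid, ri.seqid, rj.seqid, "missing backbone atoms"))
                continue
            if np.linalg.norm(need[1].xyz - need[2].xyz) >= bond_cutoff:
                continue
            om = dihedral(*(a.xyz for a in need))
            key = (cid, ri.seqid, ri.name, rj.seqid, rj.name)
            omegas.append((key, om))
            if abs(om) < cis_cutoff_deg:
                cis.append((key, om))
    return GeometryReport(omega_angles=omegas, cis_bonds=cis, disulfides=[], skipped=skipped)


def find_disulfides(model: StructureModel, sg_cutoff: float = 2.3) -> list:
    """Cys-Cys SG pairs within ``sg_cutoff`` A, greedily nearest-paired.

    Each cysteine joins at most one bridge.  Returns
    ``[((cid_i, seqid_i), (cid_j, seqid_j), distance), ...]`` sorted by
    distance.
    """
    sgs = []
    for cid, residues in model.chains:
        for res in residues:
            if res.name == "CYS" and res.atom("SG") is not None:
                sgs.append(((cid, res.seqid), res.atom("SG").xyz))
    pairs = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= sg_cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used: set = set()
    out = []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        out.append((sgs[i][0], sgs[j][0], d))
    return out
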