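"""Protein-protein interface quantification: SASA, buried area, hydrogen bonds.

Solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
sphere-point method: each atom is inflated by the probe radius (1.4 A water
probe by default) and sampled with a fixed, deterministic spherical point set
(a golden-section spiral; 960 points per atom by default).  A point survives
if it lies outside every neighbouring inflated sphere; the accessible area is
the surviving fraction of the inflated sphere's area.  Radii are
NACCESS-style united-atom values by element, hydrogens excluded.

Buried surface area (BSA) of a residue is its SASA computed for its own
selection alone minus its SASA in the complex — the standard PISA-style
definition, so results are comparable with interface servers up to radii and
point-set differences.

Hydrogen bonds use a heavy-atom donor-acceptor criterion (N/O pairs within
3.5 A, no angle term), appropriate when the model carries no hydrogens;
water-mediated bonds are reported when a single water oxygen lies within the
cutoff of polar atoms from both selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .refdata import HYDROPHOBIC_RESIDUES, UNITED_ATOM_RADII
from .structures import THREE_TO_ONE, StructureModel, WATER_NAMES


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    points_per_atom: int = 960
    radii_set: Mapping[str, float] = field(default_factory=lambda: dict(UNITED_ATOM_RADII))
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.points_per_atom < 100:
            raise ValueError("need at least 100 sample points per atom")

    def radius_of(self, element: str, atom_label: str = "?") -> float:
        try:
            return self.radii_set[element]
        except KeyError:
            raise KeyError(f"no radius for element {element!r} (atom {atom_label})") from None


@dataclass(frozen=True)
class ContactRecord:
    chain: str
    seqid: str
    resname: str
    bsa: float
    hbond: str = "none"            # none | direct | water_mediated
    polarity: str = "polar"        # hydrophobic | polar

    @property
    def label(self) -> str:
        return f"{self.resname}({self.chain}{self.seqid})"


@dataclass
class InterfaceReport:
    selection_a: tuple
    selection_b: tuple
    total_sasa_b_free: float
    buried_b: float
    contacts_a: dict    # (chain, seqid, resname) -> BSA of selection-A residues
    contacts_b: dict    # same for selection B
    buried_a: float = 0.0
    hbonds: list = field(default_factory=list)
    water_mediated: list = field(default_factory=list)

    @property
    def buried_fraction(self) -> float:
        if self.total_sasa_b_free == 0:
            return 0.0
        return 100.0 * self.buried_b / self.total_sasa_b_free


def sphere_points(n: int) -> np.ndarray:
    """Deterministic unit-sphere point set (golden-section spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def _collect_atoms(model: StructureModel, selection: Sequence[str], params: SasaParams):
    """Flattened atom arrays for a chain selection; waters always excluded."""
    keys, coords, radii = [], [], []
    for cid, residues in model.chains:
        if cid not in selection:
            continue
        for res in residues:
            if res.name in WATER_NAMES:
                continue
            for at in res.atoms.values():
                if at.element == "H" and not params.include_hydrogens:
                    continue
                keys.append((cid, res.seqid, res.name, at.name))
                coords.append(at.xyz)
                radii.append(params.radius_of(at.element, f"{cid}/{res.seqid}/{at.name}"))
    return keys, (np.array(coords) if coords else np.empty((0, 3))), np.array(radii)


def _sasa_arrays(coords: np.ndarray, radii: np.ndarray, params: SasaParams) -> np.ndarray:
    """Per-atom SASA for one atom set (numpy Shrake-Rupley)."""
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = sphere_points(params.points_per_atom)
    inflated = radii + params.probe_radius
    tree = cKDTree(coords)
    out = np.zeros(n)
    rmax = inflated.max()
    for i in range(n):
        ri = inflated[i]
        surface = coords[i] + ri * pts
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        if nbrs:
            nc = coords[nbrs]
            nr = inflated[nbrs]
            d2 = ((surface[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (nr ** 2)[None, :], axis=1)
        else:
            exposed = np.ones(len(surface), dtype=bool)
        out[i] = 4.0 * math.pi * ri * ri * exposed.mean()
    return out


def shrake_rupley_sasa(model: StructureModel, selection: Sequence[str],
                       params: SasaParams | None = None) -> tuple:
    """Per-atom and per-residue SASA of a chain selection considered alone.

    Returns ``(per_atom, per_residue)`` dictionaries keyed by
    ``(chain, seqid, resname, atom)`` and ``(chain, seqid, resname)``.
    Deterministic for a fixed point count.  Unknown elements raise, naming
    the atom.
    """
    params = params or SasaParams()
    keys, coords, radii = _collect_atoms(model, selection, params)
    values = _sasa_arrays(coords, radii, params)
    per_atom = dict(zip(keys, values.tolist()))
    per_res: dict = {}
    for (cid, seqid, resname, _), v in per_atom.items():
        per_res[(cid, seqid, resname)] = per_res.get((cid, seqid, resname), 0.0) + v
    return per_atom, per_res


def buried_surface(model: StructureModel, selection_a: Sequence[str],
                   selection_b: Sequence[str],
                   params: SasaParams | None = None) -> InterfaceReport:
    """Interface report between two disjoint chain selections.

    Per-residue BSA = SASA(selection alone) - SASA(selection in complex);
    totals and the buried fraction are reported for selection B (the smaller
    partner, e.g. an epitope peptide).  Waters never contribute to SASA.
    """
    params = params or SasaParams()
    sa, sb = tuple(selection_a), tuple(selection_b)
    if not sa or not sb:
        raise ValueError("both selections must be non-empty")
    if set(sa) & set(sb):
        raise ValueError(f"selections overlap: {set(sa) & set(sb)}")

    keys_a, xyz_a, rad_a = _collect_atoms(model, sa, params)
    keys_b, xyz_b, rad_b = _collect_atoms(model, sb, params)
    if len(keys_a) == 0 or len(keys_b) == 0:
        raise ValueError("a selection matched no atoms")

    free_a = _sasa_arrays(xyz_a, rad_a, params)
    free_b = _sasa_arrays(xyz_b, rad_b, params)
    joint = _sasa_arrays(np.vstack([xyz_a, xyz_b]), np.concatenate([rad_a, rad_b]), params)
    complex_a, complex_b = joint[: len(keys_a)], joint[len(keys_a):]

    def residue_bsa(keys, free, complexed):
        acc: dict = {}
        for (cid, seqid, resname, _), f, c in zip(keys, free, complexed):
            k = (cid, seqid, resname)
            acc[k] = acc.get(k, 0.0) + (f - c)
        return acc

    contacts_a = residue_bsa(keys_a, free_a, complex_a)
    contacts_b = residue_bsa(keys_b, free_b, complex_b)
    return InterfaceReport(
        selection_a=sa, selection_b=sb,
        total_sasa_b_free=float(free_b.sum()),
        buried_b=float((free_b - complex_b).sum()),
        buried_a=float((free_a - complex_a).sum()),
        contacts_a=contacts_a, contacts_b=contacts_b,
    )


def hydrogen_bonds(model: StructureModel, selection_a: Sequence[str],
                   selection_b: Sequence[str], d_max: float = 3.5) -> dict:
    """Direct and water-mediated hydrogen bonds between two selections.

    Polar heavy atoms (N, O) within ``d_max`` across the interface count as
    direct bonds; a water oxygen within ``d_max`` of polar atoms on both
    sides mediates an indirect bond.  Returns ``{"direct": [...],
    "water_mediated": [...]}`` with atom labels and distances.
    """
    def polar_atoms(selection):
        out = []
        for cid, residues in model.chains:
            if cid not in selection:
                continue
            for res in residues:
                if res.name in WATER_NAMES:
                    continue
                for at in res.atoms.values():
                    if at.element in ("N", "O"):
                        out.append(((cid, res.seqid, res.name, at.name), at.xyz))
        return out

    pa, pb = polar_atoms(selection_a), polar_atoms(selection_b)
    direct = []
    for ka, xa in pa:
        for kb, xb in pb:
            d = float(np.linalg.norm(xa - xb))
            if d <= d_max:
                direct.append({"a": ka, "b": kb, "distance": d})

    waters = []
    for cid, residues in model.chains:
        for res in residues:
            if res.name in WATER_NAMES:
                for at in res.atoms.values():
                    if at.element == "O":
                        waters.append(((cid, res.seqid), at.xyz))
    mediated = []
    for wk, wx in waters:
        near_a = [(ka, float(np.linalg.norm(wx - xa))) for ka, xa in pa
                  if np.linalg.norm(wx - xa) <= d_max]
        near_b = [(kb, float(np.linalg.norm(wx - xb))) for kb, xb in pb
                  if np.linalg.norm(wx - xb) <= d_max]
        if near_a and near_b:
            mediated.append({"water": wk, "a": near_a, "b": near_b})
    return {"direct": direct, "water_mediated": mediated}


def contact_table(report: InterfaceReport, bsa_threshold: float = 1.0,
                  hbonds: dict | None = None) -> list:
    """Selection-A residues burying more than ``bsa_threshold`` A^2.

    Each record carries the residue's BSA, its polarity class (hydrophobic
    vs polar side chains) and, when a hydrogen-bond report is supplied, a
    direct/water-mediated flag.  Sorted by chain then author position.
    """
    direct_res, mediated_res = set(), set()
    if hbonds:
        for b in hbonds["direct"]:
            direct_res.add(b["a"][:2])
        for m in hbonds["water_mediated"]:
            for ka, _ in m["a"]:
                mediated_res.add(ka[:2])

    def sort_key(item):
        (cid, seqid, _), _bsa = item
        num = int("".join(ch for ch in seqid if ch.isdigit()) or 0)
        icode = "".join(ch for ch in seqid if ch.isalpha())
        return (cid, num, icode)

    records = []
    for (cid, seqid, resname), bsa in sorted(report.contacts_a.items(), key=sort_key):
        if bsa <= bsa_threshold:
            continue
        key = (cid, seqid)
        flag = "direct" if key in direct_res else (
            "water_mediated" if key in mediated_res else "none")
        one = THREE_TO_ONE.get(resname, "X")
        records.append(ContactRecord(
            chain=cid, seqid=seqid, resname=resname, bsa=bsa, hbond=flag,
            polarity="hydrophobic" if one in HYDROPHOBIC_RESIDUES else "polar"))
    return records
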