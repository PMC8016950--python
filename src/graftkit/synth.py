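"""Synthetic fixtures: decoy Fv libraries, sphere systems, toy complexes, arrays.

Everything the analysis stages consume can be generated here with known
ground truth: rigid-body-perturbed Fv decoy libraries with recorded noise
levels, pseudo-atom sphere systems with closed-form solvent-accessible areas,
peptide backbones built from ideal internal coordinates with planted cis
bonds and disulfide bridges, Fab-like peptide complexes with a planted
hydrogen-bond network, and SPOT arrays with a planted epitope motif.  Every
generator is a pure function of its arguments and seed.

These are geometric/statistical stand-ins, not physically realistic protein
models: decoy noise is isotropic Gaussian, not torsion-space sampling, and
toy complexes have idealized secondary structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .epitope import SpotArray, TilingSpec, tile_peptides
from .kabat import NumberedVRegion, kabat_number_sequence
from .refdata import V_REGION_LIBRARY
from .structures import Atom, FvStructure, ONE_TO_THREE, Residue, StructureModel


# --- geometry helpers -------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C with |CD| = bond, angle BCD and torsion ABCD."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(angle),
                   bond * math.sin(angle) * math.cos(torsion),
                   bond * math.sin(angle) * math.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# ideal backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 117.2, 121.7


def make_backbone_chain(sequence: str, number_start: int = 1,
                        phi: float = -120.0, psi: float = 130.0,
                        omegas=None) -> list:
    """Residues with ideal N/CA/C backbone geometry and chosen torsions.

    ``omegas`` gives the peptide-bond omega torsion preceding each residue
    i >= 1 (default all trans, 180 degrees); pass 0.0 to plant a cis bond.
    Returns a list of :class:`Residue` with N, CA, C atoms.
    """
    n = len(sequence)
    if omegas is None:
        omegas = [180.0] * n
    coords = []  # flat [N, CA, C] per residue
    # seed triad
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([_B_N_CA, 0.0, 0.0])
    C0 = place_atom(np.array([-1.0, 1.0, 0.0]), N0, CA0, _B_CA_C, _A_N_CA_C, 45.0)
    coords.append((N0, CA0, C0))
    for i in range(1, n):
        Np, CAp, Cp = coords[-1]
        Ni = place_atom(Np, CAp, Cp, _B_C_N, _A_CA_C_N, psi)
        CAi = place_atom(CAp, Cp, Ni, _B_N_CA, _A_C_N_CA, omegas[i])
        Ci = place_atom(Cp, Ni, CAi, _B_CA_C, _A_N_CA_C, phi)
        coords.append((Ni, CAi, Ci))
    residues = []
    for i, (aa, (Ni, CAi, Ci)) in enumerate(zip(sequence.upper(), coords)):
        name = ONE_TO_THREE.get(aa, "GLY")
        residues.append(Residue(name, number_start + i, "", {
            "N": Atom("N", "N", Ni), "CA": Atom("CA", "C", CAi),
            "C": Atom("C", "C", Ci)}))
    return residues


def add_disulfide(res_i: Residue, res_j: Residue, sg_distance: float = 2.05) -> None:
    """Attach SG atoms to two residues so their separation equals ``sg_distance``."""
    ca_i, ca_j = res_i.atom("CA").xyz, res_j.atom("CA").xyz
    mid = (ca_i + ca_j) / 2.0
    u = ca_j - ca_i
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    res_i.name = "CYS"
    res_j.name = "CYS"
    res_i.atoms["SG"] = Atom("SG", "S", mid - u * sg_distance / 2.0)
    res_j.atoms["SG"] = Atom("SG", "S", mid + u * sg_distance / 2.0)


# --- decoy Fv libraries -----------------------------------------------------

@dataclass(frozen=True)
class DecoySpec:
    n_decoys: int = 5
    sigma: float = 0.5            # per-coordinate Gaussian noise, Angstrom
    max_rotation_deg: float = 180.0
    max_translation: float = 20.0
    seed: int = 0


def _helix_ca(n: int, rise: float = 1.5, radius: float = 2.3,
              turn_deg: float = 100.0, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    i = np.arange(n, dtype=float)
    ang = np.radians(turn_deg) * i
    pts = np.column_stack((radius * np.cos(ang), radius * np.sin(ang), rise * i))
    return pts + np.asarray(origin, dtype=float)


def _canonical_ca(kind: str, number: int, insertion: str,
                  rise: float = 1.5, radius: float = 2.3,
                  turn_deg: float = 100.0) -> np.ndarray:
    """Deterministic CA position for a Kabat label on a shared helical layout.

    Indexing by Kabat label (insertion letters advance fractionally) means
    every template places its framework positions identically, so framework
    superposition across templates is exact up to the applied noise — loop
    length differences never fake framework displacement.
    """
    idx = (number - 1) + 0.2 * (ord(insertion) - 64 if insertion else 0)
    ang = math.radians(turn_deg) * idx
    origin = np.array([0.0, 0.0, 0.0]) if kind == "H" else np.array([14.0, 0.0, 0.0])
    return origin + np.array([radius * math.cos(ang), radius * math.sin(ang),
                              rise * idx])


def make_fv_template(source: str = "M3/38", seed: int = 0,
                     jitter: float = 0.0) -> FvStructure:
    """A synthetic C-alpha Fv model for one of the built-in V-region pairs.

    Coordinates follow a canonical helical layout shared by all templates
    (indexed by Kabat label), optionally perturbed with seeded Gaussian
    ``jitter`` — geometrically plausible spacing, not a physical antibody
    fold.  Residues are keyed by Kabat position via the sequence numbering
    pipeline.
    """
    vh, vl = V_REGION_LIBRARY[source]
    rng = np.random.default_rng(seed)
    fv = {}
    for kind, seq in (("H", vh), ("L", vl)):
        numbered = kabat_number_sequence(seq, kind, source)
        dom = {}
        for pos, aa in numbered:
            xyz = _canonical_ca(kind, pos.number, pos.insertion)
            if jitter > 0:
                xyz = xyz + jitter * rng.standard_normal(3)
            dom[pos] = Residue(ONE_TO_THREE[aa], pos.number, pos.insertion,
                               {"CA": Atom("CA", "C", xyz)})
        fv[kind] = dom
    return FvStructure(heavy=fv["H"], light=fv["L"], source_id=source)


def _transform_fv(fv: FvStructure, rotation: np.ndarray, translation: np.ndarray,
                  noise_sigma: float, rng, source_id: str) -> FvStructure:
    def move(dom):
        out = {}
        for pos, res in dom.items():
            atoms = {}
            for at in res.atoms.values():
                xyz = rotation @ at.xyz + translation
                if noise_sigma > 0:
                    xyz = xyz + noise_sigma * rng.standard_normal(3)
                atoms[at.name] = Atom(at.name, at.element, xyz)
            out[pos] = Residue(res.name, res.number, res.icode, atoms)
        return out
    return FvStructure(heavy=move(fv.heavy), light=move(fv.light), source_id=source_id)


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_decoy_library(template: FvStructure, spec: DecoySpec,
                       sigmas=None) -> tuple:
    """Rigidly jittered, noise-perturbed copies of a template Fv.

    ``sigmas`` optionally gives one noise level per decoy (overrides
    ``spec.sigma``).  Noise is applied after the rigid jitter, so the
    recorded sigma drives the expected post-fit rmsd (~ sigma * sqrt(3)).
    Returns ``(decoys, truth)`` where each decoy is ``(FvStructure, meta)``
    and truth records the applied sigma per decoy id.
    """
    rng = np.random.default_rng(spec.seed)
    if sigmas is None:
        sigmas = [spec.sigma] * spec.n_decoys
    decoys, truth = [], {}
    for i, sigma in enumerate(sigmas):
        R = random_rotation(rng)
        t = rng.uniform(-spec.max_translation, spec.max_translation, 3)
        decoy_id = f"decoy{i:03d}"
        fv = _transform_fv(template, R, t, float(sigma), rng, decoy_id)
        decoys.append((fv, {"pdb_id": decoy_id, "source_tag": "synthetic"}))
        truth[decoy_id] = {"sigma": float(sigma)}
    return decoys, truth


# --- sphere systems with analytic SASA --------------------------------------

@dataclass(frozen=True)
class SphereSystemSpec:
    radii: tuple
    centers: tuple        # ((x, y, z), ...)
    probe_radius: float = 1.4
    element: str = "C"


def analytic_pair_sasa(r1: float, r2: float, d: float, probe: float) -> tuple:
    """Closed-form SASA of two (possibly overlapping) probe-inflated spheres."""
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4 * math.pi * R1 ** 2, 4 * math.pi * R2 ** 2
    if d >= R1 + R2:
        return full1, full2
    if d <= abs(R1 - R2):
        # one sphere swallowed by the other
        return (full1, 0.0) if R1 >= R2 else (0.0, full2)
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return full1 - 2 * math.pi * R1 * h1, full2 - 2 * math.pi * R2 * h2


def make_sphere_system(spec: SphereSystemSpec) -> tuple:
    """Pseudo-atom model plus closed-form per-sphere SASA.

    Only pairwise overlaps are supported analytically; a triple overlap
    raises.  Returns ``(StructureModel, [sasa_per_sphere])``.
    """
    centers = [np.asarray(c, dtype=float) for c in spec.centers]
    radii = list(spec.radii)
    if len(centers) != len(radii):
        raise ValueError("radii and centers must have equal length")
    n = len(centers)
    inflated = [r + spec.probe_radius for r in radii]
    # verify the no-triple-overlap precondition
    for i in range(n):
        overlaps = [j for j in range(n) if j != i and
                    np.linalg.norm(centers[i] - centers[j]) < inflated[i] + inflated[j]]
        for a in range(len(overlaps)):
            for b in range(a + 1, len(overlaps)):
                raise ValueError(f"sphere {i} overlaps both {overlaps[a]} and "
                                 f"{overlaps[b]}: no closed form")
    analytic = [4 * math.pi * R * R for R in inflated]
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d < inflated[i] + inflated[j]:
                s1, s2 = analytic_pair_sasa(radii[i], radii[j], d, spec.probe_radius)
                analytic[i] = min(analytic[i], s1)
                analytic[j] = min(analytic[j], s2)
    residues = [Residue("SPH", i + 1, "", {"X": Atom("X", spec.element, c)})
                for i, c in enumerate(centers)]
    return StructureModel(chains=[("A", residues)], name="spheres"), analytic


# --- toy Fab-peptide complex ------------------------------------------------

def make_toy_complex(seed: int = 0) -> dict:
    """A Fab-like complex with planted geometry ground truth.

    Two antibody chains (H, 40 residues; L, 35 residues) built from ideal
    backbone geometry, a 9-residue peptide (chain P) lying in the groove
    between them, plus one bridging water (chain W).  Planted truth:

    * cis peptide bonds: 3 in H (pairs starting at residues 9, 19, 29) and
      2 in L (pairs starting at residues 7 and 24) — five in total;
    * disulfides: H22-H40, L10-L30 (intra-chain) and H5-L5 (inter-chain);
    * one direct hydrogen bond H(res 15, backbone N) to P(res 5, backbone N)
      at 2.9 A and one water bridging polar atoms of both selections.

    Returns a dict with the model, and the truth lists.
    """
    rng = np.random.default_rng(seed)

    h_omegas = [180.0] * 40
    for idx in (9, 19, 29):
        h_omegas[idx] = 0.0
    l_omegas = [180.0] * 35
    for idx in (7, 24):
        l_omegas[idx] = 0.0

    h_res = make_backbone_chain("A" * 40, phi=-120, psi=130, omegas=h_omegas)
    l_res = make_backbone_chain("A" * 35, phi=-60, psi=-45, omegas=l_omegas)
    p_res = make_backbone_chain("QAPPGAYPG", phi=-120, psi=130)

    # lay the chains out: L shifted aside, peptide floated into the groove
    for res in l_res:
        for at in res.atoms.values():
            at.xyz = at.xyz + np.array([12.0, 0.0, 0.0])
    h_ca = np.array([r.atom("CA").xyz for r in h_res])
    l_ca = np.array([r.atom("CA").xyz for r in l_res])
    groove = (h_ca.mean(axis=0) + l_ca.mean(axis=0)) / 2.0
    p_ca = np.array([r.atom("CA").xyz for r in p_res])
    shift = groove - p_ca.mean(axis=0) + np.array([0.0, 4.5, 0.0])
    for res in p_res:
        for at in res.atoms.values():
            at.xyz = at.xyz + shift

    add_disulfide(h_res[21], h_res[39])
    add_disulfide(l_res[9], l_res[29])
    add_disulfide(h_res[4], l_res[4])

    # plant one direct H-bond: move peptide residue 5 N to 2.9 A from H15 N
    target = h_res[14].atom("N").xyz
    pn = p_res[4].atom("N")
    direction = pn.xyz - target
    direction /= np.linalg.norm(direction)
    delta = target + 2.9 * direction - pn.xyz
    for at in p_res[4].atoms.values():
        at.xyz = at.xyz + delta

    # bridging water: pull peptide residue 7 to 6 A from H18's backbone N,
    # then drop one water at the midpoint (3 A from each polar atom)
    wa = h_res[17].atom("N").xyz
    pn7 = p_res[6].atom("N")
    direction = pn7.xyz - wa
    direction /= np.linalg.norm(direction)
    delta7 = wa + 6.0 * direction - pn7.xyz
    for at in p_res[6].atoms.values():
        at.xyz = at.xyz + delta7
    water_xyz = (wa + p_res[6].atom("N").xyz) / 2.0
    water = Residue("HOH", 1, "", {"O": Atom("O", "O", water_xyz)})

    model = StructureModel(chains=[("H", h_res), ("L", l_res),
                                   ("P", p_res), ("W", [water])],
                           name="toy-complex")
    return {
        "model": model,
        "n_cis": 5,
        "cis_pairs": [("H", 9), ("H", 19), ("H", 29), ("L", 7), ("L", 24)],
        "disulfides": [(("H", "22"), ("H", "40")), (("L", "10"), ("L", "30")),
                       (("H", "5"), ("L", "5"))],
        "hbond_direct": (("H", "15"), ("P", "5")),
        "water_bridge": (("H", "18"), ("P", "7")),
    }


# --- SPOT arrays with a planted motif ---------------------------------------

def make_spot_array(antigen_seq: str, motif: str, spec: TilingSpec | None = None,
                    signal: float = 0.9, background: float = 0.1,
                    noise: float = 0.0, seed: int = 0) -> tuple:
    """A tiled SPOT array whose intensities encode a planted motif.

    Spots whose peptide contains the full motif receive ``signal`` (+/-
    noise), all others ``background`` (+/- noise); intensities are then
    normalized to a maximum of 1.  Returns ``(SpotArray, planted_indices)``.
    """
    if motif not in antigen_seq:
        raise ValueError("motif must occur in the antigen sequence")
    array = tile_peptides(antigen_seq, spec)
    rng = np.random.default_rng(seed)
    planted = [s.index for s in array.spots if motif in s.sequence]
    raw = {}
    for s in array.spots:
        base = signal if s.index in planted else background
        if noise > 0:
            base = base + noise * rng.standard_normal()
        raw[s.index] = max(base, 0.0)
    top = max(raw.values())
    if top <= 0:
        raise ValueError("all intensities vanished")
    array.intensities = {k: v / top for k, v in raw.items()}
    return array, planted
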