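"""Framework-restricted Fv superposition and acceptor ranking.

Candidate human acceptor Fv structures are compared with a donor Fv by rigid
least-squares superposition of C-alpha atoms.  Residue correspondence is by
shared Kabat label (deterministic, no 3D search); the transform is fitted on
the framework masks — the conserved beta-sheet core — so that CDR-loop
differences do not bias the fit.  Candidates are ranked by the
length-weighted similarity score

    Q = N_align^2 / [(1 + (rmsd/r0)^2) * N_query * N_target]

with r0 = 3.0 A, which rewards both low deviation and large common coverage:
Q = 1 only for a complete self-match at zero rmsd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kabat import RegionPartition
from .structures import FvStructure

DEFAULT_R0 = 3.0


class InsufficientOverlapError(ValueError):
    """Too few shared framework positions for a meaningful superposition."""


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray   # 3x3, det = +1
    translation: np.ndarray
    rmsd: float
    n_align: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class AcceptorCandidate:
    pdb_id: str
    q: float
    rmsd: float
    n_align: int
    n_residue: int
    seq_identity: float
    source_tag: str = "unknown"


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple:
    """Optimal rigid transform mapping P onto Q (least-squares, Kabsch).

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1; reflections are corrected by flipping the smallest singular
    direction).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _mask_positions(fv: FvStructure, masks: RegionPartition, frameworks_only: bool):
    out = []
    for kind in ("H", "L"):
        for pos in fv.positions(kind):
            if masks.is_framework(pos) or (not frameworks_only and masks.is_cdr(pos)):
                if fv.domain(kind)[pos].atom("CA") is not None:
                    out.append(pos)
    return out


def superpose_frameworks(query: FvStructure, target: FvStructure,
                         masks: RegionPartition | None = None,
                         min_common: int = 20) -> SuperpositionResult:
    """Rigid C-alpha superposition on the shared framework positions.

    Correspondence is by identical Kabat label within the framework masks of
    both chains.  Raises :class:`InsufficientOverlapError` below
    ``min_common`` shared positions.
    """
    masks = masks or RegionPartition.default()
    qpos = set(_mask_positions(query, masks, frameworks_only=True))
    tpos = set(_mask_positions(target, masks, frameworks_only=True))
    common = sorted(qpos & tpos)
    if len(common) < min_common:
        raise InsufficientOverlapError(
            f"only {len(common)} shared framework positions (need >= {min_common})")
    P = target.ca_coords(common)
    Q = query.ca_coords(common)
    R, t, rmsd = kabsch(P, Q)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_align=len(common))


def q_score(n_align: int, rmsd: float, n_query: int, n_target: int,
            r0: float = DEFAULT_R0) -> float:
    """Length-weighted similarity score in (0, 1]."""
    if min(n_align, n_query, n_target) <= 0:
        raise ValueError("counts must be positive")
    if rmsd < 0 or r0 <= 0:
        raise ValueError("rmsd must be >= 0 and r0 > 0")
    return n_align ** 2 / ((1.0 + (rmsd / r0) ** 2) * n_query * n_target)


def _seq_identity(query: FvStructure, target: FvStructure, positions) -> float:
    match = 0
    for pos in positions:
        qa = query.domain(pos.chain_kind)[pos].one_letter()
        ta = target.domain(pos.chain_kind)[pos].one_letter()
        match += int(qa is not None and qa == ta)
    return 100.0 * match / len(positions) if positions else 0.0


def rank_acceptors(query: FvStructure, library: list,
                   masks: RegionPartition | None = None, r0: float = DEFAULT_R0,
                   full_fv_align: bool = True) -> tuple:
    """Superpose, score and rank a library of candidate acceptor Fvs.

    ``library`` holds ``(FvStructure, metadata_dict)`` pairs; metadata may
    carry ``pdb_id`` and ``source_tag``.  The rigid transform is always
    fitted on the framework masks; with ``full_fv_align`` (default) the
    reported rmsd/N_align additionally cover the shared CDR positions under
    that framework-fitted transform, mirroring whole-Fv match statistics.
    Ranking is by Q descending, ties broken by rmsd ascending then pdb_id.
    Per-entry failures are collected, not fatal.

    Returns ``(candidates, failures)``.
    """
    masks = masks or RegionPartition.default()
    n_query = query.n_residues()
    results, failures = [], []
    for fv, meta in library:
        pdb_id = str(meta.get("pdb_id", fv.source_id or "?"))
        try:
            sup = superpose_frameworks(query, fv, masks)
            if full_fv_align:
                qall = set(_mask_positions(query, masks, frameworks_only=False))
                tall = set(_mask_positions(fv, masks, frameworks_only=False))
                common = sorted(qall & tall)
                moved = sup.transform(fv.ca_coords(common))
                ref = query.ca_coords(common)
                rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
                n_align = len(common)
            else:
                common = None
                rmsd, n_align = sup.rmsd, sup.n_align
            n_target = fv.n_residues()
            q = q_score(n_align, rmsd, n_query, n_target, r0)
            ident = _seq_identity(query, fv, common if common is not None else
                                  sorted(set(_mask_positions(query, masks, True)) &
                                         set(_mask_positions(fv, masks, True))))
            results.append(AcceptorCandidate(
                pdb_id=pdb_id, q=q, rmsd=rmsd, n_align=n_align,
                n_residue=n_target, seq_identity=ident,
                source_tag=str(meta.get("source_tag", "unknown"))))
        except Exception as exc:  # noqa: BLE001 - per-entry failures logged
            failures.append((pdb_id, f"{type(exc).__name__}: {exc}"))
    results.sort(key=lambda c: (-c.q, c.rmsd, c.pdb_id))
    return results, failures


def filter_by_source(candidates: list, allowed_tags) -> list:
    """Keep only candidates whose source tag is in ``allowed_tags``; order kept."""
    allowed = set(allowed_tags)
    return [c for c in candidates if c.source_tag in allowed]
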