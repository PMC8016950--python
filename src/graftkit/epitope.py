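"""Overlapping-peptide SPOT arrays and linear epitope extraction.

A SPOT array tiles an antigen region with short synthetic peptides — here
8-mers shifted by 2 residues by default — immobilized as numbered spots.
Probing the membrane with a labelled antibody lights up the spots whose
peptide contains the epitope; the linear epitope is then the longest
sequence common to all positive spots, located back onto the antigen.

Coordinates are 1-based and inclusive on the antigen throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class TilingSpec:
    """Window/step tiling of an inclusive 1-based antigen region."""

    window: int = 8
    step: int = 2
    region_start: int = 1
    region_end: int | None = None  # None: to the end of the sequence

    def __post_init__(self):
        if not (1 <= self.step <= self.window):
            raise ValueError("require 1 <= step <= window")


@dataclass(frozen=True)
class Spot:
    index: int       # 1-based spot number
    start: int       # 1-based antigen position of the first residue
    sequence: str


@dataclass
class SpotArray:
    spots: list
    intensities: dict = field(default_factory=dict)  # spot index -> [0, 1]

    def __len__(self) -> int:
        return len(self.spots)

    def spot(self, index: int) -> Spot:
        for s in self.spots:
            if s.index == index:
                return s
        raise KeyError(f"no spot {index}")

    def peptides(self) -> list:
        return [s.sequence for s in self.spots]


@dataclass(frozen=True)
class EpitopeMotif:
    sequence: str
    support: tuple         # spot indices the motif was derived from
    occurrences: tuple     # 1-based start positions on the antigen

    def __bool__(self) -> bool:
        return bool(self.sequence)


def tile_peptides(antigen_seq: str, spec: TilingSpec | None = None,
                  max_spots: int | None = None) -> SpotArray:
    """Design the peptide array: full windows at starts region_start, +step, ...

    Spot k starts at ``region_start + (k-1)*step``; all windows fully inside
    the region are kept (optionally truncated to ``max_spots``).
    """
    spec = spec or TilingSpec()
    antigen_seq = antigen_seq.strip().upper()
    end = spec.region_end or len(antigen_seq)
    if not (1 <= spec.region_start <= end <= len(antigen_seq)):
        raise ValueError("region outside sequence bounds")
    region_len = end - spec.region_start + 1
    if spec.window > region_len:
        raise ValueError(f"window {spec.window} exceeds region length {region_len}")
    spots = []
    k = 1
    start = spec.region_start
    while start + spec.window - 1 <= end:
        spots.append(Spot(k, start, antigen_seq[start - 1: start - 1 + spec.window]))
        k += 1
        start += spec.step
    if max_spots is not None:
        spots = spots[:max_spots]
    return SpotArray(spots=spots)


def call_positive_spots(array: SpotArray, threshold: float = 0.5) -> list:
    """Spot indices with intensity >= threshold, ascending.

    Requires intensities normalized so the maximum is 1.
    """
    if not array.intensities:
        raise ValueError("array has no intensities")
    return sorted(i for i, v in array.intensities.items() if v >= threshold)


def _substrings(s: str) -> set:
    return {s[i:j] for i in range(len(s)) for j in range(i + 1, len(s) + 1)}


def minimal_common_motif(array: SpotArray, positive: Sequence[int]) -> EpitopeMotif:
    """Longest substring common to every positive spot's peptide.

    Among equal-length candidates the one occurring earliest in the
    lowest-index positive peptide wins.  With no common substring the empty
    motif is returned.  Peptides are short, so exhaustive substring
    intersection is used directly.
    """
    if not positive:
        raise ValueError("need at least one positive spot")
    positive = sorted(positive)
    peptides = [array.spot(i).sequence for i in positive]
    common = _substrings(peptides[0])
    for pep in peptides[1:]:
        common &= _substrings(pep)
    if not common:
        return EpitopeMotif("", tuple(positive), ())
    best_len = max(len(s) for s in common)
    candidates = [s for s in common if len(s) == best_len]
    winner = min(candidates, key=lambda s: peptides[0].find(s))
    return EpitopeMotif(winner, tuple(positive), ())


def locate_motif(antigen_seq: str, motif: str) -> EpitopeMotif:
    """All (possibly overlapping) 1-based occurrences of a motif."""
    if not motif:
        raise ValueError("motif must be non-empty")
    antigen_seq = antigen_seq.strip().upper()
    motif = motif.strip().upper()
    hits = []
    i = antigen_seq.find(motif)
    while i != -1:
        hits.append(i + 1)
        i = antigen_seq.find(motif, i + 1)
    return EpitopeMotif(motif, (), tuple(hits))


def map_epitope(antigen_seq: str, array: SpotArray, threshold: float = 0.5) -> EpitopeMotif:
    """Call positives, extract the common motif and locate it on the antigen."""
    positive = call_positive_spots(array, threshold)
    motif = minimal_common_motif(array, positive)
    if not motif:
        return motif
    located = locate_motif(antigen_seq, motif.sequence)
    return EpitopeMotif(motif.sequence, motif.support, located.occurrences)
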