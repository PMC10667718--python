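"""Placement of accepted peptides onto therapeutic chains.

Peptides come from a no-enzyme search, so any contiguous substring of a
chain is a legal placement.  Placements carry CDR overlap, chain-coordinate
modification sites and a uniqueness flag against an optional background
proteome.  ``il_equivalent`` matching treats I and L as the same residue
(mass spectrometry cannot distinguish them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .identification_filter import ConfidenceTier, assign_confidence
from .psm_io import PSMRecord
from .sequence_model import TherapeuticMolecule

MATCH_MODES = ("exact", "il_equivalent")


def _canon(seq: str, match_mode: str) -> str:
    if match_mode == "exact":
        return seq
    if match_mode == "il_equivalent":
        return seq.replace("I", "L")
    raise ValidationError(f"unknown match_mode {match_mode!r}")


@dataclass
class MappedPeptide:
    """One placement of an accepted peptide on a therapeutic chain."""

    record: PSMRecord
    chain_id: str
    start: int  # 1-based inclusive chain coordinates
    end: int
    tier: ConfidenceTier
    mods: list[tuple[str, int | None]] = field(default_factory=list)  # (kind, chain pos)
    cdr_overlaps: list[str] = field(default_factory=list)
    unique_to_therapeutic: bool = False

    @property
    def peptide(self) -> str:
        return self.record.peptide

    @property
    def donor_id(self) -> str:
        return self.record.donor_id

    @property
    def sample_id(self) -> str:
        return self.record.sample_id

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_occurrences(needle: str, haystack: str, match_mode: str = "exact") -> list[int]:
    """All 1-based start positions of ``needle`` in ``haystack`` (overlapping)."""
    needle = _canon(needle, match_mode)
    haystack = _canon(haystack, match_mode)
    positions = []
    i = haystack.find(needle)
    while i != -1:
        positions.append(i + 1)
        i = haystack.find(needle, i + 1)
    return positions


def map_peptide(
    peptide: str,
    molecule: TherapeuticMolecule,
    match_mode: str = "exact",
) -> list[tuple[str, int, int]]:
    """Every (chain_id, start, end) where the peptide occurs as a substring.

    An empty list means the peptide is not therapeutic-derived.
    """
    placements = []
    for chain in molecule.chains:
        for start in find_occurrences(peptide, chain.sequence, match_mode):
            placements.append((chain.chain_id, start, start + len(peptide) - 1))
    return placements


def annotate_cdr_overlap(
    placement: tuple[str, int, int],
    molecule: TherapeuticMolecule,
) -> list[str]:
    """Names of every CDR sharing >= 1 residue with the placement interval."""
    chain_id, start, end = placement
    chain = molecule.chain(chain_id)
    if not (1 <= start <= end <= len(chain)):
        raise ValidationError(f"placement [{start}, {end}] out of bounds on {chain_id}")
    return [c.name for c in chain.cdrs if c.overlaps(start, end)]


def is_unique_to_therapeutic(
    peptide: str,
    molecule: TherapeuticMolecule,
    background_proteome: Mapping[str, str],
    match_mode: str = "exact",
) -> bool:
    """True iff the peptide maps to a therapeutic chain and to no background protein."""
    if not map_peptide(peptide, molecule, match_mode):
        return False
    needle = _canon(peptide, match_mode)
    for seq in background_proteome.values():
        if needle in _canon(seq, match_mode):
            return False
    return True


def map_records(
    records: Sequence[PSMRecord],
    molecule: TherapeuticMolecule,
    background_proteome: Mapping[str, str] | None = None,
    match_mode: str = "exact",
) -> list[MappedPeptide]:
    """Place accepted records on the molecule; one MappedPeptide per placement.

    Localized modification positions are translated to chain coordinates;
    unlocalized modifications keep a ``None`` position.
    """
    background = background_proteome or {}
    # uniqueness depends only on the bare sequence — cache per peptide
    unique_cache: dict[str, bool] = {}
    mapped: list[MappedPeptide] = []
    for rec in records:
        placements = map_peptide(rec.peptide, molecule, match_mode)
        if not placements:
            continue
        if rec.peptide not in unique_cache:
            unique_cache[rec.peptide] = is_unique_to_therapeutic(
                rec.peptide, molecule, background, match_mode
            )
        for chain_id, start, end in placements:
            mods = [
                (m.kind, None if m.position is None else start + m.position - 1)
                for m in rec.mods
            ]
            mapped.append(
                MappedPeptide(
                    record=rec,
                    chain_id=chain_id,
                    start=start,
                    end=end,
                    tier=assign_confidence(rec.charge, rec.xcorr),
                    mods=mods,
                    cdr_overlaps=annotate_cdr_overlap((chain_id, start, end), molecule),
                    unique_to_therapeutic=unique_cache[rec.peptide],
                )
            )
    return mapped


@dataclass
class LengthStats:
    """Median (lower-median convention) and histogram of peptide lengths."""

    median: int | None
    histogram: dict[int, int]

    @property
    def n(self) -> int:
        return sum(self.histogram.values())


def length_statistics(mapped_peptides: Iterable[MappedPeptide]) -> LengthStats:
    """Length stats over distinct bare peptide sequences.

    Each distinct sequence counts once regardless of modifications, charge
    states or multiple placements.  An empty input yields empty statistics
    rather than an error.
    """
    lengths = sorted({mp.peptide: len(mp.peptide) for mp in mapped_peptides}.values())
    if not lengths:
        return LengthStats(median=None, histogram={})
    histogram: dict[int, int] = {}
    for ln in lengths:
        histogram[ln] = histogram.get(ln, 0) + 1
    median = lengths[(len(lengths) - 1) // 2]  # lower median for even counts
    return LengthStats(median=median, histogram=histogram)
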