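"""Therapeutic antibody chains, CDR intervals and region utilities.

Coordinates are 1-based inclusive throughout the package, matching the
residue numbering used when describing antibody regions (e.g. "HC residue
73 to 92").  Chains are restricted to the 20 canonical amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rounding import round_half_up
from .errors import SequenceModelError

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

CHAIN_IDS = ("HC", "LC")


@dataclass(frozen=True)
class CdrInterval:
    """A named CDR region on one chain, 1-based inclusive."""

    chain_id: str
    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.chain_id not in CHAIN_IDS:
            raise SequenceModelError(f"chain_id must be HC or LC, got {self.chain_id!r}")
        if not (1 <= self.start <= self.end):
            raise SequenceModelError(
                f"CDR {self.name!r}: need 1 <= start <= end, got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end] shares at least one residue with this CDR."""
        return max(self.start, start) <= min(self.end, end)


@dataclass
class TherapeuticChain:
    """One antibody chain with its CDR annotation."""

    chain_id: str
    sequence: str
    cdrs: list[CdrInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.chain_id not in CHAIN_IDS:
            raise SequenceModelError(f"chain_id must be HC or LC, got {self.chain_id!r}")
        if not self.sequence:
            raise SequenceModelError(f"{self.chain_id}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise SequenceModelError(
                f"{self.chain_id}: non-canonical residues {sorted(bad)}"
            )
        self._validate_cdrs()

    def _validate_cdrs(self):
        names = [c.name for c in self.cdrs]
        if len(names) != len(set(names)):
            raise SequenceModelError(f"{self.chain_id}: duplicate CDR names")
        n = len(self.sequence)
        for c in self.cdrs:
            if c.chain_id != self.chain_id:
                raise SequenceModelError(
                    f"CDR {c.name!r} declared on {c.chain_id} attached to {self.chain_id}"
                )
            if c.end > n:
                raise SequenceModelError(
                    f"CDR {c.name!r} [{c.start}, {c.end}] out of bounds for "
                    f"{self.chain_id} of length {n}"
                )
        ordered = sorted(self.cdrs, key=lambda c: c.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise SequenceModelError(
                    f"{self.chain_id}: CDRs {a.name!r} and {b.name!r} overlap"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def region(self, start: int, end: int) -> str:
        """Slice of the chain in 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise SequenceModelError(
                f"{self.chain_id}: region [{start}, {end}] out of bounds"
            )
        return self.sequence[start - 1 : end]


@dataclass
class TherapeuticMolecule:
    """A therapeutic with exactly one heavy and one light chain."""

    name: str
    hc: TherapeuticChain
    lc: TherapeuticChain
    ada_rate_text: str | None = None

    def __post_init__(self):
        if self.hc.chain_id != "HC":
            raise SequenceModelError("hc slot must hold the HC chain")
        if self.lc.chain_id != "LC":
            raise SequenceModelError("lc slot must hold the LC chain")

    @property
    def chains(self) -> tuple[TherapeuticChain, TherapeuticChain]:
        return (self.hc, self.lc)

    def chain(self, chain_id: str) -> TherapeuticChain:
        if chain_id == "HC":
            return self.hc
        if chain_id == "LC":
            return self.lc
        raise SequenceModelError(f"unknown chain_id {chain_id!r}")

    def cdrs(self) -> list[CdrInterval]:
        return list(self.hc.cdrs) + list(self.lc.cdrs)


def _chain_role_from_header(header: str) -> str | None:
    # header token "|HC" / "|LC" designates the chain role
    for token in header.replace(" ", "|").split("|"):
        if token in CHAIN_IDS:
            return token
    return None


def load_therapeutic(
    fasta_path: str | Path,
    regions_path: str | Path,
    name: str | None = None,
    ada_rate_text: str | None = None,
) -> TherapeuticMolecule:
    """Load a therapeutic definition from a FASTA + CDR-regions sidecar.

    The FASTA must contain one record per chain with a ``|HC`` or ``|LC``
    token in the header.  The regions file is tab-separated with columns
    ``chain_id  region_name  start  end`` (1-based inclusive), with an
    optional header row.
    """
    fasta_path = Path(fasta_path)
    regions_path = Path(regions_path)
    sequences: dict[str, str] = {}
    first_header = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        role = _chain_role_from_header(rec.description)
        if role is None:
            raise SequenceModelError(
                f"{fasta_path}: header {rec.description!r} lacks an |HC or |LC token"
            )
        if role in sequences:
            raise SequenceModelError(f"{fasta_path}: duplicate {role} record")
        sequences[role] = str(rec.seq).upper()
        if first_header is None:
            first_header = rec.id.split("|")[0]
    for role in CHAIN_IDS:
        if role not in sequences:
            raise SequenceModelError(f"{fasta_path}: missing {role} chain record")

    cdrs: dict[str, list[CdrInterval]] = {"HC": [], "LC": []}
    with open(regions_path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise SequenceModelError(
                    f"{regions_path} line {line_no}: expected 4 tab-separated fields"
                )
            chain_id, region_name, start_s, end_s = parts
            if line_no == 1 and not (start_s.isdigit() and end_s.isdigit()):
                continue  # header row
            if chain_id not in CHAIN_IDS:
                raise SequenceModelError(
                    f"{regions_path} line {line_no}: unknown chain {chain_id!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise SequenceModelError(
                    f"{regions_path} line {line_no}: non-integer bounds"
                ) from exc
            cdrs[chain_id].append(CdrInterval(chain_id, region_name, start, end))

    molecule_name = name if name is not None else (first_header or fasta_path.stem)
    return TherapeuticMolecule(
        name=molecule_name,
        hc=TherapeuticChain("HC", sequences["HC"], cdrs["HC"]),
        lc=TherapeuticChain("LC", sequences["LC"], cdrs["LC"]),
        ada_rate_text=ada_rate_text,
    )


def write_therapeutic(
    molecule: TherapeuticMolecule,
    fasta_path: str | Path,
    regions_path: str | Path,
) -> None:
    """Serialize a molecule to the canonical FASTA + regions files.

    ``load_therapeutic`` of the written files round-trips byte-identically
    when written again.
    """
    records = [
        SeqRecord(Seq(chain.sequence), id=f"{molecule.name}|{chain.chain_id}", description="")
        for chain in molecule.chains
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")
    with open(regions_path, "w") as fh:
        fh.write("chain_id\tregion_name\tstart\tend\n")
        for chain in molecule.chains:
            for c in sorted(chain.cdrs, key=lambda c: c.start):
                fh.write(f"{c.chain_id}\t{c.name}\t{c.start}\t{c.end}\n")


def region_homology(
    seq_a: str,
    seq_b: str,
    interval_a: tuple[int, int],
    interval_b: tuple[int, int],
) -> int:
    """Ungapped percent identity between two equal-length regions.

    Returns ``100 * identical_positions / length`` rounded half-up to the
    nearest integer.  No alignment is performed; unequal interval lengths
    are an error.
    """
    a_start, a_end = interval_a
    b_start, b_end = interval_b
    for seq, (start, end), label in ((seq_a, interval_a, "a"), (seq_b, interval_b, "b")):
        if not (1 <= start <= end <= len(seq)):
            raise SequenceModelError(
                f"interval_{label} [{start}, {end}] out of bounds for sequence of "
                f"length {len(seq)}"
            )
    if (a_end - a_start) != (b_end - b_start):
        raise SequenceModelError(
            "region_homology requires equal-length intervals "
            f"({a_end - a_start + 1} vs {b_end - b_start + 1})"
        )
    region_a = seq_a[a_start - 1 : a_end]
    region_b = seq_b[b_start - 1 : b_end]
    matches = sum(x == y for x, y in zip(region_a, region_b))
    return int(round_half_up(100.0 * matches / len(region_a), 0))
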