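"""PSM table I/O and modification-annotation parsing.

The canonical interchange format is a flat TSV with columns (exact order)::

    sample_id  donor_id  day  analyst  peptide  charge  xcorr  mods  proteins  is_decoy

The ``mods`` field is a ``;``-separated list of tokens
``<residue><position>(<ox|deam>)`` where ``?`` in place of the position
marks an unlocalized modification, e.g. ``M4(ox);N?(deam)``.  ``proteins``
is a ``,``-separated accession list.  ``is_decoy`` is ``true``/``false``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import PsmParseError, ValidationError

COLUMNS = (
    "sample_id",
    "donor_id",
    "day",
    "analyst",
    "peptide",
    "charge",
    "xcorr",
    "mods",
    "proteins",
    "is_decoy",
)

MOD_KINDS = ("MetOx", "Deamidation")

#: fixed monoisotopic mass deltas (Da) per modification kind
MASS_DELTAS = {"MetOx": 15.995, "Deamidation": 0.984}

_ALLOWED_RESIDUES = {"MetOx": frozenset("M"), "Deamidation": frozenset("NQ")}
_KIND_CODES = {"MetOx": "ox", "Deamidation": "deam"}
_CODE_KINDS = {v: k for k, v in _KIND_CODES.items()}

_MOD_TOKEN = re.compile(r"^([A-Z])(\d+|\?)\((ox|deam)\)$")

CHARGE_MIN, CHARGE_MAX = 2, 7

_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass(frozen=True)
class Modification:
    """A variable modification on one peptide.

    ``position`` is the 1-based index within the peptide, or ``None`` for
    an unlocalized modification (spectral evidence supports the mass shift
    but not the site).
    """

    kind: str
    residue: str
    position: int | None

    def __post_init__(self):
        if self.kind not in MOD_KINDS:
            raise ValidationError(f"unknown modification kind {self.kind!r}")
        if self.residue not in _ALLOWED_RESIDUES[self.kind]:
            raise ValidationError(
                f"{self.kind} not applicable to residue {self.residue!r}"
            )
        if self.position is not None and self.position < 1:
            raise ValidationError("modification position must be >= 1")

    @property
    def mass_delta(self) -> float:
        return MASS_DELTAS[self.kind]

    @property
    def localized(self) -> bool:
        return self.position is not None

    def to_token(self) -> str:
        pos = "?" if self.position is None else str(self.position)
        return f"{self.residue}{pos}({_KIND_CODES[self.kind]})"


def parse_mod_token(token: str) -> Modification:
    m = _MOD_TOKEN.match(token)
    if m is None:
        raise ValidationError(f"malformed modification token {token!r}")
    residue, pos_s, code = m.groups()
    position = None if pos_s == "?" else int(pos_s)
    return Modification(kind=_CODE_KINDS[code], residue=residue, position=position)


def parse_mods(spec: str) -> list[Modification]:
    """Parse the ``mods`` column; empty string means no modifications."""
    if not spec:
        return []
    return [parse_mod_token(tok) for tok in spec.split(";")]


def format_mods(mods: Iterable[Modification]) -> str:
    return ";".join(m.to_token() for m in mods)


@dataclass
class PSMRecord:
    """One peptide-spectrum match with donor/replicate provenance."""

    sample_id: str
    donor_id: str
    day: str
    analyst: str
    peptide: str
    charge: int
    xcorr: float
    mods: list[Modification] = field(default_factory=list)
    protein_ids: list[str] = field(default_factory=list)
    is_decoy: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.peptide:
            raise ValidationError("empty peptide")
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValidationError(f"non-canonical residues in peptide {self.peptide!r}")
        if not (CHARGE_MIN <= self.charge <= CHARGE_MAX):
            raise ValidationError(
                f"charge {self.charge} outside the accepted range "
                f"{CHARGE_MIN}-{CHARGE_MAX}"
            )
        if self.xcorr < 0:
            raise ValidationError(f"negative xcorr {self.xcorr}")
        for mod in self.mods:
            if mod.position is not None:
                if mod.position > len(self.peptide):
                    raise ValidationError(
                        f"modification {mod.to_token()} beyond peptide length "
                        f"{len(self.peptide)}"
                    )
                if self.peptide[mod.position - 1] != mod.residue:
                    raise ValidationError(
                        f"modification {mod.to_token()} does not match residue "
                        f"{self.peptide[mod.position - 1]!r} at that position"
                    )


def _parse_bool(text: str) -> bool:
    lowered = text.strip().lower()
    if lowered in ("true", "1", "yes"):
        return True
    if lowered in ("false", "0", "no"):
        return False
    raise ValidationError(f"expected a boolean, got {text!r}")


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read a PSM TSV, validating every row; row order is preserved.

    Every malformed row raises :class:`PsmParseError` carrying its 1-based
    line number — no silent drops.
    """
    records: list[PSMRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != COLUMNS:
            raise PsmParseError(
                f"unexpected header {header!r}; expected {chr(9).join(COLUMNS)!r}",
                line=1,
            )
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(COLUMNS):
                raise PsmParseError(
                    f"expected {len(COLUMNS)} fields, got {len(parts)}", line=line_no
                )
            row = dict(zip(COLUMNS, parts))
            try:
                record = PSMRecord(
                    sample_id=row["sample_id"],
                    donor_id=row["donor_id"],
                    day=row["day"],
                    analyst=row["analyst"],
                    peptide=row["peptide"],
                    charge=int(row["charge"]),
                    xcorr=float(row["xcorr"]),
                    mods=parse_mods(row["mods"]),
                    protein_ids=row["proteins"].split(",") if row["proteins"] else [],
                    is_decoy=_parse_bool(row["is_decoy"]),
                )
            except (ValidationError, ValueError) as exc:
                raise PsmParseError(str(exc), line=line_no) from exc
            records.append(record)
    return records


def write_psm_table(records: Iterable[PSMRecord], path: str | Path) -> None:
    """Write records as the canonical TSV; inverse of :func:`read_psm_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.sample_id,
                        rec.donor_id,
                        rec.day,
                        rec.analyst,
                        rec.peptide,
                        str(rec.charge),
                        repr(rec.xcorr),
                        format_mods(rec.mods),
                        ",".join(rec.protein_ids),
                        "true" if rec.is_decoy else "false",
                    )
                )
                + "\n"
            )
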