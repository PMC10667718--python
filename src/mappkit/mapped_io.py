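"""TSV serialization of mapped peptides.

Columns (exact order)::

    sample_id  donor_id  peptide  chain  start  end  tier  mods  cdrs  unique_flag

``mods`` holds chain-coordinate tokens ``<kind>@<pos>`` with ``?`` for
unlocalized modifications, ``;``-separated.  ``cdrs`` is a ``,``-separated
list of CDR names.  Reading back synthesises a minimal provenance record
(charge/xcorr are placeholders consistent with the stored tier; the tier
column, not the placeholder score, is authoritative downstream).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .errors import PsmParseError
from .identification_filter import ConfidenceTier
from .peptide_mapping import MappedPeptide
from .psm_io import PSMRecord

MAPPED_COLUMNS = (
    "sample_id",
    "donor_id",
    "peptide",
    "chain",
    "start",
    "end",
    "tier",
    "mods",
    "cdrs",
    "unique_flag",
)

# placeholder charge-2 XCorr values reproducing each tier on read-back
_TIER_XCORR = {ConfidenceTier.high: 3.0, ConfidenceTier.medium: 2.1, ConfidenceTier.reject: 0.0}


def write_mapped_table(mapped: Iterable[MappedPeptide], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MAPPED_COLUMNS) + "\n")
        for mp in mapped:
            mods = ";".join(
                f"{kind}@{'?' if pos is None else pos}" for kind, pos in mp.mods
            )
            fh.write(
                "\t".join(
                    (
                        mp.sample_id,
                        mp.donor_id,
                        mp.peptide,
                        mp.chain_id,
                        str(mp.start),
                        str(mp.end),
                        mp.tier.name,
                        mods,
                        ",".join(mp.cdr_overlaps),
                        "true" if mp.unique_to_therapeutic else "false",
                    )
                )
                + "\n"
            )


def read_mapped_table(path: str | Path) -> list[MappedPeptide]:
    mapped: list[MappedPeptide] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != MAPPED_COLUMNS:
            raise PsmParseError(f"unexpected mapped-table header {header!r}", line=1)
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(MAPPED_COLUMNS):
                raise PsmParseError(
                    f"expected {len(MAPPED_COLUMNS)} fields, got {len(parts)}",
                    line=line_no,
                )
            row = dict(zip(MAPPED_COLUMNS, parts))
            try:
                tier = ConfidenceTier[row["tier"]]
                start, end = int(row["start"]), int(row["end"])
                mods: list[tuple[str, int | None]] = []
                if row["mods"]:
                    for tok in row["mods"].split(";"):
                        kind, pos_s = tok.split("@")
                        mods.append((kind, None if pos_s == "?" else int(pos_s)))
                record = PSMRecord(
                    sample_id=row["sample_id"],
                    donor_id=row["donor_id"],
                    day="",
                    analyst="",
                    peptide=row["peptide"],
                    charge=2,
                    xcorr=_TIER_XCORR[tier],
                )
            except (KeyError, ValueError) as exc:
                raise PsmParseError(str(exc), line=line_no) from exc
            if end - start + 1 != len(row["peptide"]):
                raise PsmParseError(
                    f"interval [{start}, {end}] inconsistent with peptide length",
                    line=line_no,
                )
            mapped.append(
                MappedPeptide(
                    record=record,
                    chain_id=row["chain"],
                    start=start,
                    end=end,
                    tier=tier,
                    mods=mods,
                    cdr_overlaps=row["cdrs"].split(",") if row["cdrs"] else [],
                    unique_to_therapeutic=row["unique_flag"].strip().lower() == "true",
                )
            )
    return mapped
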