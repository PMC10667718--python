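"""SVG peptide-coverage heat maps.

Layout: for each chain (HC then LC), a 1-based residue axis with CDR
intervals drawn as a blue band, then one row-group per sample containing
the sample's peptides as blocks spanning [start, end].  Block fill encodes
the confidence tier (dark green high, light green medium); methionine
oxidation is over-marked in purple at its chain position, localized
deamidation in yellow, and unlocalized deamidation as a red outline across
the whole block (no position exists).  Blocks are packed into lanes
first-fit on the start coordinate with a deterministic (start, length,
sequence) tie-break, so rendering the same input twice is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
from xml.sax.saxutils import escape

from .errors import ValidationError
from .identification_filter import ConfidenceTier
from .peptide_mapping import MappedPeptide
from .sequence_model import TherapeuticMolecule


@dataclass
class HeatmapStyle:
    high_color: str = "#1a7a2e"        # dark green: high confidence
    medium_color: str = "#a7d9a0"      # light green: medium confidence
    cdr_color: str = "#2c5fa8"         # blue CDR band
    metox_color: str = "#7b2d8b"       # purple Met-ox mark
    deamidation_color: str = "#e8c412"  # yellow localized deamidation
    unlocalized_color: str = "#cc2222"  # red unlocalized-deamidation outline
    cell_width: float = 6.0
    row_height: float = 10.0
    lane_gap: float = 2.0
    margin: float = 40.0
    axis_height: float = 18.0
    group_gap: float = 14.0
    font_size: float = 9.0

    def __post_init__(self):
        colors = [
            self.high_color,
            self.medium_color,
            self.cdr_color,
            self.metox_color,
            self.deamidation_color,
            self.unlocalized_color,
        ]
        if len(set(colors)) != 6:
            raise ValidationError("heat-map style requires six distinct colors")


def pack_lanes(blocks: Sequence[MappedPeptide]) -> list[list[MappedPeptide]]:
    """First-fit lane packing on start coordinate.

    Blocks are taken in (start, length, sequence) order and placed into the
    first lane whose last block ends before they start; no two blocks in a
    lane overlap horizontally.
    """
    ordered = sorted(blocks, key=lambda mp: (mp.start, mp.length, mp.peptide))
    lanes: list[list[MappedPeptide]] = []
    lane_ends: list[int] = []
    for mp in ordered:
        for i, end in enumerate(lane_ends):
            if mp.start > end:
                lanes[i].append(mp)
                lane_ends[i] = mp.end
                break
        else:
            lanes.append([mp])
            lane_ends.append(mp.end)
    return lanes


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def render_heatmap(
    molecule: TherapeuticMolecule,
    peptides_by_sample: Mapping[str, Sequence[MappedPeptide]],
    style: HeatmapStyle | None = None,
) -> str:
    """Render the coverage heat map for one molecule as an SVG 1.1 string."""
    if style is None:
        style = HeatmapStyle()
    cw, rh = style.cell_width, style.row_height

    for sid, peptides in peptides_by_sample.items():
        for mp in peptides:
            chain = molecule.chain(mp.chain_id)  # raises for unknown chain
            if not (1 <= mp.start <= mp.end <= len(chain)):
                raise ValidationError(
                    f"sample {sid}: peptide {mp.peptide!r} interval "
                    f"[{mp.start}, {mp.end}] not on {molecule.name} {mp.chain_id}"
                )

    sample_ids = sorted(peptides_by_sample)
    parts: list[str] = []
    y = style.margin
    max_chain_len = max(len(c) for c in molecule.chains)
    width = style.margin * 2 + max_chain_len * cw

    for chain in molecule.chains:
        x0 = style.margin
        # chain label + residue axis
        parts.append(
            f'<text x="{_fmt(x0)}" y="{_fmt(y + style.font_size)}" '
            f'font-size="{_fmt(style.font_size)}" class="chain-label">'
            f"{escape(chain.chain_id)}</text>"
        )
        y += style.font_size + 4
        axis_y = y
        parts.append(
            f'<rect x="{_fmt(x0)}" y="{_fmt(axis_y)}" '
            f'width="{_fmt(len(chain) * cw)}" height="{_fmt(style.axis_height / 3)}" '
            f'fill="#d8d8d8" class="axis" data-chain="{chain.chain_id}"/>'
        )
        for cdr in sorted(chain.cdrs, key=lambda c: c.start):
            parts.append(
                f'<rect x="{_fmt(x0 + (cdr.start - 1) * cw)}" y="{_fmt(axis_y)}" '
                f'width="{_fmt(cdr.length * cw)}" height="{_fmt(style.axis_height / 3)}" '
                f'fill="{style.cdr_color}" class="cdr-band" '
                f'data-chain="{chain.chain_id}" data-name="{escape(cdr.name)}" '
                f'data-start="{cdr.start}" data-end="{cdr.end}"/>'
            )
        y = axis_y + style.axis_height

        for sample_id in sample_ids:
            blocks = [
                mp for mp in peptides_by_sample[sample_id] if mp.chain_id == chain.chain_id
            ]
            parts.append(
                f'<text x="{_fmt(4.0)}" y="{_fmt(y + style.font_size)}" '
                f'font-size="{_fmt(style.font_size)}" class="sample-label" '
                f'data-chain="{chain.chain_id}">{escape(sample_id)}</text>'
            )
            lanes = pack_lanes(blocks)
            for lane in lanes:
                for mp in lane:
                    bx = x0 + (mp.start - 1) * cw
                    bw = mp.length * cw
                    fill = (
                        style.high_color
                        if mp.tier >= ConfidenceTier.high
                        else style.medium_color
                    )
                    unlocalized_deam = any(
                        kind == "Deamidation" and pos is None for kind, pos in mp.mods
                    )
                    stroke = (
                        f' stroke="{style.unlocalized_color}" stroke-width="1.5"'
                        if unlocalized_deam
                        else ""
                    )
                    parts.append(
                        f'<rect x="{_fmt(bx)}" y="{_fmt(y)}" width="{_fmt(bw)}" '
                        f'height="{_fmt(rh)}" fill="{fill}"{stroke} class="peptide-block" '
                        f'data-sample="{escape(sample_id)}" data-chain="{mp.chain_id}" '
                        f'data-start="{mp.start}" data-end="{mp.end}" '
                        f'data-peptide="{escape(mp.peptide)}" data-tier="{mp.tier.name}"/>'
                    )
                    for kind, pos in sorted(
                        mp.mods, key=lambda kp: (kp[0], -1 if kp[1] is None else kp[1])
                    ):
                        if pos is None:
                            continue  # unlocalized: rendered as the block outline
                        mark_color = (
                            style.metox_color if kind == "MetOx" else style.deamidation_color
                        )
                        mark_class = "mod-metox" if kind == "MetOx" else "mod-deamidation"
                        parts.append(
                            f'<rect x="{_fmt(x0 + (pos - 1) * cw)}" y="{_fmt(y + rh / 4)}" '
                            f'width="{_fmt(cw)}" height="{_fmt(rh / 2)}" '
                            f'fill="{mark_color}" class="{mark_class}" '
                            f'data-sample="{escape(sample_id)}" data-chain="{mp.chain_id}" '
                            f'data-position="{pos}"/>'
                        )
                y += rh + style.lane_gap
            if not lanes:
                y += rh + style.lane_gap  # keep an empty row for the sample
            y += style.lane_gap
        y += style.group_gap

    height = y + style.margin
    header = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
    )
    return header + "\n".join(parts) + "\n</svg>\n"
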