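"""Quantitative panel outputs: counts, frequencies, concordance, report bundle.

Conventions: "total peptides" for a sample is the number of distinct
accepted peptide sequences, therapeutic plus background (these totals are
large because they are not rescored).  Percent-therapeutic is reported to
2 significant figures; donor frequencies to the nearest integer; cluster
presentation frequencies and concordance to one decimal.  All rounding is
half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._rounding import round_half_up, round_sig_half_up
from .clustering import (
    DEFAULT_MIN_CORE_OVERLAP,
    Cluster,
    build_clusters,
    cluster_presentation_frequency,
    match_clusters_across_runs,
)
from .errors import ValidationError
from .peptide_mapping import LengthStats, MappedPeptide, length_statistics
from .psm_io import MOD_KINDS, PSMRecord


def pct_therapeutic(n_hc: int, n_lc: int, n_total: int) -> float:
    """Percent of total identified peptides attributable to the therapeutic.

    ``100 * (n_hc + n_lc) / n_total`` rounded half-up to 2 significant
    figures.
    """
    if n_hc < 0 or n_lc < 0:
        raise ValidationError("peptide counts must be non-negative")
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if n_hc + n_lc > n_total:
        raise ValidationError("therapeutic peptide count exceeds the total")
    return round_sig_half_up(100.0 * (n_hc + n_lc) / n_total, 2)


@dataclass
class SampleSummary:
    sample_id: str
    donor_id: str
    n_hc_peptides: int
    n_lc_peptides: int
    n_total_peptides: int
    pct_therapeutic: float


def summarize_sample(
    sample_id: str,
    accepted_records: Sequence[PSMRecord],
    mapped_peptides: Sequence[MappedPeptide],
) -> SampleSummary:
    """Per-sample counts over distinct bare peptide sequences.

    A peptide mapping to both chains counts once per chain; the total is
    the distinct accepted sequences in the sample, therapeutic or not.
    """
    sample_records = [r for r in accepted_records if r.sample_id == sample_id]
    total = len({r.peptide for r in sample_records})
    hc = len({mp.peptide for mp in mapped_peptides
              if mp.sample_id == sample_id and mp.chain_id == "HC"})
    lc = len({mp.peptide for mp in mapped_peptides
              if mp.sample_id == sample_id and mp.chain_id == "LC"})
    donor_ids = {r.donor_id for r in sample_records}
    donor_id = sorted(donor_ids)[0] if donor_ids else ""
    pct = pct_therapeutic(hc, lc, total) if total else 0.0
    return SampleSummary(
        sample_id=sample_id,
        donor_id=donor_id,
        n_hc_peptides=hc,
        n_lc_peptides=lc,
        n_total_peptides=total,
        pct_therapeutic=pct,
    )


def modification_donor_frequency(
    mapped_peptides: Iterable[MappedPeptide],
    panel_donors: Sequence[str],
    mod_kind: str,
    region: Cluster | tuple[str, int, int] | None = None,
) -> int:
    """Percent of panel donors with >= 1 accepted therapeutic peptide bearing
    ``mod_kind``, optionally restricted to a cluster or (chain, start, end)
    region; rounded half-up to the nearest integer."""
    if mod_kind not in MOD_KINDS:
        raise ValidationError(f"unknown modification kind {mod_kind!r}")
    if not panel_donors:
        raise ValidationError("empty donor panel")
    if region is None:
        in_region = lambda mp: True  # noqa: E731
    elif isinstance(region, Cluster):
        member_ids = {id(m) for m in region.members}
        in_region = lambda mp: id(mp) in member_ids  # noqa: E731
    else:
        chain_id, start, end = region
        in_region = (  # noqa: E731
            lambda mp: mp.chain_id == chain_id
            and max(mp.start, start) <= min(mp.end, end)
        )
    donors = {
        mp.donor_id
        for mp in mapped_peptides
        if in_region(mp) and any(kind == mod_kind for kind, _ in mp.mods)
    }
    donors &= set(panel_donors)
    return int(round_half_up(100.0 * len(donors) / len(set(panel_donors)), 0))


def replicate_concordance(
    run_a_clusters: Sequence[Cluster],
    run_b_clusters: Sequence[Cluster],
    min_core_overlap: int = DEFAULT_MIN_CORE_OVERLAP,
) -> float:
    """Cluster-level Jaccard agreement between two runs, as a percent.

    ``100 * matched / (|A| + |B| - matched)``, half-up to one decimal.
    Two empty runs agree vacuously (100.0).
    """
    if not run_a_clusters and not run_b_clusters:
        return 100.0
    pairs = match_clusters_across_runs(run_a_clusters, run_b_clusters, min_core_overlap)
    union = len(run_a_clusters) + len(run_b_clusters) - len(pairs)
    return round_half_up(100.0 * len(pairs) / union, 1)


def peptide_concordance(
    run_a_peptides: Iterable[MappedPeptide],
    run_b_peptides: Iterable[MappedPeptide],
) -> float:
    """Secondary metric: Jaccard of bare peptide sequence sets, as a percent."""
    set_a = {mp.peptide for mp in run_a_peptides}
    set_b = {mp.peptide for mp in run_b_peptides}
    if not set_a and not set_b:
        return 100.0
    return round_half_up(100.0 * len(set_a & set_b) / len(set_a | set_b), 1)


@dataclass
class PanelSummary:
    """The quantitative output surface of one donor panel."""

    molecule_name: str
    donor_count: int
    samples: list[SampleSummary]
    clusters: list[Cluster]
    cluster_frequencies: dict[int, float]  # cluster_id -> percent of donors
    modification_frequencies: dict[str, int]  # kind -> percent of donors
    length_stats: LengthStats
    concordance: dict[str, dict[str, float]] = field(default_factory=dict)
    peptide_concordance: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "molecule": self.molecule_name,
            "donor_count": self.donor_count,
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "donor_id": s.donor_id,
                    "n_hc_peptides": s.n_hc_peptides,
                    "n_lc_peptides": s.n_lc_peptides,
                    "n_total_peptides": s.n_total_peptides,
                    "pct_therapeutic": s.pct_therapeutic,
                }
                for s in self.samples
            ],
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "chain": c.chain_id,
                    "core_start": c.core_start,
                    "core_end": c.core_end,
                    "envelope_start": c.envelope_start,
                    "envelope_end": c.envelope_end,
                    "n_peptides": c.n_peptides,
                    "n_donors": len(c.donors_presenting),
                    "frequency_pct": self.cluster_frequencies[c.cluster_id],
                }
                for c in self.clusters
            ],
            "modification_frequencies": dict(sorted(self.modification_frequencies.items())),
            "length_median": self.length_stats.median,
            "length_histogram": {str(k): v for k, v in sorted(self.length_stats.histogram.items())},
            "concordance": self.concordance,
            "peptide_concordance": self.peptide_concordance,
        }


def panel_report(
    molecule_name: str,
    accepted_records: Sequence[PSMRecord],
    mapped_peptides: Sequence[MappedPeptide],
    clusters: Sequence[Cluster],
    panel_donors: Sequence[str] | None = None,
    min_core_overlap: int = DEFAULT_MIN_CORE_OVERLAP,
) -> PanelSummary:
    """Aggregate one panel into a :class:`PanelSummary`.

    Replicate concordance is computed pairwise between samples of the same
    donor (cluster-level Jaccard on per-sample clusterings, plus a
    peptide-level secondary matrix).  Deterministic given the inputs.
    """
    if panel_donors is None:
        panel_donors = sorted({r.donor_id for r in accepted_records})
    donor_count = len(panel_donors)

    sample_ids = sorted({r.sample_id for r in accepted_records})
    samples = [summarize_sample(sid, accepted_records, mapped_peptides) for sid in sample_ids]

    cluster_freqs = {
        c.cluster_id: cluster_presentation_frequency(c, donor_count) if donor_count else 0.0
        for c in clusters
    }
    mod_freqs = {
        kind: modification_donor_frequency(mapped_peptides, panel_donors, kind)
        if donor_count
        else 0
        for kind in MOD_KINDS
    }
    stats = length_statistics(mapped_peptides)

    # replicate concordance between samples sharing a donor
    by_sample: dict[str, list[MappedPeptide]] = {}
    for mp in mapped_peptides:
        by_sample.setdefault(mp.sample_id, []).append(mp)
    sample_clusters = {
        sid: build_clusters(by_sample.get(sid, []), min_core_overlap) for sid in sample_ids
    }
    donor_of = {s.sample_id: s.donor_id for s in samples}
    concordance: dict[str, dict[str, float]] = {}
    pep_concordance: dict[str, dict[str, float]] = {}
    for i, sa in enumerate(sample_ids):
        for sb in sample_ids[i + 1 :]:
            if donor_of[sa] != donor_of[sb]:
                continue
            c = replicate_concordance(sample_clusters[sa], sample_clusters[sb], min_core_overlap)
            p = peptide_concordance(by_sample.get(sa, []), by_sample.get(sb, []))
            concordance.setdefault(sa, {})[sb] = c
            pep_concordance.setdefault(sa, {})[sb] = p

    return PanelSummary(
        molecule_name=molecule_name,
        donor_count=donor_count,
        samples=samples,
        clusters=list(clusters),
        cluster_frequencies=cluster_freqs,
        modification_frequencies=mod_freqs,
        length_stats=stats,
        concordance=concordance,
        peptide_concordance=pep_concordance,
    )


def write_report_bundle(summary: PanelSummary, outdir: str | Path) -> dict[str, Path]:
    """Write summary.json, samples.tsv, clusters.tsv, frequencies.tsv, lengths.tsv.

    Output is byte-deterministic for identical summaries.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["samples"] = outdir / "samples.tsv"
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tdonor_id\tn_hc_peptides\tn_lc_peptides\tn_total_peptides\tpct_therapeutic\n")
        for s in summary.samples:
            fh.write(
                f"{s.sample_id}\t{s.donor_id}\t{s.n_hc_peptides}\t{s.n_lc_peptides}\t"
                f"{s.n_total_peptides}\t{s.pct_therapeutic}\n"
            )

    paths["clusters"] = outdir / "clusters.tsv"
    with open(paths["clusters"], "w") as fh:
        fh.write(
            "cluster_id\tchain\tcore_start\tcore_end\tenvelope_start\tenvelope_end\t"
            "n_peptides\tn_donors\tfrequency_pct\n"
        )
        for c in summary.clusters:
            fh.write(
                f"{c.cluster_id}\t{c.chain_id}\t{c.core_start}\t{c.core_end}\t"
                f"{c.envelope_start}\t{c.envelope_end}\t{c.n_peptides}\t"
                f"{len(c.donors_presenting)}\t{summary.cluster_frequencies[c.cluster_id]}\n"
            )

    paths["frequencies"] = outdir / "frequencies.tsv"
    with open(paths["frequencies"], "w") as fh:
        fh.write("metric\tvalue\n")
        for kind, pct in sorted(summary.modification_frequencies.items()):
            fh.write(f"{kind}_donor_frequency_pct\t{pct}\n")

    paths["lengths"] = outdir / "lengths.tsv"
    with open(paths["lengths"], "w") as fh:
        fh.write("length\tcount\n")
        for ln, count in sorted(summary.length_stats.histogram.items()):
            fh.write(f"{ln}\t{count}\n")

    return paths
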