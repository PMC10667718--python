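"""Nested-set clustering of mapped peptides.

Presented MHC-II peptides share a binding core but carry ragged N/C
termini; a group of such peptides is a cluster (nested set).  Clusters are
built greedily per chain so that every cluster retains a genuine common
core: intervals are sorted by (start, decreasing length); each interval
joins the first cluster whose *current* core it overlaps by at least
``min_core_overlap`` residues (shrinking that core to the intersection),
otherwise it seeds a new cluster.  The default core requirement of 9
residues is the canonical MHC-II binding-core length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._rounding import round_half_up
from .errors import ValidationError
from .peptide_mapping import MappedPeptide

DEFAULT_MIN_CORE_OVERLAP = 9


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of residues shared by two 1-based inclusive intervals (<=0 if disjoint)."""
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


@dataclass
class Cluster:
    """A nested set of mapped peptides sharing a consensus core interval."""

    cluster_id: int
    chain_id: str
    core_start: int
    core_end: int
    envelope_start: int
    envelope_end: int
    members: list[MappedPeptide] = field(default_factory=list)

    @property
    def core(self) -> tuple[int, int]:
        return (self.core_start, self.core_end)

    @property
    def envelope(self) -> tuple[int, int]:
        return (self.envelope_start, self.envelope_end)

    @property
    def donors_presenting(self) -> frozenset[str]:
        return frozenset(mp.donor_id for mp in self.members)

    @property
    def n_peptides(self) -> int:
        """Distinct bare peptide sequences among members."""
        return len({mp.peptide for mp in self.members})


class _ProtoCluster:
    __slots__ = ("core", "intervals")

    def __init__(self, seed: tuple[int, int]):
        self.core = seed
        self.intervals = [seed]


def build_clusters(
    mapped_peptides: Sequence[MappedPeptide],
    min_core_overlap: int = DEFAULT_MIN_CORE_OVERLAP,
) -> list[Cluster]:
    """Partition mapped peptides into nested-set clusters.

    Deterministic given the input; every peptide belongs to exactly one
    cluster.  Cluster ids are ordinal per molecule: HC before LC, then by
    envelope start.
    """
    if min_core_overlap < 1:
        raise ValidationError("min_core_overlap must be >= 1")

    by_chain: dict[str, list[MappedPeptide]] = {}
    for mp in mapped_peptides:
        by_chain.setdefault(mp.chain_id, []).append(mp)

    raw: list[tuple[str, _ProtoCluster]] = []
    for chain_id in sorted(by_chain, key=lambda c: (c != "HC", c)):
        members = by_chain[chain_id]
        intervals = sorted(
            {mp.interval for mp in members},
            key=lambda iv: (iv[0], -(iv[1] - iv[0])),
        )
        protos: list[_ProtoCluster] = []
        for iv in intervals:
            for proto in protos:
                if interval_overlap(iv, proto.core) >= min_core_overlap:
                    proto.core = (
                        max(proto.core[0], iv[0]),
                        min(proto.core[1], iv[1]),
                    )
                    proto.intervals.append(iv)
                    break
            else:
                protos.append(_ProtoCluster(iv))
        raw.extend((chain_id, proto) for proto in protos)

    # assign members and number clusters by (HC first, envelope start)
    clusters: list[Cluster] = []
    for chain_id, proto in raw:
        interval_set = set(proto.intervals)
        members = [
            mp for mp in by_chain[chain_id] if mp.interval in interval_set
        ]
        env_start = min(iv[0] for iv in proto.intervals)
        env_end = max(iv[1] for iv in proto.intervals)
        clusters.append(
            Cluster(
                cluster_id=0,
                chain_id=chain_id,
                core_start=proto.core[0],
                core_end=proto.core[1],
                envelope_start=env_start,
                envelope_end=env_end,
                members=members,
            )
        )
    clusters.sort(key=lambda c: (c.chain_id != "HC", c.chain_id, c.envelope_start, c.core_start))
    for i, cluster in enumerate(clusters, start=1):
        cluster.cluster_id = i
    return clusters


def cluster_presentation_frequency(cluster: Cluster, panel_donor_count: int) -> float:
    """Percent of panel donors presenting >= 1 peptide of the cluster (1 decimal)."""
    if panel_donor_count < 1:
        raise ValidationError("panel_donor_count must be >= 1")
    n_presenting = len(cluster.donors_presenting)
    if n_presenting > panel_donor_count:
        raise ValidationError(
            f"{n_presenting} presenting donors exceeds panel size {panel_donor_count}"
        )
    return round_half_up(100.0 * n_presenting / panel_donor_count, 1)


def match_clusters_across_runs(
    clusters_a: Sequence[Cluster],
    clusters_b: Sequence[Cluster],
    min_core_overlap: int = DEFAULT_MIN_CORE_OVERLAP,
) -> list[tuple[Cluster, Cluster]]:
    """Greedy one-to-one pairing of clusters from two runs.

    Two clusters are matchable iff they sit on the same chain and their
    cores overlap by >= ``min_core_overlap``; pairs are taken in order of
    descending core overlap (ties broken by cluster ids) so the pairing is
    deterministic.
    """
    candidates = []
    for ca in clusters_a:
        for cb in clusters_b:
            if ca.chain_id != cb.chain_id:
                continue
            ov = interval_overlap(ca.core, cb.core)
            if ov >= min_core_overlap:
                candidates.append((ov, ca, cb))
    candidates.sort(key=lambda t: (-t[0], t[1].cluster_id, t[2].cluster_id))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for ov, ca, cb in candidates:
        if id(ca) in used_a or id(cb) in used_b:
            continue
        used_a.add(id(ca))
        used_b.add(id(cb))
        pairs.append((ca, cb))
    return pairs
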