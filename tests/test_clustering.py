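import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mappkit.clustering import (
    build_clusters,
    cluster_presentation_frequency,
    interval_overlap,
    match_clusters_across_runs,
)
from mappkit.errors import ValidationError


def brute_force_components(intervals, min_core_overlap):
    """Oracle: connected components under pairwise overlap >= threshold."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if interval_overlap(intervals[i], intervals[j]) >= min_core_overlap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(intervals[i])
    return list(comps.values())


def common_intersection(intervals):
    lo = max(s for s, _ in intervals)
    hi = min(e for _, e in intervals)
    return (lo, hi) if lo <= hi else None


class TestBuildClusters:
    def test_identical_intervals(self, mapped_factory):
        mapped = mapped_factory([(10, 24)] * 3)
        (cluster,) = build_clusters(mapped)
        assert cluster.core == (10, 24)
        assert cluster.envelope == (10, 24)
        assert len(cluster.members) == 3
        assert cluster.n_peptides == 1  # one distinct sequence

    def test_nested_set_core_shrinks(self, mapped_factory):
        mapped = mapped_factory([(1, 15), (3, 17), (5, 19)])
        (cluster,) = build_clusters(mapped, min_core_overlap=9)
        assert cluster.core == (5, 15)
        assert cluster.envelope == (1, 19)

    def test_disjoint_intervals(self, mapped_factory):
        mapped = mapped_factory([(1, 15), (40, 55)])
        clusters = build_clusters(mapped)
        assert len(clusters) == 2

    def test_partition_property(self, mapped_factory):
        rng = np.random.default_rng(0)
        intervals = []
        for _ in range(40):
            start = int(rng.integers(1, 100))
            intervals.append((start, start + int(rng.integers(9, 20))))
        mapped = mapped_factory(intervals)
        clusters = build_clusters(mapped)
        assigned = [id(mp) for c in clusters for mp in c.members]
        assert sorted(assigned) == sorted(id(mp) for mp in mapped)

    def test_core_contained_in_all_members(self, mapped_factory):
        rng = np.random.default_rng(1)
        intervals = []
        for _ in range(30):
            start = int(rng.integers(1, 80))
            intervals.append((start, start + int(rng.integers(9, 25))))
        for c in build_clusters(mapped_factory(intervals)):
            for mp in c.members:
                assert mp.start <= c.core_start and c.core_end <= mp.end
            assert c.envelope_start == min(mp.start for mp in c.members)
            assert c.envelope_end == max(mp.end for mp in c.members)

    def test_hc_numbered_before_lc(self, mapped_factory):
        mapped = mapped_factory([(60, 75)], chain_id="LC") + mapped_factory(
            [(10, 25)], chain_id="HC"
        )
        clusters = build_clusters(mapped)
        assert [c.chain_id for c in clusters] == ["HC", "LC"]
        assert [c.cluster_id for c in clusters] == [1, 2]

    def test_min_core_overlap_validation(self, mapped_factory):
        with pytest.raises(ValidationError):
            build_clusters(mapped_factory([(1, 12)]), min_core_overlap=0)

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_greedy_refines_component_oracle(self, mapped_factory, data):
        n = data.draw(st.integers(1, 12))
        intervals = []
        for _ in range(n):
            start = data.draw(st.integers(1, 60))
            length = data.draw(st.integers(9, 26))
            intervals.append((start, min(start + length - 1, 110)))
        mapped = mapped_factory(intervals)
        clusters = build_clusters(mapped, min_core_overlap=9)
        components = brute_force_components(
            sorted(set(intervals)), min_core_overlap=9
        )

        def component_of(iv):
            for comp in components:
                if iv in comp:
                    return frozenset(comp)
            raise AssertionError

        for c in clusters:
            comps = {component_of(mp.interval) for mp in c.members}
            assert len(comps) == 1  # refinement: cluster inside one component
        # equality whenever every component has a common core of >= 9 residues
        if all(
            (ci := common_intersection(comp)) and ci[1] - ci[0] + 1 >= 9
            for comp in components
        ):
            greedy_parts = sorted(
                sorted({mp.interval for mp in c.members}) for c in clusters
            )
            oracle_parts = sorted(sorted(comp) for comp in components)
            assert greedy_parts == oracle_parts


class TestPresentationFrequency:
    def _cluster_with_donors(self, mapped_factory, donors):
        mapped = []
        for d in donors:
            mapped += mapped_factory([(10, 24)], donor=d, sample=f"{d}_r1")
        (cluster,) = build_clusters(mapped)
        return cluster

    def test_five_of_seven(self, mapped_factory):
        cluster = self._cluster_with_donors(mapped_factory, [f"D{i}" for i in range(5)])
        assert cluster_presentation_frequency(cluster, 7) == 71.4

    def test_zero_of_seven(self, mapped_factory):
        mapped = mapped_factory([(10, 24)])
        (cluster,) = build_clusters(mapped)
        cluster.members.clear()
        assert cluster_presentation_frequency(cluster, 7) == 0.0

    def test_all_of_eighteen(self, mapped_factory):
        cluster = self._cluster_with_donors(mapped_factory, [f"D{i}" for i in range(18)])
        assert cluster_presentation_frequency(cluster, 18) == 100.0

    def test_zero_panel_errors(self, mapped_factory):
        cluster = self._cluster_with_donors(mapped_factory, ["D1"])
        with pytest.raises(ValidationError):
            cluster_presentation_frequency(cluster, 0)


class TestMatchAcrossRuns:
    def test_identical_sets(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 24), (50, 66)]))
        b = build_clusters(mapped_factory([(10, 24), (50, 66)]))
        pairs = match_clusters_across_runs(a, b)
        assert len(pairs) == 2
        assert all(pa.core == pb.core for pa, pb in pairs)

    def test_shifted_cores_match(self, mapped_factory):
        a = build_clusters(mapped_factory([(73, 92)]))
        b = build_clusters(mapped_factory([(75, 94)]))
        assert len(match_clusters_across_runs(a, b, min_core_overlap=9)) == 1

    def test_different_chains_never_match(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 24)], chain_id="HC"))
        b = build_clusters(mapped_factory([(10, 24)], chain_id="LC"))
        assert match_clusters_across_runs(a, b) == []

    def test_one_to_one(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 30)]))
        b = build_clusters(mapped_factory([(10, 24), (20, 34)]))
        assert len(b) == 2  # both b clusters overlap a's core, but only one may pair
        pairs = match_clusters_across_runs(a, b)
        assert len(pairs) == 1
        # the larger core overlap wins the greedy pairing
        assert pairs[0][1].core == (10, 24)
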