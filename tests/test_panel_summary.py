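import json

import pytest

from mappkit.clustering import build_clusters
from mappkit.errors import ValidationError
from mappkit.identification_filter import FilterConfig, apply_filters
from mappkit.panel_summary import (
    modification_donor_frequency,
    panel_report,
    pct_therapeutic,
    peptide_concordance,
    replicate_concordance,
    write_report_bundle,
)
from mappkit.peptide_mapping import map_records


class TestPctTherapeutic:
    @pytest.mark.parametrize(
        "n_hc,n_lc,n_total,expected",
        [
            (1, 0, 15826, 0.0063),
            (8, 3, 12416, 0.089),
            (5, 2, 12150, 0.058),
            (12, 8, 29428, 0.068),
            (13, 6, 28803, 0.066),
            (14, 5, 29050, 0.065),
        ],
    )
    def test_worked_examples(self, n_hc, n_lc, n_total, expected):
        assert pct_therapeutic(n_hc, n_lc, n_total) == expected

    def test_zero_therapeutic(self):
        assert pct_therapeutic(0, 0, 1000) == 0.0

    def test_documented_convention_on_ambiguous_row(self):
        # (3+8)/25725*100 = 0.04276; half-up at 2 significant figures -> 0.043
        assert pct_therapeutic(3, 8, 25725) == 0.043

    def test_zero_total_errors(self):
        with pytest.raises(ValidationError):
            pct_therapeutic(0, 0, 0)

    def test_counts_exceeding_total_error(self):
        with pytest.raises(ValidationError):
            pct_therapeutic(10, 10, 15)

    def test_monotone_in_therapeutic_count(self):
        for hc in range(0, 50):
            a = 100.0 * (hc + 3) / 10000
            b = 100.0 * (hc + 4) / 10000
            assert b > a  # unrounded value strictly increases


class TestModificationDonorFrequency:
    def _mapped(self, mapped_factory, donor_mods):
        mapped = []
        for donor, mods in donor_mods.items():
            mapped += mapped_factory(
                [(10, 24)], donor=donor, sample=f"{donor}_r1", mods=mods
            )
        return mapped

    def test_eight_of_eighteen(self, mapped_factory):
        donors = [f"D{i:02d}" for i in range(18)]
        donor_mods = {
            d: ([("MetOx", 12)] if i < 8 else []) for i, d in enumerate(donors)
        }
        mapped = self._mapped(mapped_factory, donor_mods)
        assert modification_donor_frequency(mapped, donors, "MetOx") == 44

    def test_two_of_five(self, mapped_factory):
        donors = [f"D{i}" for i in range(5)]
        donor_mods = {
            d: ([("Deamidation", 15)] if i < 2 else []) for i, d in enumerate(donors)
        }
        mapped = self._mapped(mapped_factory, donor_mods)
        assert modification_donor_frequency(mapped, donors, "Deamidation") == 40

    def test_zero(self, mapped_factory):
        donors = ["D1", "D2"]
        mapped = self._mapped(mapped_factory, {d: [] for d in donors})
        assert modification_donor_frequency(mapped, donors, "MetOx") == 0

    def test_empty_panel_errors(self):
        with pytest.raises(ValidationError):
            modification_donor_frequency([], [], "MetOx")

    def test_region_restriction(self, mapped_factory):
        donors = ["D1", "D2"]
        mapped = mapped_factory([(10, 24)], donor="D1", mods=[("MetOx", 12)])
        mapped += mapped_factory([(60, 74)], donor="D2", mods=[("MetOx", 65)])
        assert modification_donor_frequency(mapped, donors, "MetOx") == 100
        assert modification_donor_frequency(
            mapped, donors, "MetOx", region=("HC", 10, 24)
        ) == 50
        (c1, c2) = build_clusters(mapped)
        assert modification_donor_frequency(mapped, donors, "MetOx", region=c1) == 50


class TestReplicateConcordance:
    def test_identical_runs(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 24), (50, 66)]))
        b = build_clusters(mapped_factory([(10, 24), (50, 66)]))
        assert replicate_concordance(a, b) == 100.0

    def test_disjoint_runs(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 24)]))
        b = build_clusters(mapped_factory([(60, 74)]))
        assert replicate_concordance(a, b) == 0.0

    def test_two_matched_of_three(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 24), (50, 66)]))
        b = build_clusters(mapped_factory([(10, 24), (50, 66), (90, 104)]))
        assert replicate_concordance(a, b) == 66.7

    def test_both_empty_vacuous(self):
        assert replicate_concordance([], []) == 100.0

    def test_symmetry(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 24), (50, 66)]))
        b = build_clusters(mapped_factory([(12, 26), (90, 104)]))
        assert replicate_concordance(a, b) == replicate_concordance(b, a)

    def test_100_iff_perfect_matching(self, mapped_factory):
        a = build_clusters(mapped_factory([(10, 24)]))
        b = build_clusters(mapped_factory([(10, 24), (60, 74)]))
        assert replicate_concordance(a, b) < 100.0

    def test_peptide_level_secondary(self, mapped_factory):
        a = mapped_factory([(10, 24), (50, 66)])
        b = mapped_factory([(10, 24)])
        assert peptide_concordance(a, b) == 50.0
        assert peptide_concordance([], []) == 100.0


@pytest.fixture(scope="module")
def report_inputs(small_panel):
    accepted = apply_filters(small_panel.all_records(), FilterConfig())
    mapped = map_records(accepted, small_panel.molecule, small_panel.background_proteome)
    clusters = build_clusters(mapped)
    return accepted, mapped, clusters


class TestPanelReport:
    def test_sample_rows(self, small_panel, report_inputs):
        accepted, mapped, clusters = report_inputs
        summary = panel_report(small_panel.molecule.name, accepted, mapped, clusters)
        assert len(summary.samples) == len(small_panel.samples)
        assert summary.donor_count == len(small_panel.donors)
        for s in summary.samples:
            assert s.n_hc_peptides + s.n_lc_peptides <= s.n_total_peptides
            assert 0.0 <= s.pct_therapeutic <= 100.0

    def test_single_donor_frequencies_degenerate(self, small_panel, report_inputs):
        accepted, mapped, clusters = report_inputs
        donor = small_panel.donors[0]
        acc = [r for r in accepted if r.donor_id == donor]
        mp = [m for m in mapped if m.donor_id == donor]
        cl = build_clusters(mp)
        summary = panel_report(small_panel.molecule.name, acc, mp, cl)
        assert all(v in (0.0, 100.0) for v in summary.cluster_frequencies.values())

    def test_deterministic_bundle(self, small_panel, report_inputs, tmp_path):
        accepted, mapped, clusters = report_inputs
        blobs = []
        for sub in ("a", "b"):
            summary = panel_report(small_panel.molecule.name, accepted, mapped, clusters)
            paths = write_report_bundle(summary, tmp_path / sub)
            blobs.append({k: p.read_bytes() for k, p in paths.items()})
        assert blobs[0] == blobs[1]

    def test_summary_json_is_valid(self, small_panel, report_inputs, tmp_path):
        accepted, mapped, clusters = report_inputs
        summary = panel_report(small_panel.molecule.name, accepted, mapped, clusters)
        paths = write_report_bundle(summary, tmp_path)
        data = json.loads(paths["summary"].read_text())
        assert data["molecule"] == small_panel.molecule.name
        assert len(data["clusters"]) == len(clusters)
        for row in data["clusters"]:
            assert 0.0 <= row["frequency_pct"] <= 100.0
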