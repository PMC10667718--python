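import filecmp
from dataclasses import replace

import numpy as np
import pytest

from mappkit.clustering import build_clusters
from mappkit.errors import ConfigError
from mappkit.identification_filter import FilterConfig, apply_filters, compute_qvalues
from mappkit.peptide_mapping import map_records
from mappkit.synthetic_data import (
    CORE_LENGTH,
    SimulationConfig,
    simulate_panel,
    truth_compare,
)

FAST = dict(background_peptides=200, n_background_proteins=20)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ConfigError):
            SimulationConfig(donor_presentation_prob=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(metox_prob=-0.1)

    def test_core_separation_floor(self):
        with pytest.raises(ConfigError, match="> 25"):
            SimulationConfig(core_min_separation=20)

    def test_charge_probs_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(charge_probs={2: 0.5, 3: 0.4})

    def test_margin_must_cover_extensions(self):
        with pytest.raises(ConfigError, match="margin"):
            SimulationConfig(core_margin=5)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=42, n_donors=2, **FAST)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_panel(cfg).write(d1)
        simulate_panel(cfg).write(d2)
        comparison = filecmp.dircmp(d1, d2)

        def assert_equal(dc):
            assert not dc.diff_files and not dc.left_only and not dc.right_only
            for sub in dc.subdirs.values():
                assert_equal(sub)

        assert_equal(comparison)

    def test_different_seeds_differ(self):
        a = simulate_panel(SimulationConfig(seed=1, n_donors=1, **FAST))
        b = simulate_panel(SimulationConfig(seed=2, n_donors=1, **FAST))
        assert a.molecule.hc.sequence != b.molecule.hc.sequence

    def test_seed_argument_overrides(self):
        cfg = SimulationConfig(seed=1, n_donors=1, **FAST)
        a = simulate_panel(cfg, seed=5)
        b = simulate_panel(SimulationConfig(seed=5, n_donors=1, **FAST))
        assert a.molecule.hc.sequence == b.molecule.hc.sequence


class TestPanelStructure:
    def test_zero_presentation_means_no_therapeutic(self):
        panel = simulate_panel(
            SimulationConfig(seed=3, donor_presentation_prob=0.0, n_donors=2, **FAST)
        )
        assert panel.truth.ladder_peptides == []
        for sid, labels in panel.truth.row_labels.items():
            assert all(core is None for _, core in labels)

    def test_ladder_peptides_contain_planted_core(self):
        panel = simulate_panel(SimulationConfig(seed=4, n_donors=3, **FAST))
        cores = {c.core_id: c for c in panel.truth.planted_cores}
        assert panel.truth.ladder_peptides
        for donor, core_id, chain_id, start, end in panel.truth.ladder_peptides:
            core = cores[core_id]
            assert chain_id == core.chain_id
            assert start <= core.start and core.end <= end
            assert panel.config.min_length <= end - start + 1 <= panel.config.max_length

    def test_background_never_matches_therapeutic(self):
        panel = simulate_panel(SimulationConfig(seed=5, n_donors=1, **FAST))
        hc, lc = panel.molecule.hc.sequence, panel.molecule.lc.sequence
        for sid, labels in panel.truth.row_labels.items():
            for rec, (is_true, core_id) in zip(panel.samples[sid], labels):
                if core_id is None and not rec.is_decoy:
                    assert rec.peptide not in hc and rec.peptide not in lc

    def test_decoy_fraction(self):
        panel = simulate_panel(SimulationConfig(seed=6, n_donors=1, **FAST))
        records = panel.samples["D01_r1"]
        n_decoys = sum(r.is_decoy for r in records)
        assert n_decoys == len(records) - n_decoys  # 0.5 raw decoy fraction

    def test_charges_in_range(self):
        panel = simulate_panel(SimulationConfig(seed=7, n_donors=1, **FAST))
        for rec in panel.samples["D01_r1"]:
            assert 2 <= rec.charge <= 7

    def test_planted_cores_separated(self):
        for seed in range(5):
            panel = simulate_panel(SimulationConfig(seed=seed, n_donors=1, **FAST))
            by_chain = {}
            for c in panel.truth.planted_cores:
                by_chain.setdefault(c.chain_id, []).append(c.start)
            for starts in by_chain.values():
                starts.sort()
                assert all(b - a > 25 for a, b in zip(starts, starts[1:]))

    def test_therapeutic_inventory_independent_of_background_size(self):
        base = SimulationConfig(seed=9, n_donors=2, **FAST)
        a = simulate_panel(base)
        b = simulate_panel(replace(base, background_peptides=0))
        assert a.truth.ladder_peptides == b.truth.ladder_peptides
        assert a.truth.mod_events == b.truth.mod_events

    def test_presentation_fraction_matches_probability(self):
        fractions = []
        for seed in range(50):
            cfg = SimulationConfig(
                seed=seed, n_donors=7, background_peptides=0,
                n_background_proteins=1, donor_presentation_prob=0.7,
            )
            panel = simulate_panel(cfg)
            present = [v for v in panel.truth.presentation.values()]
            fractions.append(np.mean(present))
        assert abs(np.mean(fractions) - 0.7) < 0.1

    def test_median_ladder_length_16(self):
        medians = []
        for seed in range(1, 21):
            cfg = SimulationConfig(seed=seed, background_peptides=0, n_background_proteins=1)
            panel = simulate_panel(cfg)
            lengths = sorted(e - s + 1 for _, _, _, s, e in panel.truth.ladder_peptides)
            medians.append(lengths[(len(lengths) - 1) // 2])
        assert all(15 <= m <= 17 for m in medians)


class TestTruthCompare:
    def _run(self, panel):
        accepted = []
        clusters_by_donor = {}
        for sid in sorted(panel.samples):
            recs = panel.samples[sid]
            accepted.extend(apply_filters(recs, FilterConfig(), compute_qvalues(recs)))
        mapped = map_records(accepted, panel.molecule, panel.background_proteome)
        for donor in panel.donors:
            clusters_by_donor[donor] = build_clusters(
                [mp for mp in mapped if mp.donor_id == donor]
            )
        return accepted, clusters_by_donor

    def test_separable_config_full_recovery(self):
        cfg = SimulationConfig(
            seed=10,
            n_donors=3,
            donor_presentation_prob=1.0,
            replicate_dropout_prob=0.0,
            **FAST,
        )
        panel = simulate_panel(cfg)
        accepted, clusters_by_donor = self._run(panel)
        metrics = truth_compare(panel, accepted, clusters_by_donor)
        assert metrics.cluster_recovery == 1.0
        assert metrics.realized_fdr <= 0.02
        assert metrics.peptide_sensitivity > 0.9

    def test_never_presented_core_excluded_from_denominator(self):
        cfg = SimulationConfig(
            seed=11,
            n_donors=2,
            donor_presentation_prob=1.0,
            presentation_probs={"LC1": 0.0},
            replicate_dropout_prob=0.0,
            **FAST,
        )
        panel = simulate_panel(cfg)
        accepted, clusters_by_donor = self._run(panel)
        metrics = truth_compare(panel, accepted, clusters_by_donor)
        # 2 donors x 2 HC cores; the LC core never enters the denominator
        assert metrics.n_presented == 4
        assert metrics.cluster_recovery == 1.0

    def test_foreign_record_rejected(self, small_panel):
        other = simulate_panel(SimulationConfig(seed=99, n_donors=1, **FAST))
        with pytest.raises(ConfigError):
            truth_compare(small_panel, other.samples["D01_r1"][:1], {})

    def test_realized_fdr_counts_false_targets(self):
        cfg = SimulationConfig(seed=12, n_donors=1, false_target_fraction=0.5, **FAST)
        panel = simulate_panel(cfg)
        records = panel.samples["D01_r1"]
        # accept everything: realized FDR should then be ~ the false fraction
        accepted = [r for r in records if not r.is_decoy]
        metrics = truth_compare(panel, accepted, {})
        assert 0.3 < metrics.realized_fdr < 0.7
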