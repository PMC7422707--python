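"""Generators reproduce their planted truth and are seed-deterministic."""

import numpy as np
import pytest

from mepephos import (
    SimulationConfig,
    Tolerance,
    assign_phospho_ladder,
    classify_major,
    collate_lcms,
    gen_evidence_table,
    gen_ortholog_family,
    gen_peaklist,
    gen_protein,
    max_phospho,
    scan_canonical,
    scan_sxd,
    site_conservation,
)


class TestGenProtein:
    def test_planted_motifs_are_exactly_recovered(self):
        cfg = SimulationConfig(seed=7, length=60, n_sxe=3, n_sxd=0)
        chain, truth = gen_protein(cfg)
        assert len(truth.sxe_positions) == 3
        assert scan_canonical(chain) == set(truth.sxe_positions)

    def test_sxd_plantings_recovered_too(self):
        cfg = SimulationConfig(seed=3, length=120, n_sxe=4, n_sxd=3)
        chain, truth = gen_protein(cfg)
        assert scan_canonical(chain) == set(truth.sxe_positions)
        assert scan_sxd(chain) == set(truth.sxd_positions)

    def test_zero_motifs_scan_empty(self):
        cfg = SimulationConfig(seed=1, length=40, n_sxe=0, n_sxd=0)
        chain, truth = gen_protein(cfg)
        assert scan_canonical(chain) == set()
        assert scan_sxd(chain) == set()

    def test_same_seed_reproduces_sequence(self):
        cfg = SimulationConfig(seed=42, length=80)
        a, _ = gen_protein(cfg)
        b, _ = gen_protein(SimulationConfig(seed=42, length=80))
        assert a.residues == b.residues

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ValueError):
            gen_protein(SimulationConfig(seed=0, length=12, n_sxe=5, n_sxd=5))


class TestGenOrthologFamily:
    def test_zero_substitution_probability_is_fully_conserved(self):
        cfg = SimulationConfig(seed=5, length=40, substitution_prob=0.0)
        chain, truth = gen_protein(cfg)
        aln, _ = gen_ortholog_family(cfg, chain, sorted(truth.sxe_positions))
        for rec in site_conservation(aln, chain.id, sorted(truth.sxe_positions)):
            assert rec.percent == 100

    def test_truth_matches_conservation_module(self):
        cfg = SimulationConfig(seed=11, length=60, substitution_prob=0.2)
        chain, truth = gen_protein(cfg)
        sites = sorted(truth.sxe_positions)
        aln, fam_truth = gen_ortholog_family(cfg, chain, sites)
        for rec in site_conservation(aln, chain.id, sites):
            assert rec.n_match == fam_truth.focal_matches[rec.ref_position]

    def test_substitution_rate_recovered_within_binomial_error(self):
        p = 0.1
        matches = 0
        trials = 0
        for seed in range(30):
            cfg = SimulationConfig(
                seed=seed, length=50, n_sxe=2, n_sxd=0,
                family_size=14, substitution_prob=p,
            )
            chain, truth = gen_protein(cfg)
            sites = sorted(truth.sxe_positions)
            _, fam_truth = gen_ortholog_family(cfg, chain, sites)
            for pos, k in fam_truth.focal_matches.items():
                matches += k - 1  # exclude the never-mutated reference
                trials += 13
        observed = matches / trials
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(observed - (1 - p)) < 4 * se


class TestGenPeaklist:
    def test_noiseless_peaks_recover_truth_exactly(self):
        cfg = SimulationConfig(
            seed=2, mass_sigma=0.0, true_phospho_counts=(0, 2, 5), noise_peak_rate=0.0
        )
        peaks, truth = gen_peaklist(cfg)
        result = assign_phospho_ladder(
            peaks, cfg.base_mass, Tolerance(0.5, relative=False)
        )
        got = {a.observed: a.n_phospho for a in result.assignments}
        assert got == truth.true_k

    def test_noisy_ladders_recover_truth_across_seeds(self):
        # σ = 0.3 Da against a 2 Da window: recovery should be exact
        for seed in range(200):
            cfg = SimulationConfig(
                seed=seed, base_mass=3000.0, mass_sigma=0.3,
                true_phospho_counts=tuple(range(8)), noise_peak_rate=0.0,
            )
            peaks, truth = gen_peaklist(cfg)
            result = assign_phospho_ladder(
                peaks, cfg.base_mass, Tolerance(2.0, relative=False)
            )
            got = {a.observed: a.n_phospho for a in result.assignments}
            assert got == truth.true_k

    def test_noise_only_list_yields_no_assignments(self):
        cfg = SimulationConfig(
            seed=9, true_phospho_counts=(), noise_peak_rate=8.0, mass_sigma=0.0
        )
        peaks, truth = gen_peaklist(cfg)
        assert truth.true_k == {}
        result = assign_phospho_ladder(
            peaks, cfg.base_mass, Tolerance(2.0, relative=False)
        )
        assert result.assignments == ()
        assert max_phospho(result) == 0


class TestGenEvidenceTable:
    def test_collation_recovers_truth_without_ambiguity(self):
        cfg = SimulationConfig(seed=13, length=150, n_sxe=5, n_sxd=3,
                               n_true_sites=6, ambiguity_rate=0.0)
        chain, _ = gen_protein(cfg)
        rows, truth = gen_evidence_table(cfg, chain)
        site_map = collate_lcms(rows, parent_sequence=chain.residues)
        got = {p for e in site_map.entries.values() for p in e.positions}
        assert got == set(truth.true_sites)
        assert truth.ambiguous_pairs == frozenset()

    def test_ambiguous_pairs_counted_once(self):
        cfg = SimulationConfig(seed=21, length=200, n_sxe=6, n_sxd=4,
                               n_true_sites=8, ambiguity_rate=1.0)
        chain, _ = gen_protein(cfg)
        rows, truth = gen_evidence_table(cfg, chain)
        site_map = collate_lcms(rows)
        assert site_map.n_sites == 8
        n_ambiguous = sum(1 for e in site_map.entries.values() if e.ambiguous)
        assert n_ambiguous == len(truth.ambiguous_pairs)

    def test_zero_true_sites_gives_empty_map(self):
        cfg = SimulationConfig(seed=1, length=80, n_true_sites=0)
        chain, _ = gen_protein(cfg)
        rows, truth = gen_evidence_table(cfg, chain)
        assert rows == []
        assert collate_lcms(rows).n_sites == 0

    def test_major_classification_matches_planted_counts(self):
        cfg = SimulationConfig(seed=17, length=150, n_sxe=5, n_sxd=3,
                               n_true_sites=6, ambiguity_rate=0.0, count_mean=15)
        chain, _ = gen_protein(cfg)
        rows, truth = gen_evidence_table(cfg, chain)
        site_map = collate_lcms(rows)
        threshold = 10
        expected = {
            key[0] for key, c in truth.counts.items() if c >= threshold
        }
        assert classify_major(site_map, threshold) == expected

    def test_rows_reference_real_tryptic_peptides(self):
        cfg = SimulationConfig(seed=4, length=120, n_true_sites=5)
        chain, _ = gen_protein(cfg)
        rows, _ = gen_evidence_table(cfg, chain)
        for row in rows:
            assert chain.residues[row.start - 1 : row.end] == row.residues

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=31, length=100, n_true_sites=4)
        chain, _ = gen_protein(cfg)
        rows_a, _ = gen_evidence_table(cfg, chain)
        rows_b, _ = gen_evidence_table(cfg, chain)
        assert rows_a == rows_b
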