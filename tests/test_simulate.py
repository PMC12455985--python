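"""Simulator determinism, truth bookkeeping and statistical calibration."""

import numpy as np
import pytest

from passage_stability import (
    SimConfig,
    classify_sites,
    gene_class_summary,
    scenario_study,
    simulate_annotation,
    simulate_callset,
    simulate_truth,
    validate_callset,
    write_callset,
)
from passage_stability.genome import classify_chromosomes
from passage_stability.simulate import truth_to_tsv


class TestConfig:
    def test_study_design_samples(self):
        cfg = scenario_study()
        assert cfg.sample_names == [
            "HiFi", "P0", "P5.1", "P5.2", "P5.3",
            "P10.1", "P10.2", "P10.3", "P10.4",
        ]
        assert cfg.het_rate == 0.002
        assert cfg.depth_lambda == 27.0
        assert cfg.gq_max == 99

    def test_optional_hifi(self):
        cfg = scenario_study(include_hifi=False)
        assert len(cfg.sample_names) == 8

    def test_chrom_lengths_partition_genome(self):
        cfg = SimConfig(genome_length=999_999, n_chromosomes=5)
        lens = cfg.chrom_lengths
        assert sum(lens.values()) == 999_999
        assert all(v >= 1 for v in lens.values())

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            SimConfig(het_rate=1.5)


class TestTruth:
    def test_empty_when_rates_zero(self):
        cfg = SimConfig(genome_length=10_000, het_rate=0.0, mu=0.0, seed=3)
        truth = simulate_truth(cfg)
        assert not truth.het_sites
        assert all(not m for m in truth.per_sample_mutations.values())

    def test_het_count_within_binomial_bounds(self):
        cfg = SimConfig(genome_length=1_000_000, seed=5)
        truth = simulate_truth(cfg)
        expected = 2000
        sd = np.sqrt(expected * 0.998)
        assert abs(len(truth.het_sites) - expected) < 3 * sd

    def test_mutation_counts_near_poisson_mean(self):
        # expected novel mutations per seed: (3*5 + 4*10) * L * mu = 550
        total = 0
        for seed in range(10):
            cfg = SimConfig(genome_length=1_000_000, mu=1e-5, seed=seed)
            truth = simulate_truth(cfg)
            total += sum(len(m) for m in truth.per_sample_mutations.values())
        expected = 10 * 550
        assert abs(total - expected) < 5 * np.sqrt(expected)

    def test_p0_and_hifi_accumulate_nothing(self):
        cfg = SimConfig(genome_length=100_000, mu=1e-4, seed=1)
        truth = simulate_truth(cfg)
        assert truth.per_sample_mutations["P0"] == {}
        assert truth.per_sample_mutations["HiFi"] == {}

    def test_artifact_and_mutation_classes_disjoint(self):
        cfg = SimConfig(genome_length=200_000, mu=1e-4, artifact_rate=0.05,
                        seed=2)
        truth = simulate_truth(cfg)
        for name in cfg.sample_names:
            muts = set(truth.per_sample_mutations[name])
            assert not muts & truth.artifact_sites[name]
        assert all(p <= cfg.genome_length for p in truth.universe)

    def test_shared_history_mutations_common_to_group(self):
        cfg = SimConfig(genome_length=500_000, mu=5e-5, seed=9,
                        shared_history_passages=5)
        truth = simulate_truth(cfg)
        p10 = [truth.per_sample_mutations[f"P10.{i}"] for i in range(1, 5)]
        shared = set(p10[0]) & set(p10[1]) & set(p10[2]) & set(p10[3])
        # five shared passages at mu*L=25/passage: expect ~125 common sites
        assert len(shared) > 50


class TestCallset:
    def test_determinism_byte_identical(self, tmp_path):
        paths = []
        for run in range(2):
            cfg = scenario_study(seed=1, genome_length=100_000,
                                artifact_rate=0.01, missing_rate=0.01)
            truth = simulate_truth(cfg)
            cs = simulate_callset(truth, cfg)
            p = tmp_path / f"run{run}.vcf"
            write_callset(cs, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seed_differs(self):
        t1 = simulate_truth(SimConfig(genome_length=100_000, seed=1))
        t2 = simulate_truth(SimConfig(genome_length=100_000, seed=2))
        assert set(t1.het_sites) != set(t2.het_sites)

    def test_output_is_valid_and_sorted(self):
        cfg = scenario_study(seed=4, genome_length=200_000,
                            artifact_rate=0.01, missing_rate=0.02)
        cs = simulate_callset(simulate_truth(cfg), cfg)
        assert validate_callset(cs) == []

    def test_clean_run_fixed_sites_match_truth(self):
        """Without artifacts/missingness, the fixed set is exactly the founder
        het sites untouched by any replicate mutation."""
        cfg = SimConfig(genome_length=300_000, mu=2e-5, seed=6)
        truth = simulate_truth(cfg)
        cs = simulate_callset(truth, cfg)
        mutated = set()
        for m in truth.per_sample_mutations.values():
            mutated |= set(m)
        expected_fixed = {
            i for i, pos in enumerate(truth.universe)
            if pos in truth.het_sites and pos not in mutated
        }
        part = classify_sites(cs)
        assert set(part.fixed_sites) == expected_fixed

    def test_single_sample_degenerate(self):
        cfg = SimConfig(genome_length=50_000, include_hifi=False,
                        passages=(("P0", 0, 1),), seed=1)
        cs = simulate_callset(simulate_truth(cfg), cfg)
        assert cs.samples == ["P0"]
        assert validate_callset(cs) == []
        assert all(c.unordered != (0, 0) for s in cs.sites for c in s.calls)

    def test_conservation_every_call_classified_or_homref(self):
        cfg = SimConfig(genome_length=200_000, mu=2e-5, artifact_rate=0.01,
                        seed=8)
        truth = simulate_truth(cfg)
        cs = simulate_callset(truth, cfg)
        # map emitted (chrom, pos) back to global positions in universe order
        universe = truth.universe
        assert len(universe) == cs.n_sites
        for i, site in enumerate(cs.sites):
            pos = universe[i]
            for j, name in enumerate(cs.samples):
                in_mut = pos in truth.per_sample_mutations[name]
                in_art = pos in truth.artifact_sites[name]
                in_het = pos in truth.het_sites
                g = site.calls[j].unordered
                assert in_mut + in_art <= 1
                if not (in_mut or in_art or in_het):
                    assert g in ((0, 0), None)

    def test_artifact_calls_have_depressed_depth(self):
        cfg = SimConfig(genome_length=500_000, artifact_rate=0.02, seed=3)
        truth = simulate_truth(cfg)
        cs = simulate_callset(truth, cfg)
        universe = truth.universe
        art_dp, normal_dp = [], []
        for i, site in enumerate(cs.sites):
            for j, name in enumerate(cs.samples):
                if site.calls[j].depth is None:
                    continue
                if universe[i] in truth.artifact_sites[name]:
                    art_dp.append(site.calls[j].depth)
                else:
                    normal_dp.append(site.calls[j].depth)
        assert np.mean(art_dp) < np.mean(normal_dp) - 5

    def test_truth_tsv_lists_all_classes(self):
        cfg = SimConfig(genome_length=100_000, mu=2e-5, artifact_rate=0.01,
                        seed=2)
        truth = simulate_truth(cfg)
        text = truth_to_tsv(truth)
        assert text.startswith("sample\tposition\tclass\tgenotype")
        assert "\thet\t" in text and "\tmutation\t" in text


class TestAnnotation:
    def test_null_case_ratios_near_one(self):
        sim = simulate_annotation(density_ratio=1.0, intron_scale=1.0,
                                  n_genes=400, seed=1)
        assert sim.truth["realized_density_ratio"] == pytest.approx(1.0, rel=0.1)
        assert sim.truth["realized_intron_scale"] == pytest.approx(1.0, rel=0.1)

    def test_zero_genes_valid_empty_gff(self, tmp_path):
        sim = simulate_annotation(n_genes=0, seed=1)
        p = tmp_path / "e.gff3"
        sim.write_gff(p)
        classes, _ = classify_chromosomes(sim.chrom_lengths)
        out = gene_class_summary(p, classes)
        assert out["macro"].gene_count == 0
        assert out["micro"].gene_count == 0

    def test_gff_parses_and_counts_match_quota(self, tmp_path):
        sim = simulate_annotation(density_ratio=2.0, intron_scale=0.5,
                                  n_genes=200, seed=2)
        p = tmp_path / "a.gff3"
        sim.write_gff(p)
        classes, counts = classify_chromosomes(sim.chrom_lengths)
        assert counts == {"macro": 2, "micro": 8}
        out = gene_class_summary(p, classes)
        assert out["macro"].gene_count == sim.truth["n_macro_genes"]
        assert out["micro"].gene_count == sim.truth["n_micro_genes"]
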