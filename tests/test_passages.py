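"""Site partitioning, private/deviant detection, recoding and the summary table."""

import pytest

from passage_stability import (
    classify_sites,
    compare_private_quality,
    deviant_sites,
    diff_vs_reference,
    passage_table,
    percent_of_genome,
    percent_of_total,
    private_sites,
    recode_genotype,
    recode_matrix,
)
from passage_stability.passages import RECODE_MAP, SENTINEL

from conftest import make_callset


class TestClassify:
    def test_identical_het_is_fixed(self):
        cs = make_callset([["0/1", "0/1", "0/1"]])
        part = classify_sites(cs)
        assert part.fixed_sites == {0} and not part.variable_sites

    def test_one_divergent_sample_is_variable(self):
        cs = make_callset([["0/1", "0/1", "1/1"]])
        assert classify_sites(cs).variable_sites == {0}

    def test_missingness_makes_variable(self):
        cs = make_callset([["0/1", "0/1", "./."]])
        assert classify_sites(cs).variable_sites == {0}

    def test_partition_conserved(self, toy_trio):
        part = classify_sites(toy_trio)
        assert part.n_fixed + part.n_variable == toy_trio.n_sites
        assert not (part.fixed_sites & part.variable_sites)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            classify_sites(make_callset([["0/1"]]))


class TestPrivate:
    def test_single_divergent_genotype(self):
        cs = make_callset([["0/1", "0/1", "1/1"]])
        assert private_sites(cs, "S1") == set()
        assert private_sites(cs, "S2") == set()
        assert private_sites(cs, "S3") == {0}

    def test_three_distinct_genotypes_all_private(self):
        cs = make_callset([["0/1", "1/1", "1/2"]])
        for s in ("S1", "S2", "S3"):
            assert private_sites(cs, s) == {0}

    def test_missing_never_private(self):
        cs = make_callset([["./.", "0/1", "1/1"]])
        assert private_sites(cs, "S1") == set()
        # S2/S3 are private: the missing sample matches nobody
        assert private_sites(cs, "S2") == {0}

    def test_unknown_sample_raises(self, toy_trio):
        with pytest.raises(KeyError):
            private_sites(toy_trio, "nope")


class TestDeviant:
    def test_mode_majority(self):
        cs = make_callset([["0/1", "0/1", "1/1"]])
        assert deviant_sites(cs, "S3") == {0}
        assert deviant_sites(cs, "S1") == set()

    def test_mode_majority_homalt(self):
        cs = make_callset([["0/1", "1/1", "1/1"]])
        assert deviant_sites(cs, "S1") == {0}
        assert deviant_sites(cs, "S2") == set()

    def test_tie_broken_by_smallest_recode(self):
        cs = make_callset([["0/1", "0/1", "1/1", "1/1"]])
        # mode = 0/1 (code 1 < code 2): samples 3 and 4 deviate
        assert deviant_sites(cs, "S1") == set()
        assert deviant_sites(cs, "S3") == {0}
        assert deviant_sites(cs, "S4") == {0}

    def test_no_repeated_genotype_means_all_deviant(self):
        cs = make_callset([["0/1", "1/1", "1/2"]])
        for s in ("S1", "S2", "S3"):
            assert deviant_sites(cs, s) == {0}

    def test_missing_genotype_is_deviant(self):
        cs = make_callset([["0/1", "0/1", "./."]])
        assert deviant_sites(cs, "S3") == {0}
        assert deviant_sites(cs, "S1") == set()

    def test_fixed_sites_never_deviant(self, toy_trio):
        part = classify_sites(toy_trio)
        for s in toy_trio.samples:
            assert deviant_sites(toy_trio, s) <= part.variable_sites


class TestDiff:
    def test_self_is_zero(self, toy_trio):
        for s in toy_trio.samples:
            assert diff_vs_reference(toy_trio, s, s) == 0

    def test_counts_differences(self):
        cs = make_callset([["0/1", "0/1"], ["1/1", "0/1"]])
        assert diff_vs_reference(cs, "S1", "S2") == 1

    def test_one_sided_missing_counts_both_missing_does_not(self):
        cs = make_callset([["./.", "0/1"], ["./.", "./."]])
        assert diff_vs_reference(cs, "S1", "S2") == 1

    def test_symmetric(self, toy_trio):
        for a in toy_trio.samples:
            for b in toy_trio.samples:
                assert (diff_vs_reference(toy_trio, a, b)
                        == diff_vs_reference(toy_trio, b, a))


class TestRecode:
    @pytest.mark.parametrize("pair,code", [
        ((0, 0), 0), ((0, 1), 1), ((1, 1), 2), ((0, 2), 3),
        ((1, 2), 4), ((2, 2), 5), ((0, 3), 6),
    ])
    def test_defined_mapping(self, pair, code):
        assert recode_genotype(pair) == code
        assert recode_genotype(pair[::-1]) == code  # order-insensitive

    @pytest.mark.parametrize("pair", [(3, 3), (1, 3), (2, 3), (0, 4)])
    def test_outside_mapping_is_sentinel(self, pair):
        assert recode_genotype(pair) == SENTINEL

    def test_missing_is_sentinel(self):
        assert recode_genotype(None) == SENTINEL

    def test_bijective_onto_codes(self):
        assert sorted(RECODE_MAP.values()) == list(range(7))
        assert len(set(RECODE_MAP.values())) == len(RECODE_MAP)

    def test_matrix(self):
        cs = make_callset([["0/1", "3/3"], ["./.", "2/0"]])
        mat = recode_matrix(cs)
        assert mat.tolist() == [[1, SENTINEL], [SENTINEL, 3]]


class TestTable:
    def test_identical_to_reference_row(self):
        cs = make_callset([["0/1", "0/1"], ["1/1", "1/1"]])
        rows = passage_table(cs, "S1", genome_size=1000)
        by = {r.sample: r for r in rows}
        assert by["S1"].diff_vs_p0 is None
        assert by["S1"].pct_diff_vs_p0 is None
        assert by["S2"].diff_vs_p0 == 0
        assert by["S2"].pct_diff_vs_p0 == 0.0

    def test_counts_and_percentages(self):
        cs = make_callset([
            ["0/1", "0/1", "0/1", "0/1"],
            ["0/1", "0/1", "0/1", "1/1"],   # S4 deviant+private, {1,1}
            ["0/1", "0/1", "0/1", "0/2"],   # S4 deviant+private, "other"
            ["0/1", "0/1", "0/1", "./."],   # S4 deviant (missing), "other"
        ])
        rows = {r.sample: r for r in passage_table(cs, "S1", genome_size=10_000)}
        r4 = rows["S4"]
        assert r4.nonfixed_count == 3
        assert r4.private_count == 2
        assert r4.het01_count == 0
        assert r4.other_count == 2  # 0/2 and missing; 1/1 excluded
        assert r4.pct_of_genome == percent_of_genome(3, 10_000) == 0.03
        assert r4.diff_vs_p0 == 3
        assert r4.pct_diff_vs_p0 == 75.0
        assert rows["S1"].nonfixed_count == 0

    def test_invariant_private_le_nonfixed(self, toy_trio):
        for row in passage_table(toy_trio, "S1", genome_size=10_000):
            assert row.private_count <= row.nonfixed_count

    def test_median_even_count_is_midpoint(self):
        cs = make_callset([["0/1", "0/1"], ["0/1", "0/1"]],
                          depths=[[10, 1], [21, 1]], quals=[[90, 1], [99, 1]])
        rows = passage_table(cs, "S1", genome_size=1000)
        assert rows[0].median_dp == 15.5
        assert rows[0].median_gq == 94.5

    def test_reference_sample_must_exist(self, toy_trio):
        with pytest.raises(KeyError):
            passage_table(toy_trio, "nope", genome_size=1000)

    def test_rounding_half_to_even(self):
        assert percent_of_total(58_620, 885_159, 2) == 6.62
        assert percent_of_genome(103_086, 1_381_008_983) == 0.0075


class TestCompareQuality:
    def test_needs_both_groups(self):
        cs = make_callset([["0/1", "0/1"]])
        with pytest.raises(ValueError, match="private"):
            compare_private_quality(cs, "S1", "depth")

    def test_depth_comparison_runs(self):
        genos = [["0/1", "0/1", "0/1"]] * 6 + [["0/2", "0/1", "0/1"]]
        depths = [[30, 30, 30]] * 6 + [[2, 30, 30]]
        cs = make_callset(genos, depths=depths)
        res = compare_private_quality(cs, "S1", "depth")
        assert res.n_private == 1 and res.n_other == 6
        assert res.method == "exact"
        assert res.statistic == 0.0

    def test_invalid_metric(self, toy_trio):
        with pytest.raises(ValueError):
            compare_private_quality(toy_trio, "S1", "qd")
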