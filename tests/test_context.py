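"""Gene density, TAD enrichment, loop linking and expression tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seatlas.context import (
    compare_cognate_expression,
    empirical_enrichment_test,
    filter_and_link_loops,
    fraction_within_tads,
    gene_density_windows,
    rank_sum_greater,
    sample_random_nongenic,
)
from seatlas.core import GeneModel, GenomicInterval
from seatlas.se import SuperEnhancer


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


class TestGeneDensity:
    def test_subtraction_formula(self):
        # 3 genes in one 15-kb window, 3,000 bp subtracted -> 3.75
        genes = [gene(f"g{i}", "c1", 1000 * i + 100, 1000 * i + 600) for i in range(3)]
        sub = [iv("c1", 5000, 8000)]
        wins = gene_density_windows(genes, sub, {"c1": 15_000})
        assert wins[0].n_genes == 3
        assert wins[0].subtracted_length == 3000
        assert wins[0].density == pytest.approx(15_000 * 3 / 12_000)

    def test_zero_genes_zero_density(self):
        wins = gene_density_windows([], [iv("c1", 0, 5000)], {"c1": 15_000})
        assert wins[0].density == 0.0

    def test_reduces_to_naive_density_without_subtraction(self):
        genes = [gene(f"g{i}", "c1", 2000 * i, 2000 * i + 500) for i in range(5)]
        wins = gene_density_windows(genes, [], {"c1": 15_000})
        assert wins[0].density == wins[0].n_genes

    def test_fully_covered_window_flagged(self):
        wins = gene_density_windows([], [iv("c1", 0, 20_000)], {"c1": 15_000})
        assert not wins[0].defined


class TestFractionWithinTads:
    def test_whole_chromosome_tad(self):
        regions = [iv("c1", 100, 200), iv("c1", 5000, 6000)]
        assert fraction_within_tads(regions, [iv("c1", 0, 10_000)]) == 1.0

    def test_no_tads(self):
        assert fraction_within_tads([iv("c1", 0, 10)], []) == 0.0

    def test_containment_vs_overlap_rule(self):
        regions = [iv("c1", 900, 1200)]  # straddles the TAD edge at 1000
        tads = [iv("c1", 1000, 5000)]
        assert fraction_within_tads(regions, tads, rule="containment") == 0.0
        assert fraction_within_tads(regions, tads, rule="overlap", min_overlap_frac=0.5) == 1.0

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            fraction_within_tads([], [iv("c1", 0, 10)])


class TestRandomNongenic:
    GENES = [gene("g1", "c1", 10_000, 20_000), gene("g2", "c1", 50_000, 60_000)]

    def test_placements_are_gene_disjoint(self):
        sets = sample_random_nongenic(
            {"c1": 100_000}, self.GENES, [500, 1500, 3000], n_sets=20, seed=3
        )
        for s in sets:
            assert [x.length for x in s] == [500, 1500, 3000]
            for x in s:
                for g in self.GENES:
                    assert (
                        x.end <= g.interval.start or x.start >= g.interval.end
                    ), f"{x} overlaps {g.gene_id}"

    def test_deterministic_given_seed(self):
        a = sample_random_nongenic({"c1": 100_000}, self.GENES, [500] * 5, 3, seed=7)
        b = sample_random_nongenic({"c1": 100_000}, self.GENES, [500] * 5, 3, seed=7)
        assert a == b

    def test_impossible_size_rejected(self):
        with pytest.raises(ValueError):
            sample_random_nongenic({"c1": 100_000}, self.GENES, [90_000], 1, seed=0)


class TestEmpiricalP:
    def test_observed_above_all_999_nulls(self):
        res = empirical_enrichment_test(0.9, [0.1] * 999)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_observed_below_all_nulls(self):
        res = empirical_enrichment_test(0.1, [0.5] * 99, alternative="greater")
        assert res.p_value == 1.0

    def test_never_zero_and_monotone(self):
        nulls = list(np.linspace(0, 1, 99))
        ps = [
            empirical_enrichment_test(obs, nulls).p_value
            for obs in (0.0, 0.25, 0.5, 0.75, 1.01)
        ]
        assert all(p > 0 for p in ps)
        assert ps == sorted(ps, reverse=True)

    def test_uniform_under_the_null(self):
        """Calibration: add-one p on exchangeable draws is ~U(0,1)."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(500):
            draws = rng.random(200)
            ps.append(empirical_enrichment_test(draws[0], draws[1:]).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLoops:
    SES = [SuperEnhancer("se1", iv("c1", 10_000, 13_000), [])]
    GENES = [gene("gA", "c1", 30_000, 33_000)]

    def _loops(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "a1_start", "a1_end", "a2_start", "a2_end", "stat", "fdr"]
        )

    def test_all_high_fdr_filtered(self):
        loops = self._loops([("c1", 10_000, 12_000, 30_000, 32_000, 5.0, 1.0)])
        assert filter_and_link_loops(loops, self.SES, self.GENES).empty

    def test_se_to_promoter_link(self):
        # second anchor hits the 500-bp promoter window upstream of gA
        loops = self._loops([("c1", 11_000, 12_000, 29_600, 29_900, 5.0, 1e-12)])
        out = filter_and_link_loops(loops, self.SES, self.GENES)
        assert out.to_dict("records") == [
            {"se_id": "se1", "gene_id": "gA", "stat": 5.0}
        ]

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            filter_and_link_loops(pd.DataFrame({"chrom": []}), self.SES, self.GENES)

    def test_planted_links_recovered(self, small_run):
        assert small_run.report["context"]["link_recall"] == 1.0


class TestRankSum:
    def test_exact_enumeration_with_ties(self):
        # U = 8.5 for a={3,4,5} vs b={1,2,3}; 2 of the 20 splits reach it
        assert rank_sum_greater([3, 4, 5], [1, 2, 3]) == pytest.approx(2 / 20)

    def test_identical_groups_not_significant(self):
        assert rank_sum_greater([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) >= 0.5

    def test_all_tied_returns_one(self):
        assert rank_sum_greater([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        p = rank_sum_greater(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_greater([], [1.0])

    def test_shifted_cognate_genes_significant_in_every_tissue(self, default_dataset):
        ds = default_dataset
        cognate = sorted(set(ds.truth.cognate_genes.values()))
        others = sorted({g.gene_id for g in ds.genes} - set(cognate))
        ps = compare_cognate_expression(ds.expression, cognate, others)
        assert (ps < 0.01).all()
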