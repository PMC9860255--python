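"""SE calling: clustering, quantile selection, cognate genes and
position classes."""

import math

import numpy as np
import pytest

from seatlas.atlas import ACR
from seatlas.core import GeneModel, GenomicInterval
from seatlas.se import (
    GENIC_EXONIC,
    GENIC_MULTIFEATURE,
    GENIC_SINGLE_INTRON,
    INTERGENIC,
    FIVE_PRIME_OF_A_FLANK,
    THREE_PRIME_OF_BOTH,
    SuperEnhancer,
    assign_cognate_gene,
    classify_se_position,
    cluster_nonpromoter_acrs,
    select_super_enhancers,
    summarize_atlas,
)

from .conftest import brute_force_merge


def acr(start, end, acr_class="nonpromoter", chrom="c1", name=None):
    return ACR(
        name or f"a{start}",
        GenomicInterval(chrom, start, end),
        frozenset({"s1"}),
        acr_class=acr_class,
    )


def se(start, end, chrom="c1"):
    return SuperEnhancer("se1", GenomicInterval(chrom, start, end), [])


class TestClustering:
    def test_chain_of_three(self):
        acrs = [acr(0, 100), acr(110, 200), acr(220, 300)]  # gaps 10 and 20
        clusters = cluster_nonpromoter_acrs(acrs)
        assert len(clusters) == 1
        assert clusters[0].n_constituents == 3
        assert clusters[0].interval == GenomicInterval("c1", 0, 300)

    def test_gap_49_chains_gap_50_does_not(self):
        acrs = [acr(0, 100), acr(149, 200), acr(250, 300)]
        clusters = cluster_nonpromoter_acrs(acrs)
        assert [c.n_constituents for c in clusters] == [2, 1]

    def test_promoter_acrs_excluded(self):
        acrs = [acr(0, 100), acr(110, 200, acr_class="promoter")]
        clusters = cluster_nonpromoter_acrs(acrs)
        assert len(clusters) == 1 and clusters[0].n_constituents == 1

    def test_unclassified_rejected(self):
        with pytest.raises(ValueError):
            cluster_nonpromoter_acrs([acr(0, 100, acr_class=None)])

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_chaining_oracle(self, seed):
        rng = np.random.default_rng(seed)
        acrs = []
        for i in range(int(rng.integers(5, 300))):
            start = int(rng.integers(0, 50_000))
            acrs.append(acr(start, start + int(rng.integers(50, 500)), name=f"a{i}"))
        spans = [c.interval for c in cluster_nonpromoter_acrs(acrs, max_gap=49)]
        oracle = brute_force_merge([a.interval for a in acrs], 49)
        assert spans == oracle


class TestSelection:
    def _clusters(self, lengths, spacing=10_000):
        acrs = []
        for i, L in enumerate(lengths):
            start = i * spacing
            acrs.append(acr(start, start + L, name=f"a{i}"))
        return cluster_nonpromoter_acrs(acrs)

    def test_ceiling_rule_200_clusters(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(100, 5000, size=200).tolist()
        ses, threshold = select_super_enhancers(self._clusters(lengths))
        assert len(ses) == 5  # ceil(0.025 * 200)
        assert threshold == sorted(lengths, reverse=True)[4]
        assert min(s.length for s in ses) == threshold

    def test_all_equal_lengths_tie_by_coordinate(self):
        ses, threshold = select_super_enhancers(self._clusters([300] * 40))
        assert len(ses) == 1
        assert threshold == 300
        assert ses[0].interval.start == 0  # earliest coordinate wins

    def test_single_se_from_40_clusters(self):
        lengths = [100] * 39 + [2000]
        ses, _ = select_super_enhancers(self._clusters(lengths))
        assert len(ses) == 1 and ses[0].length == 2000

    def test_fixed_length_threshold_mode(self):
        lengths = [100] * 30 + [1600, 1700, 2000]
        ses, threshold = select_super_enhancers(
            self._clusters(lengths), length_threshold=1500
        )
        assert threshold == 1500
        assert sorted(s.length for s in ses) == [1600, 1700, 2000]

    def test_threshold_non_increasing_in_top_fraction(self):
        rng = np.random.default_rng(1)
        clusters = self._clusters(rng.integers(100, 5000, size=300).tolist())
        thresholds = [
            select_super_enhancers(clusters, top_fraction=f)[1]
            for f in (0.01, 0.025, 0.1, 0.5)
        ]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_bad_fraction_rejected(self):
        clusters = self._clusters([100, 200])
        for f in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                select_super_enhancers(clusters, top_fraction=f)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_sort_and_ceiling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(50, 8000, size=int(rng.integers(3, 400))).tolist()
        clusters = self._clusters(lengths)
        frac = float(rng.uniform(0.01, 0.3))
        ses, threshold = select_super_enhancers(clusters, top_fraction=frac)
        k = math.ceil(frac * len(lengths))
        assert len(ses) == k
        assert threshold == sorted(lengths, reverse=True)[k - 1]


class TestCognateGene:
    GENES = [
        GeneModel("A", GenomicInterval("c1", 10_000, 12_000, "+")),
        GeneModel("B", GenomicInterval("c1", 20_000, 22_000, "+")),
    ]

    def test_se_inside_gene(self):
        s = se(10_500, 11_000)
        assert assign_cognate_gene(s, self.GENES) == ("A", 0)

    def test_closest_gene_wins(self):
        s = se(12_100, 15_000)  # 100 bp from A, 5 kb from B
        assert assign_cognate_gene(s, self.GENES) == ("A", 100)

    def test_tie_broken_by_tss_distance(self):
        genes = [
            GeneModel("A", GenomicInterval("c1", 0, 1000, "-")),  # TSS at 1000
            GeneModel("B", GenomicInterval("c1", 2100, 3000, "-")),  # TSS at 3000
        ]
        s = se(1100, 2000)  # 100 bp from both bodies; midpoint 1550 closer to A's TSS
        assert assign_cognate_gene(s, genes)[0] == "A"

    def test_gene_free_chromosome_flagged(self):
        s = se(0, 2000, chrom="c9")
        assert assign_cognate_gene(s, self.GENES) == (None, None)


class TestPositionClass:
    HOST = GeneModel(
        "host",
        GenomicInterval("c1", 10_000, 20_000, "+"),
        exons=(
            GenomicInterval("c1", 10_000, 11_000),
            GenomicInterval("c1", 15_000, 16_000),
            GenomicInterval("c1", 19_000, 20_000),
        ),
    )

    def test_se_inside_one_intron(self):
        s = se(12_000, 14_000)
        assert classify_se_position(s, [self.HOST]) == GENIC_SINGLE_INTRON

    def test_se_inside_one_exon(self):
        single_exon = GeneModel(
            "se_gene",
            GenomicInterval("c1", 10_000, 20_000, "+"),
            exons=(GenomicInterval("c1", 10_000, 20_000),),
        )
        s = se(12_000, 14_000)
        assert classify_se_position(s, [single_exon]) == GENIC_EXONIC

    def test_se_spanning_exons_and_intron(self):
        s = se(10_500, 15_500)
        assert classify_se_position(s, [self.HOST]) == GENIC_MULTIFEATURE

    def test_intergenic_three_prime_of_both_convergent(self):
        genes = [
            GeneModel("L", GenomicInterval("c1", 0, 5000, "+")),
            GeneModel("R", GenomicInterval("c1", 20_000, 25_000, "-")),
        ]
        s = se(10_000, 12_000)
        assert classify_se_position(s, genes) == INTERGENIC
        assert s.intergenic_subclass == THREE_PRIME_OF_BOTH

    def test_intergenic_five_prime_of_a_flank(self):
        genes = [
            GeneModel("L", GenomicInterval("c1", 0, 5000, "+")),
            GeneModel("R", GenomicInterval("c1", 20_000, 25_000, "+")),
        ]
        s = se(10_000, 12_000)
        classify_se_position(s, genes)
        assert s.intergenic_subclass == FIVE_PRIME_OF_A_FLANK

    def test_nearest_end_distance(self):
        genes = [GeneModel("L", GenomicInterval("c1", 0, 5000, "+"))]
        s = se(10_000, 12_000)
        classify_se_position(s, genes)
        assert s.nearest_end_distance == 5000  # to the TTS at 5000


class TestSummary:
    def test_percentages_are_exact_integer_arithmetic(self, small_run):
        summary = small_run.summary
        assert summary.n_genic + summary.n_intergenic == summary.n_ses
        assert summary.genic_percent == round(100 * summary.n_genic / summary.n_ses)
        assert 0 <= summary.promoter_fraction <= 1

    def test_disjoint_ses_and_unique_constituents(self, small_run):
        seen = set()
        for s in small_run.ses:
            for c in s.constituents:
                assert c.acr_id not in seen
                seen.add(c.acr_id)
        ivs = sorted((s.interval for s in small_run.ses), key=lambda x: (x.chrom, x.start))
        for a, b in zip(ivs, ivs[1:]):
            assert a.chrom != b.chrom or a.end <= b.start
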