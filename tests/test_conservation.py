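"""Local alignment, synteny status, motif retention and the
conservation report."""

import numpy as np
import pandas as pd
import pytest

from seatlas.conservation import (
    ABSENT,
    SYNTENIC_ADJACENT,
    SYNTENIC_NONADJACENT,
    LocalAlignParams,
    OrthologHit,
    SpanningPair,
    conservation_report,
    local_align,
    motif_retention,
    ortholog_se_search,
    revcomp,
    se_spanning_pairs,
    syntenic_status,
    synteny_maintenance,
)
from seatlas.core import GeneModel, GenomicInterval
from seatlas.se import INTERGENIC, SuperEnhancer
from seatlas.simulate import _random_sequence, mutate_sequence

from .conftest import sw_local_score

PERMISSIVE = LocalAlignParams(min_identity=0.0, min_hit_len=1, max_hits=5)


def rand_seq(length, seed):
    return _random_sequence(length, np.random.default_rng(seed)).tobytes().decode()


class TestLocalAlign:
    def test_identical_sequences_single_perfect_hit(self):
        s = rand_seq(500, 0)
        hits = local_align(s, s)
        assert len(hits) == 1
        h = hits[0]
        assert h.score == 500  # match x length
        assert h.identity == 100.0
        assert (h.query_start, h.query_end) == (0, 500)

    def test_reverse_complement_target_found_on_minus_strand(self):
        s = rand_seq(400, 1)
        hits = local_align(s, revcomp(s))
        assert hits[0].strand == "-"
        assert hits[0].identity == 100.0
        assert (hits[0].target_start, hits[0].target_end) == (0, 400)

    @pytest.mark.parametrize("seed", range(20))
    def test_unrelated_random_sequences_no_hit(self, seed):
        q = rand_seq(300, 1000 + seed)
        t = rand_seq(300, 2000 + seed)
        assert local_align(q, t) == []  # default 70% identity / 30 bp filters

    @pytest.mark.parametrize("seed", range(15))
    def test_score_equals_exhaustive_dp_oracle(self, seed):
        """First-hit score matches a hand-rolled Gotoh local aligner
        on short sequences, over both strands."""
        rng = np.random.default_rng(seed)
        q = rand_seq(int(rng.integers(10, 50)), 3000 + seed)
        t = rand_seq(int(rng.integers(10, 50)), 4000 + seed)
        oracle = max(sw_local_score(q, t), sw_local_score(q, revcomp(t)))
        hits = local_align(q, t, PERMISSIVE)
        if oracle >= 1:
            assert hits, f"oracle score {oracle} but no hit"
            assert max(h.score for h in hits) == pytest.approx(oracle)
        else:
            assert hits == []

    def test_planted_substitutions_identity(self):
        # 200 substitutions in 2 kb -> identity 90 +- 2
        rng = np.random.default_rng(11)
        s = rand_seq(2000, 11)
        pos = rng.choice(2000, size=200, replace=False)
        rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
        lst = list(s)
        for i in pos:
            lst[i] = rotate[lst[i]]
        hit = ortholog_se_search("se", "sp", s, "".join(lst), PERMISSIVE)
        assert abs(hit.identity - 90.0) <= 2.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_n_never_matches(self):
        # an all-N target can never produce a hit
        assert local_align("A" * 40, "N" * 40, PERMISSIVE) == []
        # N columns inside a hit count as mismatches, not matches
        q = rand_seq(60, 71)
        t = q[:30] + "N" * 4 + q[34:]
        hits = local_align(q, t, PERMISSIVE)
        best = max(hits, key=lambda h: h.score)
        assert best.matches <= 56


class TestOrthologSearch:
    def test_unmutated_transplant_full_recovery(self):
        s = rand_seq(1000, 21)
        target = rand_seq(200, 22) + s + rand_seq(200, 23)
        hit = ortholog_se_search("se", "sp", s, target)
        assert hit.aligned_fraction == pytest.approx(100.0, abs=0.5)
        assert hit.identity == pytest.approx(100.0, abs=0.5)

    def test_half_transplanted_half_aligned(self):
        s = rand_seq(2000, 31)
        target = rand_seq(300, 32) + s[500:1500] + rand_seq(300, 33)
        hit = ortholog_se_search("se", "sp", s, target)
        assert abs(hit.aligned_fraction - 50.0) <= 3.0

    def test_no_homology_returns_none(self):
        assert ortholog_se_search("se", "sp", rand_seq(500, 41), rand_seq(800, 42)) is None

    def test_identity_invariant_under_joint_reverse_complement(self):
        s = rand_seq(800, 51)
        target = mutate_sequence(s, 0.1, 0.005, np.random.default_rng(52))
        fwd = ortholog_se_search("se", "sp", s, target)
        rev = ortholog_se_search("se", "sp", revcomp(s), revcomp(target))
        assert rev.identity == pytest.approx(fwd.identity, abs=0.5)
        assert rev.aligned_fraction == pytest.approx(fwd.aligned_fraction, abs=0.5)

    def test_identity_monotone_in_divergence(self):
        s = rand_seq(1500, 61)
        rng = np.random.default_rng(62)
        idents = []
        for rate in (0.02, 0.10, 0.20, 0.30):
            hit = ortholog_se_search(
                "se", "sp", s, mutate_sequence(s, rate, 0.0, rng), PERMISSIVE
            )
            idents.append(hit.identity)
        assert idents == sorted(idents, reverse=True)


class TestSpanningPairs:
    GENES = [
        GeneModel("gL", GenomicInterval("c1", 0, 5000, "+")),
        GeneModel("gR", GenomicInterval("c1", 20_000, 25_000, "-")),
    ]

    def _se(self, start, end, position_class=INTERGENIC):
        s = SuperEnhancer("se1", GenomicInterval("c1", start, end), [])
        s.position_class = position_class
        return s

    def test_pair_is_the_flanking_genes(self):
        pairs, skipped = se_spanning_pairs([self._se(10_000, 12_000)], self.GENES)
        assert skipped == []
        assert (pairs[0].upstream_gene, pairs[0].downstream_gene) == ("gL", "gR")

    def test_genic_se_skipped_with_reason(self):
        pairs, skipped = se_spanning_pairs(
            [self._se(10_000, 12_000, "genic_multifeature")], self.GENES
        )
        assert pairs == [] and "genic" in skipped[0][1]

    def test_chromosome_end_flagged(self):
        genes = [GeneModel("gR", GenomicInterval("c1", 20_000, 25_000, "+"))]
        pairs, skipped = se_spanning_pairs([self._se(10_000, 12_000)], genes)
        assert pairs == [] and "flank" in skipped[0][1]


class TestSyntenicStatus:
    def _annotation(self, order):
        return [
            GeneModel(gid, GenomicInterval("t1", 1000 * i, 1000 * i + 500, "+"))
            for i, gid in enumerate(order)
        ]

    def _table(self, mapping):
        return pd.DataFrame(
            [(q, t, "blk1") for q, t in mapping.items()],
            columns=["query_gene", "target_gene", "block_id"],
        )

    def test_adjacent_partners(self):
        pairs = [SpanningPair("se1", "A", "B")]
        syntenic_status(
            pairs,
            {"sp": self._table({"A": "tA", "B": "tB"})},
            {"sp": self._annotation(["tA", "tB"])},
        )
        assert pairs[0].status["sp"] == SYNTENIC_ADJACENT

    def test_inserted_gene_breaks_adjacency(self):
        pairs = [SpanningPair("se1", "A", "B")]
        syntenic_status(
            pairs,
            {"sp": self._table({"A": "tA", "B": "tB"})},
            {"sp": self._annotation(["tA", "tX", "tB"])},
        )
        assert pairs[0].status["sp"] == SYNTENIC_NONADJACENT

    def test_missing_partner_is_absent(self):
        pairs = [SpanningPair("se1", "A", "B")]
        syntenic_status(
            pairs,
            {"sp": self._table({"A": "tA"})},
            {"sp": self._annotation(["tA"])},
        )
        assert pairs[0].status["sp"] == ABSENT

    def test_unresolvable_partner_rejected(self):
        pairs = [SpanningPair("se1", "A", "B")]
        with pytest.raises(KeyError):
            syntenic_status(
                pairs,
                {"sp": self._table({"A": "tA", "B": "tGhost"})},
                {"sp": self._annotation(["tA"])},
            )


class TestMotifRetention:
    def test_all_retained(self):
        r = motif_retention("se", "sp", ["M1", "M2", "M3", "M4"], ["M1", "M2", "M3", "M4"])
        assert r.retention_rate == 100.0

    def test_three_of_four(self):
        r = motif_retention("se", "sp", ["M1", "M2", "M3", "M4"], ["M1", "M2", "M3"])
        assert r.retention_rate == 75.0

    def test_no_query_motifs_undefined_not_zero(self):
        r = motif_retention("se", "sp", [], ["M1"])
        assert r.retention_rate is None


class TestConservationReport:
    def test_exact_integer_arithmetic_on_fixed_counts(self):
        """312 ortholog hits among 384 syntenic pairs -> 81%; 363
        CNS-containing SEs of 498 -> 73%."""
        n_pairs, n_hits, n_cns = 498, 312, 363
        n_syntenic_sp = 384
        ses = []
        pairs = []
        hits = {"bra": {}}
        cns = []
        for i in range(n_pairs):
            se_id = f"se{i:03d}"
            iv = GenomicInterval("c1", 10_000 * i + 1000, 10_000 * i + 3000)
            ses.append(SuperEnhancer(se_id, iv, []))
            p = SpanningPair(se_id, f"L{i}", f"R{i}")
            # first 384 pairs are syntenic in bra; the rest only in aly
            p.status = {
                "bra": SYNTENIC_ADJACENT if i < n_syntenic_sp else ABSENT,
                "aly": SYNTENIC_ADJACENT,
            }
            pairs.append(p)
            if i < n_syntenic_sp:
                hits["bra"][se_id] = (
                    OrthologHit(se_id, "bra", 80.0, 75.0) if i < n_hits else None
                )
            if i < n_cns:
                cns.append(GenomicInterval("c1", iv.start + 100, iv.start + 300))
        report = conservation_report(pairs, hits, ses, cns)
        assert report["per_species"]["bra"]["n_syntenic_pairs"] == 384
        assert report["per_species"]["bra"]["n_with_ortholog"] == 312
        assert report["per_species"]["bra"]["percent"] == 81
        assert report["n_ses_in_syntenic_pair"] == 498
        assert report["n_ses_with_cns"] == 363
        assert report["cns_percent"] == 73


class TestSyntenyMaintenance:
    def _pairs(self, n, per_species_keep, rng, n_species=5):
        out = []
        for i in range(n):
            p = SpanningPair(f"p{i}", "a", "b")
            p.status = {
                f"sp{j}": SYNTENIC_ADJACENT
                if rng.random() < per_species_keep
                else SYNTENIC_NONADJACENT
                for j in range(n_species)
            }
            out.append(p)
        return out

    def test_extreme_case_minimal_p(self):
        rng = np.random.default_rng(0)
        with_se = self._pairs(10, 1.0, rng)
        without = self._pairs(100, 0.0, rng)
        res = synteny_maintenance(with_se, without, min_species=5, n_resamples=99, seed=1)
        assert res.percent_with == 100.0
        assert res.p_value == pytest.approx(1 / 100)

    def test_planted_gap_detected(self):
        rng = np.random.default_rng(1)
        with_se = self._pairs(100, 0.9, rng)   # ~73% maintain >= 4 of 5
        without = self._pairs(400, 0.65, rng)  # ~43% maintain
        res = synteny_maintenance(with_se, without, min_species=4, n_resamples=1000, seed=2)
        assert res.percent_with - res.percent_without > 15
        assert res.p_value < 0.01

    def test_identical_pools_not_significant(self):
        rng = np.random.default_rng(2)
        pool = self._pairs(300, 0.7, rng)
        res = synteny_maintenance(pool[:50], pool[50:], min_species=4, n_resamples=200, seed=3)
        assert res.p_value > 0.05
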