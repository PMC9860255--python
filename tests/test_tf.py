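"""TF occupancy matrix and odds-ratio enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from seatlas.atlas import ACR
from seatlas.core import GenomicInterval
from seatlas.se import SuperEnhancer
from seatlas.tf import (
    ContingencyTable,
    TFPeakSet,
    acr_classes_with_constituents,
    enrichment_scan,
    motif_catalog,
    tf_counts_per_acr,
    tf_occupancy,
    tf_odds_ratio,
)


def acr(name, start, end, acr_class="nonpromoter"):
    return ACR(name, GenomicInterval("c1", start, end), frozenset({"s"}), acr_class)


class TestOccupancy:
    def test_full_coverage_bound(self):
        acrs = [acr("a1", 1000, 2000)]
        mat = tf_occupancy(acrs, [TFPeakSet("tf1", [GenomicInterval("c1", 500, 2500)])])
        assert bool(mat.loc["a1", "tf1"]) is True

    def test_exactly_half_coverage_is_unbound(self):
        acrs = [acr("a1", 1000, 2000)]
        mat = tf_occupancy(acrs, [TFPeakSet("tf1", [GenomicInterval("c1", 1000, 1500)])])
        assert bool(mat.loc["a1", "tf1"]) is False

    def test_union_coverage_no_double_counting(self):
        # 30% + 30% with 10% overlap -> 50% union -> unbound (strict rule)
        acrs = [acr("a1", 0, 1000)]
        peaks = [GenomicInterval("c1", 0, 300), GenomicInterval("c1", 200, 500)]
        mat = tf_occupancy(acrs, [TFPeakSet("tf1", peaks)])
        assert bool(mat.loc["a1", "tf1"]) is False

    def test_occupancy_monotone_in_peak_set(self):
        acrs = [acr("a1", 0, 1000), acr("a2", 5000, 5400)]
        small = [GenomicInterval("c1", 0, 600)]
        big = small + [GenomicInterval("c1", 5000, 5400)]
        m_small = tf_occupancy(acrs, [TFPeakSet("tf1", small)])
        m_big = tf_occupancy(acrs, [TFPeakSet("tf1", big)])
        assert (m_big["tf1"] >= m_small["tf1"]).all()

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValueError):
            tf_occupancy([], [], min_coverage=1.0)

    def test_counts_are_row_sums(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((20, 7)) < 0.4)
        assert (tf_counts_per_acr(mat).to_numpy() == mat.to_numpy().sum(axis=1)).all()


class TestOddsRatio:
    def test_direct_arithmetic(self):
        orr, lor = tf_odds_ratio(ContingencyTable(30, 10, 20, 40))
        assert orr == pytest.approx(6.0)
        assert lor == pytest.approx(math.log(6.0))

    def test_symmetric_table_gives_unity(self):
        orr, lor = tf_odds_ratio(ContingencyTable(7, 7, 7, 7))
        assert orr == 1.0 and lor == 0.0

    def test_swapping_classes_negates_log_or(self):
        _, lor = tf_odds_ratio(ContingencyTable(30, 10, 20, 40))
        _, swapped = tf_odds_ratio(ContingencyTable(20, 40, 30, 10))
        assert swapped == pytest.approx(-lor)

    def test_haldane_correction_on_zero_cell(self):
        orr, _ = tf_odds_ratio(ContingencyTable(5, 0, 3, 7))
        assert orr == pytest.approx((5.5 / 0.5) / (3.5 / 7.5))

    def test_zero_cell_without_correction_rejected(self):
        with pytest.raises(ValueError):
            tf_odds_ratio(ContingencyTable(5, 0, 3, 7), correction=None)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestEnrichmentScan:
    def _fixture(self):
        rng = np.random.default_rng(1)
        acrs = []
        classes = {}
        for i in range(60):
            name = f"a{i}"
            cls = "constituent" if i < 30 else "promoter"
            acrs.append(name)
            classes[name] = cls
        # planted: tfX binds 80% of constituents, 10% of promoters
        mat = pd.DataFrame(index=pd.Index(acrs, name="acr_id"))
        mat["tfX"] = [rng.random() < (0.8 if i < 30 else 0.1) for i in range(60)]
        mat["tfY"] = [rng.random() < 0.3 for _ in range(60)]
        return mat, pd.Series(classes)

    def test_planted_tf_ranks_first_with_matching_arithmetic(self):
        mat, classes = self._fixture()
        out = enrichment_scan(mat, classes, "constituent", "promoter")
        assert out.iloc[0]["tf_id"] == "tfX"
        row = out[out.tf_id == "tfX"].iloc[0]
        expected, _ = tf_odds_ratio(
            ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d))
        )
        assert row.odds_ratio == pytest.approx(expected)

    def test_class_swap_reverses_all_signs(self):
        mat, classes = self._fixture()
        fwd = enrichment_scan(mat, classes, "constituent", "promoter").set_index("tf_id")
        rev = enrichment_scan(mat, classes, "promoter", "constituent").set_index("tf_id")
        for tf in mat.columns:
            assert rev.loc[tf, "log_odds_ratio"] == pytest.approx(
                -fwd.loc[tf, "log_odds_ratio"]
            )

    def test_empty_class_rejected(self):
        mat, classes = self._fixture()
        with pytest.raises(ValueError):
            enrichment_scan(mat, classes, "constituent", "nosuch")


class TestMotifCatalog:
    SES = [SuperEnhancer("se1", GenomicInterval("c1", 1000, 4000), [])]

    def test_no_hits_in_se(self):
        hits = pd.DataFrame(
            [("M1", "c1", 9000, 9008)], columns=["motif_id", "chrom", "start", "end"]
        )
        assert motif_catalog(self.SES, hits).empty

    def test_distinct_motif_count(self):
        rows = [(f"M{i}", "c1", 1000 + 20 * i, 1008 + 20 * i) for i in range(1, 22)]
        rows.append(("M1", "c1", 2000, 2008))  # duplicate id counts once
        hits = pd.DataFrame(rows, columns=["motif_id", "chrom", "start", "end"])
        out = motif_catalog(self.SES, hits)
        assert out["n_distinct_motifs"].iloc[0] == 21
        assert len(out) == 22


def test_three_way_classes_cover_all_acrs(small_run):
    classes = acr_classes_with_constituents(small_run.acrs, small_run.ses)
    assert set(classes.unique()) <= {"constituent", "promoter", "nonpromoter"}
    assert len(classes) == len(small_run.acrs)
    n_constituent = sum(s.n_constituents for s in small_run.ses)
    assert (classes == "constituent").sum() == n_constituent
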