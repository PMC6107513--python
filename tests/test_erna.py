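"""eRNA locus identification, quantification, and differential calling.

The committed toy fixture under ``tests/data/erna_toy/`` is hand-derived:
12 H3K27ac/H3K4me1 candidate pairs spaced 20 kb on chr1, of which anchors
2, 5 and 8 sit within 2 kb of an exon and are discarded, leaving 9 loci.
Counts were chosen (library 25e6, locus length 1200, so RPKM = count/30)
to plant signed fold changes -3.0, +2.5, +1.5, -2.0, +2.0, plus boundary
loci at RPKM exactly 0.3, below-threshold, all-zero, and null (FC 1).
Exactly the two loci beyond ±2 are differential.
"""

import math

import numpy as np
import pandas as pd
import pytest

from sekit.erna import (
    call_differential,
    classify_by_enhancer,
    identify_erna_loci,
    quantify,
    signed_fold_change,
)
from sekit.intervals import GenomicInterval, IntervalSet
from sekit.io import read_bed

iv = GenomicInterval

TOY_LIBS = {"shCTR": [25_000_000, 25_000_000], "shKD": [25_000_000, 25_000_000]}


def toy_loci(erna_toy_dir):
    h3k27ac = read_bed(erna_toy_dir / "h3k27ac.bed")
    h3k4me1 = read_bed(erna_toy_dir / "h3k4me1.bed")
    exons = list(read_bed(erna_toy_dir / "exons.bed"))
    return identify_erna_loci(h3k27ac, h3k4me1, exons)


class TestIdentify:
    def test_pair_within_window_makes_locus(self):
        h27 = IntervalSet([iv("chr1", 1_000, 1_400)])
        h4 = IntervalSet([iv("chr1", 1_550, 1_650)])  # gap 150 <= 200
        loci = identify_erna_loci(h27, h4, [])
        assert len(loci) == 1
        assert (loci[0].locus.start, loci[0].locus.end) == (600, 1_800)
        assert loci[0].center == 1_200

    def test_padded_exon_discards_anchor(self):
        h27 = IntervalSet([iv("chr1", 1_000, 1_400)])
        h4 = IntervalSet([iv("chr1", 1_550, 1_650)])
        exon = [iv("chr1", 2_500, 2_600)]  # padded [500, 4600) overlaps anchor
        assert identify_erna_loci(h27, h4, exon) == []

    def test_no_partner_no_locus(self):
        h27 = IntervalSet([iv("chr1", 1_000, 1_400)])
        h4 = IntervalSet([iv("chr1", 2_000, 2_100)])  # gap 600
        assert identify_erna_loci(h27, h4, []) == []

    def test_locus_clipped_at_chromosome_start(self):
        h27 = IntervalSet([iv("chr1", 0, 400)])
        h4 = IntervalSet([iv("chr1", 450, 500)])
        locus = identify_erna_loci(h27, h4, [])[0].locus
        assert (locus.start, locus.end) == (0, 800)

    def test_toy_fixture_yields_nine_loci(self, erna_toy_dir):
        loci = toy_loci(erna_toy_dir)
        assert len(loci) == 9
        surviving = [0, 1, 3, 4, 6, 7, 9, 10, 11]
        expected_keys = [
            f"chr1:{10_000 + 20_000 * i - 100}-{10_000 + 20_000 * i + 1_100}"
            for i in surviving
        ]
        assert [l.key for l in loci] == expected_keys
        assert all(len(l.locus) == 1_200 for l in loci)


class TestQuantify:
    def test_replicate_mean_closed_form(self):
        h27 = IntervalSet([iv("chr1", 1_000, 1_400)])
        h4 = IntervalSet([iv("chr1", 1_450, 1_500)])
        loci = identify_erna_loci(h27, h4, [])
        counts = pd.DataFrame(
            {"c_rep1": [10], "c_rep2": [14]}, index=pd.Index([loci[0].key], name="locus")
        )
        quantify(loci, counts, {"c": [1_000_000, 1_000_000]})
        assert loci[0].rpkm["c"] == pytest.approx(10.0)  # (8.333 + 11.667)/2

    def test_missing_replicate_names_condition(self):
        h27 = IntervalSet([iv("chr1", 1_000, 1_400)])
        h4 = IntervalSet([iv("chr1", 1_450, 1_500)])
        loci = identify_erna_loci(h27, h4, [])
        counts = pd.DataFrame({"c_rep1": [10]}, index=pd.Index([loci[0].key], name="locus"))
        with pytest.raises(ValueError, match="'c'"):
            quantify(loci, counts, {"c": [1_000_000, 1_000_000]})

    def test_matches_formula_on_random_counts(self, rng):
        h27 = IntervalSet([iv("chr1", 10_000 * i, 10_000 * i + 1_000) for i in range(1, 20)])
        h4 = IntervalSet([iv("chr1", 10_000 * i + 1_050, 10_000 * i + 1_150) for i in range(1, 20)])
        loci = identify_erna_loci(h27, h4, [])
        c1 = rng.integers(0, 500, size=len(loci))
        c2 = rng.integers(0, 500, size=len(loci))
        counts = pd.DataFrame(
            {"x_rep1": c1, "x_rep2": c2}, index=pd.Index([l.key for l in loci], name="locus")
        )
        libs = [17_000_000, 23_000_000]
        quantify(loci, counts, {"x": libs})
        for l, a, b in zip(loci, c1, c2):
            expected = (a * 1e9 / (1_200 * libs[0]) + b * 1e9 / (1_200 * libs[1])) / 2
            assert l.rpkm["x"] == pytest.approx(expected, rel=1e-12)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "ctrl,kd,expected",
        [
            (1.0, 0.4, -2.5),
            (1.0, 2.0, 2.0),
            (2.0, 2.0, 1.0),
            (0.0, 1.0, math.inf),
            (1.0, 0.0, -math.inf),
        ],
    )
    def test_conventions(self, ctrl, kd, expected):
        assert signed_fold_change(ctrl, kd) == expected

    def test_both_zero_is_null(self):
        assert signed_fold_change(0.0, 0.0) is None


class TestCallDifferential:
    def test_toy_fixture_exactly_two_differential(self, erna_toy_dir):
        loci = toy_loci(erna_toy_dir)
        counts = pd.read_csv(erna_toy_dir / "counts.tsv", sep="\t", index_col="locus")
        quantify(loci, counts, TOY_LIBS)
        call_differential(loci, "shCTR", "shKD")
        by_key = {l.key: l for l in loci}
        diff = [l.key for l in loci if l.is_differential]
        assert diff == ["chr1:9900-11100", "chr1:29900-31100"]
        assert by_key["chr1:9900-11100"].fold_change == pytest.approx(-3.0)
        assert by_key["chr1:29900-31100"].fold_change == pytest.approx(2.5)

    def test_toy_boundaries_strict(self, erna_toy_dir):
        loci = toy_loci(erna_toy_dir)
        counts = pd.read_csv(erna_toy_dir / "counts.tsv", sep="\t", index_col="locus")
        quantify(loci, counts, TOY_LIBS)
        call_differential(loci, "shCTR", "shKD")
        by_key = {l.key: l for l in loci}
        # fold change exactly ±2 is not differential
        assert by_key["chr1:89900-91100"].fold_change == -2.0
        assert not by_key["chr1:89900-91100"].is_differential
        assert by_key["chr1:129900-131100"].fold_change == 2.0
        assert not by_key["chr1:129900-131100"].is_differential
        # RPKM exactly 0.3 in both conditions is not expressed
        assert by_key["chr1:149900-151100"].rpkm["shCTR"] == 0.3
        assert not by_key["chr1:149900-151100"].expressed
        # all-zero locus: not expressed, null fold change
        assert by_key["chr1:209900-211100"].fold_change is None
        assert not by_key["chr1:209900-211100"].expressed
        # below-threshold locus excluded despite 2x ratio
        assert not by_key["chr1:189900-191100"].expressed
        # differential implies expressed, everywhere
        assert all(l.expressed for l in loci if l.is_differential)

    def test_monotone_in_rpkm_min(self, erna_toy_dir):
        loci = toy_loci(erna_toy_dir)
        counts = pd.read_csv(erna_toy_dir / "counts.tsv", sep="\t", index_col="locus")
        quantify(loci, counts, TOY_LIBS)
        prev = None
        for rpkm_min in (0.0, 0.3, 1.0, 3.0):
            call_differential(loci, "shCTR", "shKD", rpkm_min=rpkm_min)
            now = {l.key for l in loci if l.is_differential}
            if prev is not None:
                assert now <= prev
            prev = now


class TestClassifyByEnhancer:
    def _loci(self):
        h27 = IntervalSet([iv("chr1", 10_000, 11_000), iv("chr1", 50_000, 51_000)])
        h4 = IntervalSet([iv("chr1", 11_050, 11_150), iv("chr1", 51_050, 51_150)])
        return identify_erna_loci(h27, h4, [])

    def test_labels(self):
        loci = self._loci()
        ses = IntervalSet([iv("chr1", 9_000, 12_000)])
        tes = IntervalSet([iv("chr1", 100_000, 101_000)])
        classify_by_enhancer(loci, ses, tes)
        assert [l.enhancer_class for l in loci] == ["super", "none"]

    def test_overlapping_se_te_rejected(self):
        ses = IntervalSet([iv("chr1", 0, 1_000)])
        tes = IntervalSet([iv("chr1", 500, 1_500)])
        with pytest.raises(ValueError, match="disjoint"):
            classify_by_enhancer(self._loci(), ses, tes)

    def test_matches_overlap_oracle(self, rng):
        loci = []
        h27 = IntervalSet(
            [iv("chr1", int(s), int(s) + 1_000) for s in rng.integers(0, 1_000_000, 40)]
        )
        h4 = IntervalSet([iv("chr1", p.end + 50, p.end + 150) for p in h27])
        loci = identify_erna_loci(h27, h4, [])
        ses = IntervalSet([iv("chr1", 0, 300_000)])
        tes = IntervalSet([iv("chr1", 600_000, 900_000)])
        classify_by_enhancer(loci, ses, tes)
        for l in loci:
            if l.locus.start < 300_000:
                assert l.enhancer_class == "super"
            elif 600_000 < l.locus.end and l.locus.start < 900_000:
                assert l.enhancer_class == "typical"
            else:
                assert l.enhancer_class == "none"
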