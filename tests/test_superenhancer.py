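"""Stitching, ranking, the hockey-stick cutoff, and SE target assignment."""

import numpy as np
import pytest

from sekit.intervals import GenomicInterval, IntervalSet
from sekit.io import ExpressionTable, GeneModel
from sekit.signal import CoverageTrack
from sekit.simulate import LandscapeConfig, make_genome, make_landscape
from sekit.superenhancer import (
    StitchedRegion,
    assign_se_targets,
    build_stitched_enhancers,
    classify,
    expressed_genes,
    se_cutoff,
)

iv = GenomicInterval


def _flat_track(value=1.0, length=100_000, lib=1_000_000):
    return CoverageTrack.from_steps({"chr1": [(0, length, value)]}, library_size=lib)


class TestBuildStitchedEnhancers:
    def test_cluster_plus_isolated(self):
        peaks = IntervalSet(
            [
                iv("chr1", 1_000, 2_000),
                iv("chr1", 6_000, 7_000),
                iv("chr1", 12_000, 13_000),
                iv("chr1", 60_000, 61_000),
            ]
        )
        out = build_stitched_enhancers(peaks, _flat_track())
        assert sorted(r.n_constituents for r in out) == [1, 3]

    def test_far_apart_one_region_per_peak(self):
        peaks = IntervalSet([iv("chr1", i * 20_000, i * 20_000 + 500) for i in range(1, 5)])
        out = build_stitched_enhancers(peaks, _flat_track())
        assert len(out) == 4

    def test_tied_signals_ranked_by_coordinate(self):
        peaks = IntervalSet([iv("chr1", 40_000, 41_000), iv("chr1", 20_000, 21_000)])
        out = build_stitched_enhancers(peaks, _flat_track())
        assert [r.rank for r in sorted(out, key=lambda r: r.region.start)] == [1, 2]

    def test_empty_input(self):
        assert build_stitched_enhancers(IntervalSet(), _flat_track()) == []


class TestSeCutoff:
    def test_quadratic_analytic_tangent(self):
        # y = x^2: the unit-slope tangent touches at x = 0.5, y = 0.25
        signals = [(i / 1000) ** 2 for i in range(1001)]
        cutoff = se_cutoff(signals)
        assert cutoff == pytest.approx(0.25, abs=0.02)
        n_super = sum(s / max(signals) > cutoff for s in signals)
        assert abs(n_super - 500) <= 10

    def test_linear_curve_no_supers(self):
        signals = [i / 1000 for i in range(1001)]
        assert se_cutoff(signals) == 1.0  # slopes exactly 1, strict > fails

    def test_all_equal_no_supers(self):
        with pytest.warns(UserWarning, match="all signals equal"):
            assert se_cutoff([5.0] * 10) == 1.0

    def test_too_few_signals_rejected(self):
        with pytest.raises(ValueError):
            se_cutoff([1.0, 2.0])

    def test_scale_invariance(self, rng):
        signals = np.concatenate(
            [rng.uniform(1, 10, size=200), rng.uniform(500, 1_000, size=20)]
        )
        c1 = se_cutoff(signals)
        c2 = se_cutoff(signals * 37.5)
        assert c1 == pytest.approx(c2, rel=1e-12)


def _regions_from_signals(signals):
    regions = [
        StitchedRegion(
            region=iv("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 500),
            constituents=(),
            signal=float(s),
        )
        for i, s in enumerate(signals)
    ]
    regions.sort(key=lambda r: (-r.signal, r.region.start))
    for i, r in enumerate(regions, 1):
        r.rank = i
    return regions


class TestClassify:
    def test_planted_bimodal_recovered(self, default_landscape):
        ls = default_landscape
        regions = build_stitched_enhancers(ls.h3k27ac_intervals, ls.track, ls.control_track)
        supers, typicals = classify(regions)
        planted = {(r.chrom, r.start, r.end) for r in ls.manifest.se_regions}
        called = {(r.region.chrom, r.region.start, r.region.end) for r in supers}
        assert called == planted
        assert len(typicals) == ls.config.n_te

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        regions = _regions_from_signals(rng.uniform(0, 100, size=50))
        supers, typicals = classify(regions)
        assert len(supers) + len(typicals) == 50
        assert not ({id(r) for r in supers} & {id(r) for r in typicals})

    def test_no_regions(self):
        assert classify([]) == ([], [])

    def test_input_order_invariance(self, rng):
        signals = rng.uniform(0, 100, size=40)
        a = _regions_from_signals(signals)
        b = list(a)
        rng.shuffle(b)
        sup_a = {r.region for r in classify(a)[0]}
        sup_b = {r.region for r in classify(b)[0]}
        assert sup_a == sup_b


class TestExpressedGenes:
    def _table(self, **genes):
        return ExpressionTable(
            values={g: {"c1": list(v[0]), "c2": list(v[1])} for g, v in genes.items()},
            conditions=["c1", "c2"],
        )

    def test_expressed_in_one_condition(self):
        t = self._table(g1=((1.5, 2.0), (0.1, 0.1)))
        assert expressed_genes(t) == {"g1"}

    def test_union_over_conditions(self):
        t = self._table(g1=((0.5, 3.0), (1.2, 1.1)))
        assert expressed_genes(t) == {"g1"}

    def test_strict_threshold(self):
        t = self._table(g1=((1.0, 5.0), (1.0, 0.2)))
        assert expressed_genes(t) == set()

    def test_protein_coding_restriction(self):
        t = self._table(g1=((5, 5), (5, 5)), g2=((5, 5), (5, 5)))
        genes = [
            GeneModel("g1", "chr1", "+", iv("chr1", 0, 100, "+"), (), "protein_coding"),
            GeneModel("g2", "chr1", "+", iv("chr1", 200, 300, "+"), (), "pseudogene"),
        ]
        assert expressed_genes(t, genes) == {"g1"}


def _se(start, end, chrom="chr1"):
    r = iv(chrom, start, end)
    return StitchedRegion(region=r, constituents=(r,), signal=1.0)


def _gene(gid, start, end, chrom="chr1", strand="+"):
    return GeneModel(gid, chrom, strand, iv(chrom, start, end, strand, name=gid), ())


class TestAssignSeTargets:
    GENES = [
        _gene("near", 700_000, 710_000),
        _gene("far", 760_000, 770_000),
        _gene("inside", 520_000, 530_000),
    ]

    def test_nearest_within_cap_retained(self):
        out = assign_se_targets([_se(500_000, 550_000)], self.GENES[:2], {"near", "far"})
        assert out[0].genes == (("near", 150_000),)

    def test_beyond_cap_excluded(self):
        genes = [_gene("g", 760_001, 770_000)]
        out = assign_se_targets([_se(500_000, 550_000)], genes, {"g"})
        assert out[0].genes == ()  # gap 210 001 > 200 kb

    def test_overlapping_gene_distance_zero(self):
        out = assign_se_targets([_se(500_000, 550_000)], self.GENES, {"inside", "near"})
        assert ("inside", 0) in out[0].genes and ("near", 150_000) in out[0].genes

    def test_non_expressed_invisible(self):
        # only "far" expressed: nearest downstream at gap 210 kb, beyond the cap
        out = assign_se_targets([_se(500_000, 550_000)], self.GENES, {"far"})
        assert out[0].genes == ()

    def test_unknown_expressed_id_rejected(self):
        with pytest.raises(ValueError, match="absent from gene models"):
            assign_se_targets([_se(0, 10)], self.GENES, {"ghost"})

    def test_matches_brute_force_scan(self, rng):
        genes = []
        for i in range(60):
            s = int(rng.integers(0, 2_000_000))
            genes.append(_gene(f"g{i}", s, s + int(rng.integers(1_000, 30_000))))
        expressed = {g.gene_id for g in genes if rng.random() < 0.6}
        ses = [
            _se(int(s), int(s) + 25_000)
            for s in rng.integers(0, 2_000_000, size=25).tolist()
        ]
        out = assign_se_targets(ses, genes, expressed)
        for a in out:
            se = a.se.region
            exp = {}
            best_up = best_down = None
            for g in genes:
                if g.gene_id not in expressed:
                    continue
                b = g.body
                ol = min(se.end, b.end) - max(se.start, b.start)
                if ol >= 1:
                    exp[g.gene_id] = 0
                elif b.end <= se.start:
                    gap = se.start - b.end
                    if best_up is None or gap < best_up[1] or (gap == best_up[1] and b.start < best_up[2]):
                        best_up = (g.gene_id, gap, b.start)
                else:
                    gap = b.start - se.end
                    if best_down is None or gap < best_down[1] or (gap == best_down[1] and b.start < best_down[2]):
                        best_down = (g.gene_id, gap, b.start)
            if best_up and best_up[1] <= 200_000:
                exp[best_up[0]] = -best_up[1]
            if best_down and best_down[1] <= 200_000:
                exp[best_down[0]] = best_down[1]
            assert dict(a.genes) == exp


class TestCutoffRecoveryAcrossSeeds:
    def test_jaccard_over_20_seeds(self):
        """Planted SE sets recovered with >= 95% mean Jaccard over 20 seeds."""
        jaccards = []
        for seed in range(1, 21):
            cfg = LandscapeConfig(seed=seed)
            ls = make_landscape(cfg, make_genome(cfg))
            regions = build_stitched_enhancers(ls.h3k27ac_intervals, ls.track, ls.control_track)
            supers, _ = classify(regions)
            planted = {(r.chrom, r.start, r.end) for r in ls.manifest.se_regions}
            called = {(r.region.chrom, r.region.start, r.region.end) for r in supers}
            jaccards.append(len(planted & called) / len(planted | called))
        assert float(np.mean(jaccards)) >= 0.95
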