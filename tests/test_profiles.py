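import numpy as np
import pytest

from colocscreen.profiles import (
    aggregate_profile,
    metagene_profile,
    peak_center,
    region_density,
    rpkm_normalize,
)
from colocscreen.types import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    PipelineUsageError,
)

from conftest import make_peak

SIZES = {"chrA": 100_000}


def constant_track(value, sizes=SIZES):
    return CoverageTrack(
        [(c, 0, L, value) for c, L in sizes.items()], chrom_sizes=sizes
    )


class TestPeakCenter:
    @pytest.mark.parametrize(
        "start, end, summit, expected",
        [
            (100, 200, 50, 150),   # summit wins
            (100, 200, -1, 150),   # midpoint
            (100, 201, -1, 150),   # floor tie-break
            (100, 200, 0, 100),
        ],
    )
    def test_center_rule(self, start, end, summit, expected):
        assert peak_center(make_peak("c", start, end, summit=summit)) == expected


class TestAggregateProfile:
    def test_constant_track_gives_constant_profile(self):
        track = constant_track(3.5)
        pm = aggregate_profile(track, [("chrA", 50_000), ("chrA", 20_000)], 2000, 50)
        assert np.allclose(pm.values, 3.5)
        assert np.allclose(pm.mean_curve, 3.5)

    def test_rectangular_bump_fills_central_bins_only(self):
        # bump covering exactly the central two bins of a 2000/500 profile
        track = CoverageTrack([("chrA", 49_500, 50_500, 7.0)], chrom_sizes=SIZES)
        pm = aggregate_profile(track, [("chrA", 50_000)], 2000, 500)
        expected = np.array([0, 0, 0, 7.0, 7.0, 0, 0, 0])
        assert np.allclose(pm.values[0], expected)

    def test_partial_bin_is_length_weighted(self):
        track = CoverageTrack([("chrA", 49_750, 50_000, 4.0)], chrom_sizes=SIZES)
        pm = aggregate_profile(track, [("chrA", 50_000)], 2000, 500)
        assert pm.values[0][3] == pytest.approx(4.0 * 250 / 500)

    def test_out_of_bounds_anchor_dropped_and_counted(self):
        track = constant_track(1.0)
        pm = aggregate_profile(track, [("chrA", 500), ("chrA", 50_000)], 2000, 50)
        assert pm.n_anchors == 1
        assert pm.n_dropped == 1

    def test_all_anchors_dropped_is_error(self):
        with pytest.raises(PipelineUsageError):
            aggregate_profile(constant_track(1.0), [("chrA", 10)], 2000, 50)

    def test_unknown_chromosome_is_error(self):
        from colocscreen.types import GenomicDataError

        with pytest.raises(GenomicDataError):
            aggregate_profile(constant_track(1.0), [("chrZ", 50_000)], 2000, 50)

    def test_linearity_in_the_track(self):
        rng = np.random.default_rng(0)
        edges = np.arange(0, 100_001, 100)
        vx = rng.uniform(0, 5, len(edges) - 1)
        vy = rng.uniform(0, 5, len(edges) - 1)
        mk = lambda v: CoverageTrack(
            [("chrA", int(s), int(e), float(val))
             for s, e, val in zip(edges[:-1], edges[1:], v)],
            chrom_sizes=SIZES,
        )
        anchors = [("chrA", int(a)) for a in rng.integers(3_000, 97_000, 20)]
        px = aggregate_profile(mk(vx), anchors, 2000, 50).values
        py = aggregate_profile(mk(vy), anchors, 2000, 50).values
        pxy = aggregate_profile(mk(2 * vx + 3 * vy), anchors, 2000, 50).values
        assert np.allclose(pxy, 2 * px + 3 * py, atol=1e-9)

    def test_anchor_permutation_invariance_of_mean(self):
        rng = np.random.default_rng(1)
        track = CoverageTrack(
            [("chrA", i * 100, (i + 1) * 100, float(v))
             for i, v in enumerate(rng.uniform(0, 5, 1000))],
            chrom_sizes=SIZES,
        )
        anchors = [("chrA", int(a)) for a in rng.integers(3_000, 97_000, 30)]
        fwd = aggregate_profile(track, anchors, 2000, 50).mean_curve
        rev = aggregate_profile(track, anchors[::-1], 2000, 50).mean_curve
        assert np.allclose(fwd, rev, atol=1e-12)


class TestMetageneProfile:
    def test_constant_track_gives_flat_curve(self):
        track = constant_track(2.25)
        genes = [GeneModel("chrA", 30_000, 37_000, "+", "g1")]
        mg = metagene_profile(track, genes, 2000, 100, 50)
        assert np.allclose(mg.curve, 2.25)

    def test_strand_mirror_gives_bitwise_identical_curve(self):
        L = 100_000
        rng = np.random.default_rng(2)
        steps, pos = [], 0
        while pos < L - 400:
            pos += int(rng.integers(1, 200))
            end = min(pos + int(rng.integers(1, 300)), L)
            steps.append(("chrA", pos, end, float(rng.uniform(0, 10))))
            pos = end
        track = CoverageTrack(steps, chrom_sizes=SIZES)
        mirror = CoverageTrack(
            [("chrA", L - e, L - s, v) for _, s, e, v in steps], chrom_sizes=SIZES
        )
        plus = GeneModel("chrA", 30_000, 37_321, "+", "g")  # non-divisible length
        minus = GeneModel("chrA", L - 37_321, L - 30_000, "-", "g")
        curve_plus = metagene_profile(track, [plus], 2000, 100, 50).curve
        curve_minus = metagene_profile(mirror, [minus], 2000, 100, 50).curve
        assert np.array_equal(curve_plus, curve_minus)

    def test_symmetric_scenario_gives_symmetric_curve(self):
        # Signal symmetric about the gene midpoint -> curve symmetric too.
        gene = GeneModel("chrA", 40_000, 50_000, "+", "g")
        steps = [("chrA", 44_000, 46_000, 5.0), ("chrA", 38_000, 40_000, 2.0),
                 ("chrA", 50_000, 52_000, 2.0)]
        track = CoverageTrack(steps, chrom_sizes=SIZES)
        mg = metagene_profile(track, [gene], 2000, 100, 50)
        assert np.allclose(mg.curve, mg.curve[::-1], atol=1e-12)

    def test_short_genes_dropped_and_counted(self):
        track = constant_track(1.0)
        genes = [GeneModel("chrA", 30_000, 37_000, "+", "ok"),
                 GeneModel("chrA", 60_000, 60_050, "+", "short")]
        mg = metagene_profile(track, genes, 2000, 100, 50)
        assert mg.n_genes == 1 and mg.n_dropped == 1

    def test_no_usable_genes_is_error(self):
        with pytest.raises(PipelineUsageError):
            metagene_profile(constant_track(1.0),
                             [GeneModel("chrA", 100, 150, "+", "g")], 2000, 100, 50)


class TestRegionDensity:
    def test_formula_on_known_region(self):
        track = CoverageTrack([("chrA", 0, 1000, 0.1)], chrom_sizes=SIZES)
        # 100 signal units over 1 kb, total 1e6 -> density 100
        (d,) = region_density(track, [("r1", "promoter",
                                       GenomicInterval("chrA", 0, 1000))], 1e6)
        assert d.density == pytest.approx(100.0)
        (d2,) = region_density(track, [("r2", "body",
                                        GenomicInterval("chrA", 0, 2000))], 1e6)
        assert d2.density == pytest.approx(50.0)

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(3)
        edges = np.arange(0, 100_001, 250)
        vals = rng.uniform(0, 4, len(edges) - 1)
        track = CoverageTrack(
            [("chrA", int(s), int(e), float(v))
             for s, e, v in zip(edges[:-1], edges[1:], vals)],
            chrom_sizes=SIZES,
        )
        regions = []
        for i in range(50):
            s = int(rng.integers(0, 95_000))
            regions.append((f"r{i}", "promoter",
                            GenomicInterval("chrA", s, s + int(rng.integers(100, 5000)))))
        total = track.total_signal()
        result = region_density(track, regions, total)
        for (rid, _, iv), d in zip(regions, result):
            naive = sum(
                v * max(0, min(e, iv.end) - max(s, iv.start))
                for s, e, v in zip(edges[:-1], edges[1:], vals)
            )
            expected = naive / (iv.length / 1000) / (total / 1e6)
            assert d.density == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_step_splitting(self):
        iv = GenomicInterval("chrA", 100, 2100)
        coarse = CoverageTrack([("chrA", 0, 3000, 2.0)], chrom_sizes=SIZES)
        fine = CoverageTrack(
            [("chrA", i * 100, (i + 1) * 100, 2.0) for i in range(30)],
            chrom_sizes=SIZES,
        )
        (dc,) = region_density(coarse, [("r", "body", iv)], 1e6)
        (df,) = region_density(fine, [("r", "body", iv)], 1e6)
        assert dc.density == pytest.approx(df.density, abs=1e-12)


class TestRpkmNormalize:
    def test_formula_on_planted_bin(self):
        sizes = {"chrA": 10_000}
        # 10 reads in one 100 bp bin out of 1000 total:
        # 10 / 0.1 kb / (1000/1e6) = 100,000
        reads = [GenomicInterval("chrA", 500, 520) for _ in range(10)]
        reads += [GenomicInterval("chrA", 9_000, 9_010) for _ in range(990)]
        track = rpkm_normalize(reads, 100, sizes)
        assert track.mean("chrA", 500, 600) == pytest.approx(100_000.0)
        assert track.mean("chrA", 100, 200) == 0.0

    def test_matches_per_bin_brute_force(self):
        sizes = {"chrA": 20_000}
        rng = np.random.default_rng(4)
        reads = []
        for _ in range(500):
            s = int(rng.integers(0, 19_900))
            reads.append(GenomicInterval("chrA", s, s + int(rng.integers(1, 100))))
        bin_size = 250
        track = rpkm_normalize(reads, bin_size, sizes)
        factor = len(reads) / 1e6
        for b0 in range(0, 20_000, bin_size):
            b1 = min(b0 + bin_size, 20_000)
            count = sum(1 for r in reads if r.start < b1 and b0 < r.end)
            expected = count / ((b1 - b0) / 1000) / factor
            assert track.mean("chrA", b0, b1) == pytest.approx(expected, abs=1e-9)

    def test_no_reads_is_error(self):
        with pytest.raises(PipelineUsageError):
            rpkm_normalize([], 100, SIZES)
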