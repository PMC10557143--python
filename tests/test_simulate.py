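import json

import numpy as np
import pytest

from colocscreen.annotation import promoter_fraction, promoter_regions
from colocscreen.intervals import intersect_report_a
from colocscreen.simulate import (
    ScenarioConfig,
    generate_scenario,
    make_genes,
    make_genome,
    make_structure_peaks,
    write_scenario,
)
from colocscreen.types import PipelineUsageError

from conftest import SMALL_CONFIG


class TestMakeGenome:
    def test_basic(self):
        assert make_genome(2, 10_000_000) == {
            "chrS1": 10_000_000, "chrS2": 10_000_000
        }

    def test_minimal_genome_accepted(self):
        assert make_genome(1, 100_000) == {"chrS1": 100_000}

    @pytest.mark.parametrize("args", [(0, 1_000_000), (1, 50_000)])
    def test_bad_parameters_rejected(self, args):
        with pytest.raises(PipelineUsageError):
            make_genome(*args)


class TestMakeGenes:
    def test_zero_genes(self):
        rng = np.random.default_rng(0)
        assert make_genes({"chrS1": 1_000_000}, 0, (1000, 2000), rng) == []

    def test_genes_pairwise_non_overlapping_and_sorted(self):
        rng = np.random.default_rng(1)
        genes = make_genes({"chrS1": 2_000_000}, 100, (2000, 5000), rng)
        assert len(genes) == 100
        ordered = sorted(genes, key=lambda g: (g.chrom, g.tx_start))
        assert genes == ordered
        for a, b in zip(genes, genes[1:]):
            if a.chrom == b.chrom:
                assert a.tx_end <= b.tx_start

    def test_same_seed_identical_placement(self):
        g1 = make_genes({"chrS1": 2_000_000}, 50, (2000, 5000),
                        np.random.default_rng(42))
        g2 = make_genes({"chrS1": 2_000_000}, 50, (2000, 5000),
                        np.random.default_rng(42))
        assert g1 == g2

    def test_infeasible_density_rejected(self):
        with pytest.raises(PipelineUsageError):
            make_genes({"chrS1": 100_000}, 100, (1000, 2000),
                       np.random.default_rng(0))


@pytest.fixture(scope="module")
def structure_setup():
    rng = np.random.default_rng(5)
    sizes = {"chrS1": 2_000_000}
    genes = make_genes(sizes, 80, (3000, 6000), rng)
    promoters = promoter_regions(genes, 1000, 500, sizes)
    return sizes, promoters, rng


class TestMakeStructurePeaks:
    def test_full_promoter_planting(self, structure_setup):
        sizes, promoters, rng = structure_setup
        peaks, info = make_structure_peaks(promoters, sizes, 200, 1.0,
                                           np.random.default_rng(0))
        assert promoter_fraction(peaks, promoters) == 100.0

    def test_planted_70_percent_is_exact(self, structure_setup):
        sizes, promoters, _ = structure_setup
        peaks, info = make_structure_peaks(promoters, sizes, 1000, 0.7,
                                           np.random.default_rng(1))
        assert info["n_promoter_planted"] == 700
        assert promoter_fraction(peaks, promoters) == 70.0

    def test_zero_cooccurrence_means_zero_overlap(self, structure_setup):
        sizes, promoters, _ = structure_setup
        target, _ = make_structure_peaks(promoters, sizes, 100, 0.5,
                                         np.random.default_rng(2))
        other, info = make_structure_peaks(promoters, sizes, 100, 0.5,
                                           np.random.default_rng(3),
                                           cooccur_with=target, rho=0.0)
        assert info["n_cooccur_planted"] == 0
        assert intersect_report_a(other, target) == []

    def test_planted_cooccurrence_is_exact(self, structure_setup):
        sizes, promoters, _ = structure_setup
        target, _ = make_structure_peaks(promoters, sizes, 100, 0.5,
                                         np.random.default_rng(2))
        other, info = make_structure_peaks(promoters, sizes, 200, 0.5,
                                           np.random.default_rng(4),
                                           cooccur_with=target, rho=0.4)
        assert info["n_cooccur_planted"] == 80
        assert len(intersect_report_a(other, target)) == 80


class TestScenario:
    def test_ledger_counts_rederivable_from_peak_sets(self, small_scenario):
        # generate_scenario already self-verifies with the interval engine;
        # spot-check one protein independently here.
        sc = small_scenario
        protein = sorted(sc.tf_sets)[0]
        planted = sc.ledger["proteins"][protein]
        assert len(intersect_report_a(sc.tf_sets[protein], sc.rloop)) == \
            planted["n_rloop"]
        assert len(intersect_report_a(sc.tf_sets[protein], sc.g4)) == \
            planted["n_g4"]

    def test_same_seed_byte_identical_files(self, tmp_path):
        a = write_scenario(generate_scenario(3, SMALL_CONFIG), tmp_path / "a")
        b = write_scenario(generate_scenario(3, SMALL_CONFIG), tmp_path / "b")
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        sc1 = generate_scenario(3, SMALL_CONFIG)
        sc2 = generate_scenario(4, SMALL_CONFIG)
        assert sc1.rloop != sc2.rloop

    def test_emitted_files_are_valid_io_inputs(self, tmp_path, small_scenario):
        from colocscreen import io as gio

        out = write_scenario(small_scenario, tmp_path / "sc")
        sizes = gio.read_chrom_sizes(out / "chrom.sizes")
        genes = gio.read_gene_models(out / "genes.bed")
        rloop = gio.read_peaks(out / "rloop.narrowPeak", "narrowPeak")
        track = gio.read_bedgraph(out / "signal.bedgraph", sizes)
        assert len(genes) == SMALL_CONFIG.n_genes
        assert len(rloop) == SMALL_CONFIG.n_structure
        assert rloop == small_scenario.rloop
        assert track.total_signal() == pytest.approx(
            small_scenario.signal_track.total_signal())
        ledger = json.loads((out / "ledger.json").read_text())
        assert ledger["seed"] == small_scenario.seed

    def test_noiseless_coverage_matches_truth_exactly(self):
        from colocscreen.profiles import aggregate_profile

        cfg = ScenarioConfig(
            n_chroms=1, chrom_length=1_000_000, n_genes=40,
            gene_len_range=(3000, 6000), n_structure=80, n_proteins=3,
            n_peaks_per_protein=40, noise_sd=0.0,
        )
        sc = generate_scenario(9, cfg)
        pm = aggregate_profile(sc.signal_track, sc.anchors, cfg.window,
                               cfg.bin_size, sc.chrom_sizes)
        truth = np.array(sc.ledger["coverage"]["truth_mean_curve"])
        assert np.allclose(pm.mean_curve, truth, atol=0)
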