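"""Synthetic-data generator: determinism, truth consistency, structure."""

import numpy as np
import pytest
from scipy import stats

from g4access.differential import CountMatrix
from g4access.genome import reverse_complement
from g4access.simulate import DEMO_DAR_FDR, PlacementError, SimConfig, \
    draw_counts, simulate_dataset, simulate_gene_models, simulate_genome, \
    simulate_peaks_and_counts, structure_demo_config


def small_config(**kw) -> SimConfig:
    defaults = dict(seed=1, contig_length=400_000, n_genes=26, n_peaks=40,
                    library_size_mean=40_000)
    defaults.update(kw)
    return SimConfig(**defaults)


def run_all(config):
    genome, truth = simulate_genome(config)
    genes = simulate_gene_models(genome, config)
    peaks, matrix, truth = simulate_peaks_and_counts(genome, genes, truth,
                                                     config)
    return genome, genes, peaks, matrix, truth


class TestSimulateGenome:
    def test_planted_motif_count_matches_request(self):
        cfg = small_config(n_planted_motifs=50)
        _, truth = simulate_genome(cfg)
        assert len(truth.planted_pg4_intervals) == 50

    def test_identical_config_gives_identical_fasta(self):
        cfg = small_config(n_planted_motifs=20)
        g1, _ = simulate_genome(cfg)
        g2, _ = simulate_genome(cfg)
        assert g1.to_fasta_str() == g2.to_fasta_str()

    def test_gc_fraction_within_binomial_interval(self):
        cfg = SimConfig(seed=2, contig_length=1_000_000, gc_fraction=0.5,
                        n_genes=70)
        genome, _ = simulate_genome(cfg)
        seq = genome.contigs["chr1"]
        gc = (seq.count(b"G") + seq.count(b"C")) / len(seq)
        # 99.9% two-sided binomial interval around 0.5 at n = 1e6
        half = stats.norm.ppf(0.9995) * np.sqrt(0.25 / len(seq))
        assert abs(gc - 0.5) < half

    def test_planted_motifs_readable_from_sequence(self):
        cfg = small_config(n_planted_motifs=30)
        genome, truth = simulate_genome(cfg)
        for iv in truth.planted_pg4_intervals:
            got = genome.fetch(iv.contig, iv.start, iv.end)
            expected = cfg.motif_template if iv.strand == "+" \
                else reverse_complement(cfg.motif_template)
            assert got == expected

    def test_motif_longer_than_contig_rejected(self):
        cfg = SimConfig(seed=0, contig_length=3_000, n_genes=1, n_peaks=1,
                        n_true_dars=0, n_planted_motifs=1,
                        promoter_upstream=100, promoter_downstream=50,
                        motif_template="G" * 5000)
        with pytest.raises(PlacementError, match="chr1"):
            simulate_genome(cfg)

    def test_unplaceable_motifs_rejected(self):
        cfg = SimConfig(seed=0, contig_length=100_000, n_genes=5, n_peaks=5,
                        n_true_dars=0, n_planted_motifs=4000)
        with pytest.raises(PlacementError, match="chr1"):
            simulate_genome(cfg)


class TestSimulateGeneModels:
    def test_requested_number_of_nonoverlapping_genes(self):
        cfg = small_config()
        genome, _ = simulate_genome(cfg)
        genes = simulate_gene_models(genome, cfg)
        assert len(genes) == cfg.n_genes
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append((g.start, g.end))
        for spans in by_contig.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_strand_vector_reproducible(self):
        cfg = small_config()
        genome, _ = simulate_genome(cfg)
        strands1 = [g.strand for g in simulate_gene_models(genome, cfg)]
        strands2 = [g.strand for g in simulate_gene_models(genome, cfg)]
        assert strands1 == strands2
        assert set(strands1) == {"+", "-"}

    def test_genes_within_contig_bounds(self):
        cfg = small_config()
        genome, _ = simulate_genome(cfg)
        for g in simulate_gene_models(genome, cfg):
            assert 0 <= g.start < g.end <= genome.length(g.contig)
            for es, ee in g.exons:
                assert g.start <= es < ee <= g.end

    def test_too_many_genes_rejected(self):
        cfg = SimConfig(seed=0, contig_length=50_000, n_genes=30, n_peaks=10,
                        n_true_dars=5)
        genome, _ = simulate_genome(cfg)
        with pytest.raises(PlacementError, match="chr1"):
            simulate_gene_models(genome, cfg)


class TestPeaksAndCounts:
    def test_null_config_has_no_dars_and_equal_condition_means(self):
        cfg = small_config(n_true_dars=0, nb_dispersion=0.0,
                           size_factor_sigma=0.0, library_size_mean=400_000)
        _, _, peaks, matrix, truth = run_all(cfg)
        assert truth.true_dars == {}
        a = matrix.counts[matrix.samples_of("control")].to_numpy().mean(axis=1)
        b = matrix.counts[matrix.samples_of("treated")].to_numpy().mean(axis=1)
        # Poisson noise only: per-region relative deviation is small
        ratio = (b + 1) / (a + 1)
        assert np.median(np.abs(np.log2(ratio))) < 0.1

    def test_true_log2fc_sets_condition_mean_ratio(self):
        cfg = small_config(n_true_dars=6, true_log2fc=-2.0, nb_dispersion=0.0,
                           size_factor_sigma=0.0, library_size_mean=2_000_000)
        _, _, peaks, matrix, truth = run_all(cfg)
        a = matrix.counts[matrix.samples_of("control")].mean(axis=1)
        b = matrix.counts[matrix.samples_of("treated")].mean(axis=1)
        for rid in truth.true_dars:
            assert b[rid] / a[rid] == pytest.approx(0.25, rel=0.15)

    def test_down_dar_containment_hits_target_exactly(self):
        # 22 reduced promoter DARs at containment 0.955 -> exactly 21
        cfg = structure_demo_config(seed=4)
        _, _, peaks, matrix, truth = run_all(cfg)
        down = [r for r, l in truth.true_dars.items() if l < 0]
        assert len(down) == 22
        assert sum(truth.pg4_flags[r] for r in down) == 21
        prom_with = sum(truth.pg4_flags[r] for r in truth.promoter_regions)
        assert prom_with == round(0.809 * len(truth.promoter_regions))

    def test_too_many_dars_rejected(self):
        with pytest.raises(ValueError, match="n_true_dars"):
            SimConfig(n_peaks=10, n_true_dars=11, n_genes=20)

    def test_byte_identical_outputs_across_runs(self, tmp_path):
        cfg = small_config(n_true_dars=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = simulate_dataset(cfg, d1)
        p2 = simulate_dataset(cfg, d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_direction_split_controllable(self):
        cfg = small_config(n_true_dars=10, frac_dars_increased=0.3,
                           dar_promoter_fraction=0.5)
        _, _, _, _, truth = run_all(cfg)
        signs = [l > 0 for l in truth.true_dars.values()]
        assert sum(signs) == 3


class TestCountMarginals:
    def test_zero_dispersion_reduces_to_poisson_mean(self, rng):
        mu, n = 37.0, 10_000
        draws = draw_counts(np.full(n, mu), 0.0, rng)
        se = np.sqrt(mu / n)
        assert abs(draws.mean() - mu) < 3 * se
        assert abs(draws.var() - mu) / mu < 0.1

    def test_nb_dispersion_sets_variance(self, rng):
        mu, phi, n = 50.0, 0.3, 20_000
        draws = draw_counts(np.full(n, mu), phi, rng)
        expected_var = mu + phi * mu ** 2
        assert draws.var() == pytest.approx(expected_var, rel=0.1)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(gc_fraction=0.0), dict(gc_fraction=1.2),
        dict(n_peaks=0), dict(nb_dispersion=-0.1),
        dict(pg4_background_rate=1.5), dict(motif_template="GGQ"),
        dict(promoter_upstream=3_000_000),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_demo_config_pairs_with_strict_threshold(self):
        cfg = structure_demo_config(seed=9)
        assert cfg.seed == 9 and cfg.nb_dispersion == 0.0
        assert 0 < DEMO_DAR_FDR < 1e-3
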