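"""Simulator: density, segregation, crossover law, observation model."""

import numpy as np
import pytest
from scipy import stats

from spermlink import ParameterError
from spermlink import synthdata as sd


class TestParentGenome:
    def test_site_density_matches_requested_spacing(self):
        g = sd.simulate_parent_genome(1, 245_000, 245, seed=1)
        n = len(g.het_positions["chr1"])
        expected = 245_000 / 245
        assert abs(n - expected) <= 3 * np.sqrt(expected)

    def test_mean_spacing_within_20pct_on_megabase_chromosome(self):
        g = sd.simulate_parent_genome(1, 1_000_000, 245, seed=2)
        pos = g.het_positions["chr1"]
        spacing = np.diff(pos).mean()
        assert abs(spacing - 245) / 245 < 0.2

    def test_positions_strictly_increasing_and_alleles_distinct(self):
        g = sd.simulate_parent_genome(2, 100_000, 500, seed=3)
        for chrom in ("chr1", "chr2"):
            pos = g.het_positions[chrom]
            assert (np.diff(pos) > 0).all()
            assert (g.hap0[chrom] != g.hap1[chrom]).all()

    def test_spacing_exceeding_length_is_a_parameter_error(self):
        with pytest.raises(ParameterError):
            sd.simulate_parent_genome(1, 1_000, 1_000_000, seed=1)

    @pytest.mark.parametrize("bad", [(0, 1000, 10), (1, 0, 10), (1, 1000, 0)])
    def test_non_positive_sizes_rejected(self, bad):
        with pytest.raises(ParameterError):
            sd.simulate_parent_genome(*bad, seed=1)

    def test_same_seed_reproduces_identical_sites(self):
        a = sd.simulate_parent_genome(1, 500_000, 245, seed=7)
        b = sd.simulate_parent_genome(1, 500_000, 245, seed=7)
        assert np.array_equal(a.het_positions["chr1"], b.het_positions["chr1"])
        assert np.array_equal(a.hap0["chr1"], b.hap0["chr1"])
        assert np.array_equal(a.ref_is_hap0["chr1"], b.ref_is_hap0["chr1"])


class TestFragmentation:
    def test_contig_lengths_partition_each_chromosome(self):
        g = sd.simulate_parent_genome(2, 1_000_000, 500, seed=1)
        contigs, truth = sd.fragment_into_contigs(g, 100_000, seed=2)
        ta = truth.contig_assignment
        for chrom in ("chr1", "chr2"):
            sub = ta[ta["chrom"] == chrom].sort_values("start_bp")
            assert sub["start_bp"].iloc[0] == 1
            assert sub["end_bp"].iloc[-1] == 1_000_000
            assert (
                sub["start_bp"].iloc[1:].to_numpy()
                == sub["end_bp"].iloc[:-1].to_numpy() + 1
            ).all()
            total = (sub["end_bp"] - sub["start_bp"] + 1).sum()
            assert total == 1_000_000

    def test_reverse_contig_site_order_is_reversed(self):
        g = sd.simulate_parent_genome(1, 500_000, 500, seed=3)
        contigs, truth = sd.fragment_into_contigs(g, 100_000, seed=4)
        minus = [c for c in contigs if c.orientation == "-" and len(c.local_pos) > 1]
        assert minus, "expected at least one reverse-complemented contig"
        for c in minus:
            # ascending local positions correspond to descending chromosome
            # positions: the site index array runs backwards
            assert (np.diff(c.local_pos) > 0).all()
            assert (np.diff(c.site_idx) < 0).all()
            chrom_pos = g.het_positions[c.chrom][c.site_idx]
            assert np.array_equal(c.local_pos, c.end_bp - chrom_pos + 1)

    def test_fixed_seed_reproduces_identical_breakpoints(self):
        g = sd.simulate_parent_genome(1, 500_000, 500, seed=3)
        _, t1 = sd.fragment_into_contigs(g, 80_000, seed=9)
        _, t2 = sd.fragment_into_contigs(g, 80_000, seed=9)
        assert t1.contig_assignment.equals(t2.contig_assignment)

    def test_too_small_mean_contig_rejected(self):
        g = sd.simulate_parent_genome(1, 100_000, 500, seed=1)
        with pytest.raises(ParameterError):
            sd.fragment_into_contigs(g, 600, seed=1)


class TestGamete:
    def test_zero_rate_without_obligate_gives_constant_indicator(self):
        g = sd.simulate_parent_genome(1, 100_000, 500, seed=1)
        model = sd.CrossoverModel(rate_per_chrom=0.0, obligate=False)
        gm = sd.simulate_gamete(g, model, seed=2)
        assert len(gm.crossovers["chr1"]) == 0
        assert len(np.unique(gm.haplotype["chr1"])) == 1

    def test_mendelian_segregation_at_fixed_site(self):
        g = sd.simulate_parent_genome(1, 50_000, 1000, seed=1)
        model = sd.CrossoverModel(rate_per_chrom=1.0, obligate=True)
        rng = np.random.default_rng(10)
        n = 10_000
        hits = sum(
            int(sd.simulate_gamete(g, model, rng).haplotype["chr1"][3])
            for _ in range(n)
        )
        sigma = np.sqrt(n * 0.25)
        assert abs(hits - n / 2) <= 3 * sigma

    def test_crossover_count_distribution_matches_obligate_poisson_law(self):
        # obligate: count - 1 ~ Poisson(rate - 1); chi-square GOF at alpha 0.01
        g = sd.simulate_parent_genome(1, 50_000, 1000, seed=1)
        rate = 1.5
        model = sd.CrossoverModel(rate_per_chrom=rate, obligate=True)
        rng = np.random.default_rng(11)
        n = 10_000
        counts = np.array(
            [len(sd.simulate_gamete(g, model, rng).crossovers["chr1"]) for _ in range(n)]
        )
        assert counts.min() >= 1
        extras = counts - 1
        kmax = 6
        observed = np.bincount(np.minimum(extras, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), rate - 1.0)
        expected = np.append(pmf, 1 - pmf.sum()) * n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=kmax)

    def test_no_crossovers_inside_suppression_window(self):
        g = sd.simulate_parent_genome(1, 1_000_000, 500, seed=1)
        g.centromere_pos = {"chr1": 500_000}
        model = sd.CrossoverModel(
            rate_per_chrom=2.0, obligate=True, centromere_suppression_width_bp=200_000
        )
        rng = np.random.default_rng(12)
        for _ in range(2_000):
            xo = sd.simulate_gamete(g, model, rng).crossovers["chr1"]
            assert not ((xo >= 400_000) & (xo <= 600_000)).any()

    def test_suppression_covering_chromosome_with_obligate_crossover_errors(self):
        g = sd.simulate_parent_genome(1, 100_000, 500, seed=1)
        g.centromere_pos = {"chr1": 50_000}
        model = sd.CrossoverModel(
            rate_per_chrom=1.0, obligate=True,
            centromere_suppression_width_bp=400_000,
        )
        with pytest.raises(ParameterError):
            sd.simulate_gamete(g, model, seed=1)


@pytest.fixture(scope="module")
def small():
    g = sd.simulate_parent_genome(1, 500_000, 245, seed=1)
    contigs, _truth = sd.fragment_into_contigs(g, 100_000, seed=2)
    gm = sd.simulate_gamete(g, sd.CrossoverModel(), seed=3)
    gm2 = sd.simulate_gamete(g, sd.CrossoverModel(), seed=4)
    return g, contigs, gm, gm2


class TestCellObservations:
    def test_zero_hit_rate_gives_empty_column(self, small):
        _, contigs, gm, _ = small
        idx, vals = sd.simulate_cell_observations(contigs, [gm], 0.0, 0.0, seed=1)
        assert len(idx) == 0 and len(vals) == 0

    def test_full_errorfree_haploid_coverage_has_no_both_calls(self, small):
        g, contigs, gm, _ = small
        idx, vals = sd.simulate_cell_observations(contigs, [gm], 1.0, 0.0, seed=1)
        n_markers = sum(len(c.local_pos) for c in contigs)
        assert len(idx) == n_markers
        assert set(np.unique(vals)) <= {1, 2}

    def test_observation_count_is_binomial_at_low_hit_rate(self, small):
        _, contigs, gm, _ = small
        n_markers = sum(len(c.local_pos) for c in contigs)
        idx, _ = sd.simulate_cell_observations(contigs, [gm], 0.13, 0.0, seed=5)
        mean = 0.13 * n_markers
        sigma = np.sqrt(n_markers * 0.13 * 0.87)
        assert abs(len(idx) - mean) <= 3 * sigma

    def test_doublet_both_calls_appear_exactly_where_gametes_disagree(self, small):
        g, contigs, gm, gm2 = small
        idx, vals = sd.simulate_cell_observations(
            contigs, [gm, gm2], 1.0, 0.0, cell_class="doublet", seed=6
        )
        markers = []
        for c in sorted(contigs.contigs, key=lambda c: c.id):
            h1 = gm.haplotype[c.chrom][c.site_idx]
            h2 = gm2.haplotype[c.chrom][c.site_idx]
            markers.append(h1 != h2)
        disagree = np.concatenate(markers)
        assert np.array_equal(vals == 3, disagree[idx])

    def test_diploid_shows_both_alleles_at_every_hit_site(self, small):
        _, contigs, gm, _ = small
        idx, vals = sd.simulate_cell_observations(
            contigs, [gm], 0.5, 0.0, cell_class="diploid", seed=7
        )
        assert (vals == 3).all() and len(idx) > 0

    def test_bad_rates_rejected(self, small):
        _, contigs, gm, _ = small
        with pytest.raises(ParameterError):
            sd.simulate_cell_observations(contigs, [gm], 1.5, 0.0, seed=1)


class TestDataset:
    def test_same_seed_gives_byte_identical_dataset(self):
        kw = dict(n_chrom=1, chrom_len_bp=100_000, n_cells=20, seed=42)
        a = sd.simulate_dataset(**kw)
        b = sd.simulate_dataset(**kw)
        assert (a.matrix.X != b.matrix.X).nnz == 0
        assert a.matrix.markers.equals(b.matrix.markers)
        assert a.truth.cell_class == b.truth.cell_class

    def test_cell_class_fractions_validated(self):
        with pytest.raises(ParameterError):
            sd.simulate_dataset(
                n_chrom=1, chrom_len_bp=100_000, n_cells=5,
                doublet_fraction=0.9, diploid_fraction=0.4, seed=1,
            )
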