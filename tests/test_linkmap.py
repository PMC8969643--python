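"""Recombination fractions, grouping, ordering, orientation and cM."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spermlink import Config
from spermlink.linkmap import (
    EndCalls,
    brute_force_order,
    chain_objective,
    cluster_groups,
    canonicalize_group,
    genetic_positions,
    order_contigs,
    orient_contigs,
    pairwise_end_stats,
    rec_fraction,
)
from spermlink.phasing import H_NA


def h_vec(bits):
    return np.asarray(bits, dtype=np.int8)


class TestRecFraction:
    def test_identical_vectors_have_zero_r(self):
        a = h_vec([0, 1] * 25)
        r, n = rec_fraction(a, a)
        assert r == 0.0 and n == 50

    def test_complementary_vectors_have_zero_r_after_gauge(self):
        a = h_vec([0, 1] * 25)
        r, n = rec_fraction(a, 1 - a)
        assert r == 0.0 and n == 50

    def test_hand_counted_disagreements(self):
        a = h_vec([0] * 12)
        b = a.copy()
        b[:3] = 1
        r, n = rec_fraction(a, b)
        assert r == pytest.approx(0.25) and n == 12

    def test_na_cells_excluded_and_empty_overlap_undefined(self):
        a = h_vec([0, 0, H_NA, H_NA])
        b = h_vec([H_NA, H_NA, 1, 1])
        r, n = rec_fraction(a, b)
        assert n == 0 and np.isnan(r)

    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=4, max_size=40))
    def test_symmetry_and_gauge_invariance(self, bits):
        a = h_vec(bits)
        rng = np.random.default_rng(0)
        b = h_vec(rng.choice([-1, 0, 1], size=len(bits)))
        r_ab, n_ab = rec_fraction(a, b)
        r_ba, n_ba = rec_fraction(b, a)
        assert n_ab == n_ba
        if n_ab:
            assert r_ab == r_ba
            flipped = np.where(b == H_NA, H_NA, 1 - b).astype(np.int8)
            r_flip, _ = rec_fraction(a, flipped)
            assert r_flip == pytest.approx(r_ab)
            assert 0.0 <= r_ab <= 0.5


def synthetic_ends(segments, n_cells=200, seed=0):
    """EndCalls for a chain of contigs: ``segments`` lists per contig the
    number of cells whose haplotype flips between its left end and the
    previous contig's right end, and between its own two ends, as
    (gap_flips, internal_flips)."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2, size=n_cells).astype(np.int8)
    contigs, left, right = [], [], []
    cursor = base.copy()
    flip_pool = rng.permutation(n_cells)
    k = 0
    for idx, (gap_flips, internal_flips) in enumerate(segments):
        for _ in range(gap_flips):
            cursor[flip_pool[k % n_cells]] ^= 1
            k += 1
        l = cursor.copy()
        for _ in range(internal_flips):
            cursor[flip_pool[k % n_cells]] ^= 1
            k += 1
        r = cursor.copy()
        contigs.append(f"ctg{idx}")
        left.append(l)
        right.append(r)
    return EndCalls(
        contigs=contigs,
        left=np.stack(left),
        right=np.stack(right),
        lengths={c: 1000 for c in contigs},
    )


class TestClustering:
    def test_tightly_linked_chain_forms_one_group(self):
        ends = synthetic_ends([(0, 2), (2, 2), (2, 2)])
        stats = pairwise_end_stats(ends)
        groups, unplaced = cluster_groups(stats, Config())
        assert groups == [[0, 1, 2]] and unplaced == []

    def test_weakly_linked_contigs_stay_apart(self):
        # 40 of 200 cells flip across the junction: r = 0.2, LD 0.6 < 0.9
        ends = synthetic_ends([(0, 2), (40, 2)])
        stats = pairwise_end_stats(ends)
        groups, unplaced = cluster_groups(stats, Config())
        assert groups == [] and unplaced == [0, 1]

    def test_no_informative_pairs_leaves_all_unplaced(self):
        na = np.full((2, 50), H_NA, dtype=np.int8)
        ends = EndCalls(
            contigs=["a", "b"], left=na, right=na.copy(), lengths={"a": 1, "b": 1}
        )
        stats = pairwise_end_stats(ends)
        groups, unplaced = cluster_groups(stats, Config())
        assert groups == [] and unplaced == [0, 1]


class TestOrdering:
    def test_three_contig_chain_recovers_linear_order(self):
        ends = synthetic_ends([(0, 2), (2, 2), (2, 2)])
        stats = pairwise_end_stats(ends)
        cfg = Config()
        chain = order_contigs([0, 1, 2], stats, cfg)
        order = [i for i, _ in chain]
        assert order in ([0, 1, 2], [2, 1, 0])
        _, best_obj = brute_force_order([0, 1, 2], stats, cfg.cs)
        assert chain_objective(stats, chain, cfg.cs) == pytest.approx(best_obj)

    def test_single_contig_group_is_itself(self):
        ends = synthetic_ends([(0, 2)])
        stats = pairwise_end_stats(ends)
        assert order_contigs([0], stats, Config()) == [(0, "+")]

    def test_greedy_plus_two_opt_matches_exhaustive_on_five_contigs(self):
        ends = synthetic_ends([(0, 3), (3, 2), (2, 4), (3, 2), (2, 3)], seed=3)
        stats = pairwise_end_stats(ends)
        cfg = Config()
        chain = order_contigs([0, 1, 2, 3, 4], stats, cfg)
        _, best_obj = brute_force_order([0, 1, 2, 3, 4], stats, cfg.cs)
        assert chain_objective(stats, chain, cfg.cs) == pytest.approx(best_obj)


class TestOrientation:
    def test_internal_recombination_orients_contigs(self):
        ends = synthetic_ends([(0, 6), (3, 6), (3, 6)])
        stats = pairwise_end_stats(ends)
        cfg = Config()
        chain = order_contigs([0, 1, 2], stats, cfg)
        reported = orient_contigs(chain, stats, cfg.cs)
        assert all(o in "+-" for o in reported)

    def test_no_internal_recombination_is_unorientable(self):
        ends = synthetic_ends([(0, 0), (4, 6), (4, 0)])
        stats = pairwise_end_stats(ends)
        cfg = Config()
        chain = order_contigs([0, 1, 2], stats, cfg)
        reported = orient_contigs(chain, stats, cfg.cs)
        by_contig = {i: o for (i, _), o in zip(chain, reported)}
        assert by_contig[0] == "?" and by_contig[2] == "?"
        assert by_contig[1] in "+-"

    def test_flipping_a_contig_in_the_simulation_flips_its_report(self):
        ends = synthetic_ends([(0, 6), (3, 6), (3, 6)], seed=7)
        cfg = Config()
        stats = pairwise_end_stats(ends)
        chain = order_contigs([0, 1, 2], stats, cfg)
        reported = orient_contigs(chain, stats, cfg.cs)
        # swap contig 1's end calls: its reported orientation must invert
        ends2 = EndCalls(
            contigs=ends.contigs,
            left=ends.left.copy(),
            right=ends.right.copy(),
            lengths=ends.lengths,
        )
        ends2.left[1], ends2.right[1] = ends.right[1].copy(), ends.left[1].copy()
        stats2 = pairwise_end_stats(ends2)
        chain2 = order_contigs([0, 1, 2], stats2, cfg)
        reported2 = orient_contigs(chain2, stats2, cfg.cs)
        o1 = {i: o for (i, _), o in zip(chain, reported)}[1]
        o2 = {i: o for (i, _), o in zip(chain2, reported2)}[1]
        assert {o1, o2} == {"+", "-"}


class TestGeneticPositions:
    def test_one_percent_recombination_is_one_centimorgan(self):
        ends = synthetic_ends([(0, 4), (2, 4)])  # 2/200 = 0.01 between contigs
        stats = pairwise_end_stats(ends)
        cfg = Config()
        chain = order_contigs([0, 1], stats, cfg)
        reported = orient_contigs(chain, stats, cfg.cs)
        cm_start, cm_end = genetic_positions(chain, reported, stats, cfg)
        gap = cm_start[1] - cm_end[0]
        assert gap == pytest.approx(1.0)

    def test_zero_recombination_block_shares_one_position(self):
        ends = synthetic_ends([(0, 0), (0, 0), (0, 0)])
        stats = pairwise_end_stats(ends)
        cfg = Config()
        chain = order_contigs([0, 1, 2], stats, cfg)
        reported = orient_contigs(chain, stats, cfg.cs)
        cm_start, cm_end = genetic_positions(chain, reported, stats, cfg)
        assert set(cm_start) == {0.0} and set(cm_end) == {0.0}

    def test_positions_are_non_decreasing(self, recovery_results):
        df = recovery_results.map.df
        for g in recovery_results.map.groups:
            sub = df[df["group"] == g].sort_values("order_index")
            pos = np.concatenate(
                [sub[["cM_start", "cM_end"]].to_numpy().ravel()]
            )
            assert (np.diff(pos) >= -1e-9).all()

    def test_map_length_tracks_mean_crossover_count(self, recovery_dataset,
                                                    recovery_results):
        # total cM per group ~ 100 x mean crossovers per chromosome
        truth = recovery_dataset.truth
        kept = set(recovery_results.kept_cells)
        per_chrom = {}
        for cell, xos in truth.cell_crossovers.items():
            if cell not in kept:
                continue
            for chrom, pos in xos.items():
                per_chrom.setdefault(chrom, []).append(len(pos))
        from spermlink.evaluate import match_groups

        chrom_to_group = match_groups(recovery_results, recovery_dataset.truth)
        df = recovery_results.map.df
        for chrom, group in chrom_to_group.items():
            counts = np.array(per_chrom[chrom])
            expected = 100.0 * counts.mean()
            sigma = 100.0 * counts.std(ddof=1) / np.sqrt(len(counts))
            observed = df.loc[df["group"] == group, "cM_end"].max()
            # noise from genotyping error inflates the map slightly; allow
            # 3 sigma plus a 10 cM noise floor
            assert abs(observed - expected) <= 3 * sigma + 10.0


class TestCanonicalization:
    def test_longer_arm_reported_first(self):
        ends = synthetic_ends([(0, 2), (2, 2), (2, 2)])
        stats = pairwise_end_stats(ends)
        stats.lengths_by_index = [100, 200, 5000]
        chain = [(0, "+"), (1, "+"), (2, "+")]
        canon = canonicalize_group(chain, stats)
        assert canon[0][0] == 2  # heavy contig end leads after reversal
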