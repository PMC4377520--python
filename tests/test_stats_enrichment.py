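"""Enrichment, outlier filtering, t-tests and genomic characteristics."""

import math

import numpy as np
import pytest

from nolscan.genome_io import GeneModel
from nolscan.stats_enrichment import (CategoryMap, category_vs_genome_test,
                                      compute_gene_stats,
                                      hypergeometric_enrichment, iqr_filter,
                                      two_sample_ttest)


def exact_hypergeom_tail(N, K, n, k):
    """Independent oracle: combinatorial sum of P[X >= k]."""
    total = math.comb(N, n)
    s = 0
    for j in range(k, min(K, n) + 1):
        s += math.comb(K, j) * math.comb(N - K, n - j)
    return s / total


class TestHypergeometricEnrichment:
    def _map(self, members, universe_size=10):
        universe = {f"g{i}" for i in range(universe_size)}
        return CategoryMap({g: {"cat"} for g in members}, universe)

    def test_small_worked_example(self):
        cmap = self._map({f"g{i}" for i in range(5)})
        target = [f"g{i}" for i in range(4)]
        (r,) = hypergeometric_enrichment(target, cmap)
        assert r.n_overlap == 4
        assert r.p_raw == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_full_tail(self):
        cmap = self._map({"g0", "g1", "g2"})
        (r,) = hypergeometric_enrichment(["g5", "g6"], cmap)
        assert r.n_overlap == 0 and r.p_raw == pytest.approx(1.0)

    def test_target_equals_universe(self):
        cmap = self._map({"g0", "g1"})
        (r,) = hypergeometric_enrichment([f"g{i}" for i in range(10)], cmap)
        assert r.n_overlap == 2 and r.p_raw == pytest.approx(1.0)

    def test_matches_combinatorial_oracle_on_grid(self):
        universe = [f"g{i}" for i in range(24)]
        rng = np.random.default_rng(5)
        for K in (1, 6, 12, 24):
            members = set(rng.choice(universe, size=K, replace=False))
            cmap = CategoryMap({g: {"c"} for g in members}, set(universe))
            for n in (1, 5, 12, 24):
                target = list(rng.choice(universe, size=n, replace=False))
                (r,) = hypergeometric_enrichment(target, cmap)
                expected = exact_hypergeom_tail(24, K, n, r.n_overlap)
                assert r.p_raw == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_monotone_and_bounded(self):
        universe = {f"g{i}" for i in range(40)}
        rng = np.random.default_rng(2)
        mapping = {}
        for c in range(8):
            for g in rng.choice(sorted(universe), size=10, replace=False):
                mapping.setdefault(g, set()).add(f"c{c}")
        cmap = CategoryMap(mapping, universe)
        res = hypergeometric_enrichment(sorted(universe)[:12], cmap)
        ps = [r.p_raw for r in res]
        adj = [r.p_adj for r in res]
        assert all(a >= p for p, a in zip(ps, adj))
        assert all(0 <= a <= 1 for a in adj)
        assert adj == sorted(adj)  # results come sorted by p_raw

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], self._map({"g0"}))

    def test_stray_mapped_gene_rejected(self):
        with pytest.raises(ValueError):
            CategoryMap({"gX": {"c"}}, {"g0"})


class TestIqrFilter:
    def test_worked_example_one_iqr_fence(self):
        res = iqr_filter([1, 2, 3, 4, 100])
        assert (res.q1, res.q3, res.iqr) == (2.0, 4.0, 2.0)
        assert res.kept.tolist() == [1, 2, 3, 4]
        assert res.removed.tolist() == [100]

    def test_constant_input_keeps_everything(self):
        res = iqr_filter([5, 5, 5, 5])
        assert res.iqr == 0 and res.removed.size == 0

    def test_symmetric_input_keeps_symmetric_set(self):
        res = iqr_filter([-9, -2, -1, 0, 1, 2, 9])
        assert sorted(res.kept) == sorted(-res.kept)

    def test_bounds_are_closed(self):
        # q1=2, q3=4, iqr=2 -> bounds [0, 6]; 0 and 6 retained
        res = iqr_filter([0, 2, 3, 4, 6])
        assert res.removed.size == 0

    def test_partition_is_exact(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200) * 10
        res = iqr_filter(vals)
        lo, hi = res.q1 - res.iqr, res.q3 + res.iqr
        assert set(map(float, res.kept)) == {float(v) for v in vals
                                             if lo <= v <= hi}
        assert len(res.kept) + len(res.removed) == len(vals)

    def test_conventional_fence_option(self):
        # q1=2, q3=4, iqr=2: 1x bounds [0,6] exclude 6.5; 1.5x bounds
        # [-1,7] retain it
        vals = [1, 2, 3, 4, 6.5]
        assert iqr_filter(vals, multiplier=1.0).removed.size == 1
        assert iqr_filter(vals, multiplier=1.5).removed.size == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([1, 2, 3])


class TestTwoSampleTTest:
    def test_identical_samples(self):
        res = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert res.t_stat == 0 and res.p_value == pytest.approx(1.0)

    def test_separated_samples(self):
        res = two_sample_ttest([1, 2, 3], [101, 102, 103])
        assert res.p_value < 0.01 and res.t_stat < 0

    def test_matches_welch_closed_form(self):
        a, b = np.array([1, 2, 3, 4.0]), np.array([2, 3, 4, 5.0])
        res = two_sample_ttest(a, b)
        sa, sb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa ** 2 / 3 + sb ** 2 / 3)
        assert res.t_stat == pytest.approx(t)
        assert res.df == pytest.approx(df)
        from scipy import stats
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), df))

    def test_swap_flips_sign_only(self):
        a, b = [1, 2, 3, 9.0], [4, 4, 5, 6.0]
        r1, r2 = two_sample_ttest(a, b), two_sample_ttest(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_constant_equal_means(self):
        res = two_sample_ttest([2, 2, 2], [2, 2])
        assert res.degenerate and res.p_value == 1.0

    def test_constant_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([2, 2, 2], [3, 3])

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1], [2, 3])


class TestGenomicStats:
    def test_two_exon_example(self):
        m = GeneModel("t", "g", "c", "+", (0, 200), (100, 300))
        stats = compute_gene_stats([m])
        assert stats.exon_sizes["g"] == [100, 100]
        assert stats.intron_sizes["g"] == [100]
        assert stats.exon_counts["g"] == 2

    def test_single_exon_gene(self):
        m = GeneModel("t", "g", "c", "+", (0,), (50,))
        stats = compute_gene_stats([m])
        assert stats.exon_sizes["g"] == [50]
        assert stats.intron_sizes["g"] == []
        assert stats.exon_counts["g"] == 1

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(3)
        models = []
        for i in range(20):
            n = int(rng.integers(1, 8))
            starts, ends, pos = [], [], 0
            for _ in range(n):
                pos += int(rng.integers(50, 500))
                starts.append(pos)
                pos += int(rng.integers(30, 400))
                ends.append(pos)
            models.append(GeneModel(f"t{i}", f"g{i}", "c", "+",
                                    tuple(starts), tuple(ends)))
        stats = compute_gene_stats(models)
        for m in models:
            assert stats.exon_sizes[m.gene] == [
                e - s for s, e in zip(m.exon_starts, m.exon_ends)]
            assert stats.intron_sizes[m.gene] == [
                m.exon_starts[j + 1] - m.exon_ends[j]
                for j in range(m.n_exons - 1)]

    def test_longest_transcript_represents_gene(self):
        short = GeneModel("t1", "g", "c", "+", (0,), (100,))
        long_ = GeneModel("t2", "g", "c", "+", (0, 300), (100, 500))
        stats = compute_gene_stats([short, long_])
        assert stats.exon_counts["g"] == 2

    def test_pooled_selects_genes(self):
        models = [GeneModel("t1", "g1", "c", "+", (0,), (10,)),
                  GeneModel("t2", "g2", "c", "+", (0,), (30,))]
        stats = compute_gene_stats(models)
        assert stats.pooled("exon_size", ["g2"]).tolist() == [30]
        assert sorted(stats.pooled("exon_size")) == [10, 30]


class TestCategoryVsGenome:
    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(0)
        cat = rng.normal(size=40)
        gen = rng.normal(size=400)
        r1 = category_vs_genome_test(cat, gen, seed=7)
        r2 = category_vs_genome_test(cat, gen, seed=7)
        assert (r1.t_stat, r1.p_value) == (r2.t_stat, r2.p_value)

    def test_category_larger_than_genome_rejected(self):
        with pytest.raises(ValueError):
            category_vs_genome_test(np.arange(50), np.arange(10), seed=0)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        gen = rng.normal(0, 1, size=1000)
        cat = rng.normal(5, 1, size=50)
        res = category_vs_genome_test(cat, gen, seed=0)
        assert res.p_value < 0.05 and res.mean_a > res.mean_b
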