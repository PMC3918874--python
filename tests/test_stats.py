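"""Bin-table preparation, normalization algebra, rank-sum correctness and
the category / top-ratio analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endosirna import stats as an
from endosirna.copynumber import CopyNumberTrack
from endosirna.mapping import BinTrack


def make_tracks(sirna_counts, total_counts, cn_values, bin_size=100):
    """Build matching BinTracks and a CopyNumberTrack from plain arrays."""
    n = len(sirna_counts)
    size = n * bin_size
    sizes = {"chrI": size}
    sirna = BinTrack(bin_size, sizes, {("chrI", "."): np.asarray(sirna_counts, dtype=np.int64)})
    total = BinTrack(bin_size, sizes, {("chrI", "."): np.asarray(total_counts, dtype=np.int64)})
    # per-start multiplicity constant within each bin
    mult = np.repeat(np.asarray(cn_values, dtype=float), bin_size)[: size - 19]
    cn = CopyNumberTrack(20, {"chrI": mult}, sizes)
    return sirna, total, cn


def prepared_table(sirna, total, cn_values, **kwargs):
    s, t, c = make_tracks(sirna, total, cn_values)
    return an.make_bin_table(s, t, c, **kwargs)


class TestMakeBinTable:
    def test_pseudocount_applied(self):
        table = prepared_table([0, 5], [0, 9], [1, 1])
        assert list(table["sirna"]) == [1, 6]
        assert list(table["total"]) == [1, 10]
        assert list(table["sirna_raw"]) == [0, 5]

    def test_total_cap_exclusion(self):
        table = prepared_table([0, 0], [100_001, 100_000], [1, 1])
        assert table["excluded"].tolist() == [True, False]
        assert table.loc[0, "exclusion_reason"] == "total_above_max"

    def test_exclusion_regions_flagged(self):
        table = prepared_table(
            [1] * 5, [1] * 5, [1] * 5, exclusion_regions=[("chrI", 150, 250)]
        )
        assert table["excluded"].tolist() == [False, True, True, False, False]

    def test_mismatched_grids_rejected(self):
        s, t, c = make_tracks([1, 2], [1, 2], [1, 1])
        t50 = BinTrack(50, t.chrom_sizes, t.counts)
        with pytest.raises(an.AnalysisError):
            an.make_bin_table(s, t50, c)

    def test_empty_tracks_empty_table(self):
        s = BinTrack(100, {}, {})
        t = BinTrack(100, {}, {})
        c = CopyNumberTrack(20, {}, {})
        assert len(an.make_bin_table(s, t, c)) == 0


class TestNormalize:
    def test_schemes_by_definition(self):
        table = prepared_table([4], [7], [4])
        out = an.normalize(table, "total_times_cn")
        assert out.loc[0, "sirna_norm"] == 5 and out.loc[0, "total_norm"] == 32
        out = an.normalize(table, "none")
        assert out.loc[0, "sirna_norm"] == 5 and out.loc[0, "total_norm"] == 8
        out = an.normalize(table, "both_times_cn")
        assert out.loc[0, "sirna_norm"] == 20 and out.loc[0, "total_norm"] == 32

    def test_cn_one_schemes_coincide(self, rng):
        table = prepared_table(rng.integers(0, 50, 20), rng.integers(0, 50, 20), [1] * 20)
        frames = [an.normalize(table, s) for s in an.SCHEMES]
        for f in frames[1:]:
            pd.testing.assert_frame_equal(
                frames[0][["sirna_norm", "total_norm"]], f[["sirna_norm", "total_norm"]]
            )

    def test_ratio_cancellation_bit_exact(self, rng):
        """siRNA:total ratios are identical under `none` and `both_times_cn`
        — copy-number normalization cancels in the ratio."""
        n = 500
        table = prepared_table(
            rng.integers(0, 100, n),
            rng.integers(0, 1000, n),
            rng.choice([1, 2, 4, 8, 16], n),
        )
        a = an.normalize(table, "none")
        b = an.normalize(table, "both_times_cn")
        ra = a["sirna_norm"].to_numpy() / a["total_norm"].to_numpy()
        rb = b["sirna_norm"].to_numpy() / b["total_norm"].to_numpy()
        assert np.array_equal(ra, rb)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.normalize(prepared_table([1], [1], [1]), "bogus")


class TestRankSum:
    def test_exact_matches_enumeration_oracle(self, rng):
        """Small-group p equals a from-scratch enumeration over all group
        assignments, including tied data."""
        for trial in range(20):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            pool = rng.integers(0, 6, n + m).astype(float)  # heavy ties
            x, y = pool[:n], pool[n:]
            _, p = an.rank_sum_test(x, y)
            # oracle
            ranks = sps.rankdata(pool)
            mu = n * ranks.sum() / (n + m)
            obs = abs(ranks[:n].sum() - mu)
            hits = total = 0
            for comb in itertools.combinations(range(n + m), n):
                w = ranks[list(comb)].sum()
                total += 1
                if abs(w - mu) >= obs - 1e-9:
                    hits += 1
            assert p == pytest.approx(hits / total)

    def test_exact_matches_scipy_without_ties(self, rng):
        for trial in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            _, p = an.rank_sum_test(x, y)
            p_ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_normal_approximation_matches_permutation(self, rng):
        """Asymptotic p within 1e-3 of a 10^5-rep permutation estimate at
        group sizes ~100."""
        x = rng.normal(0.0, 1.0, 100)
        y = rng.normal(0.35, 1.0, 110)
        _, p = an.rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        N = len(pooled)
        mu = len(x) * ranks.sum() / N
        obs = abs(ranks[: len(x)].sum() - mu)
        reps, chunk = 1_000_000, 50_000
        hits = 0
        for _ in range(reps // chunk):
            order = np.argsort(rng.random((chunk, N)), axis=1)[:, : len(x)]
            w = ranks[order].sum(axis=1)
            hits += int(np.count_nonzero(np.abs(w - mu) >= obs - 1e-9))
        p_perm = hits / reps
        assert abs(p - p_perm) < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(an.AnalysisError):
            an.rank_sum_test([], [1.0])


class TestCategoryCompare:
    def _table(self, rng, n=3000, shift=0.0):
        """Single- and multi-copy bins with log-uniform totals; multi siRNA
        optionally shifted upward."""
        cn = rng.choice([1.0, 4.0], n, p=[0.5, 0.5])
        total = np.exp(rng.uniform(np.log(3), np.log(5000), n)).astype(int)
        lam = 5.0 + shift * (cn > 1)
        sirna = rng.poisson(lam)
        return prepared_table(sirna, total, cn)

    def test_empty_multi_group_not_applicable(self, rng):
        table = prepared_table(rng.integers(0, 9, 50), rng.integers(3, 100, 50), [1] * 50)
        cats = an.category_compare(an.normalize(table, "none"))
        assert all(math.isnan(c.p) for c in cats)

    def test_shifted_multi_detected_in_populated_categories(self, rng):
        table = self._table(rng, shift=5.0)
        cats = an.category_compare(an.normalize(table, "none"))
        for c in cats:
            if c.n_single >= 500 and c.n_multi >= 500:
                assert c.p < 0.01
                assert c.multi_higher

    def test_type_one_error_calibrated(self, rng):
        """Identical group distributions: rejection rate at alpha=.05 within
        the 99% binomial CI over simulated tables."""
        n_tables, rejections, applicable = 150, 0, 0
        for _ in range(n_tables):
            table = self._table(rng, n=800, shift=0.0)
            cats = an.category_compare(an.normalize(table, "none"))
            for c in cats:
                if c.applicable and min(c.n_single, c.n_multi) >= 20:
                    applicable += 1
                    rejections += c.p < 0.05
        rate = rejections / applicable
        lo, hi = sps.binom.interval(0.99, applicable, 0.05)
        assert lo / applicable <= rate <= hi / applicable

    def test_non_monotone_boundaries_rejected(self, rng):
        table = an.normalize(self._table(rng, n=100), "none")
        with pytest.raises(an.AnalysisError):
            an.category_compare(table, boundaries=(0, 4, 2))


class TestTopRatio:
    def test_constructed_multi_copy_ratio_dominates(self, rng):
        """Bins where CN>=2 get 10x the ratio: the top 1% is all multi-copy."""
        n = 2000
        cn = np.where(np.arange(n) % 50 == 0, 4.0, 1.0)  # 2% multi
        total = np.full(n, 200)
        sirna = np.where(cn > 1, 100, 10)
        table = prepared_table(sirna, total, cn)
        res = an.top_ratio_analysis(table, 0.01)
        top_cn = table.loc[res.top_index, "copy_number"]
        assert (top_cn > 1).all()
        assert res.p < 1e-6
        assert res.mean_cn_top > res.mean_cn_bulk

    def test_membership_invariant_across_cancelling_schemes(self, rng):
        """Top-1% membership identical whether or not both counts are scaled
        by copy number (ranking uses the normalization-free ratio)."""
        n = 3000
        table = prepared_table(
            rng.integers(0, 60, n),
            rng.integers(3, 3000, n),
            rng.choice([1.0, 2.0, 8.0], n),
        )
        res_none = an.top_ratio_analysis(an.normalize(table, "none"), 0.01)
        res_both = an.top_ratio_analysis(an.normalize(table, "both_times_cn"), 0.01)
        assert list(res_none.top_index) == list(res_both.top_index)

    def test_noise_category_dropped(self):
        # bins with tiny totals carry extreme pseudocount ratios; the noise
        # filter removes them before ranking
        sirna = [50] * 10 + [1] * 990
        total = [0] * 10 + [500] * 990
        table = prepared_table(sirna, total, [1.0] * 1000)
        res = an.top_ratio_analysis(table, 0.01, drop_noise=True)
        noisy = set(range(10))
        assert noisy.isdisjoint(set(res.top_index))

    def test_too_few_bins_rejected(self):
        table = prepared_table([1] * 20, [100] * 20, [1] * 20)
        with pytest.raises(an.AnalysisError):
            an.top_ratio_analysis(table, 0.01)

    def test_cn_histogram_bins(self, rng):
        table = prepared_table(
            [10] * 200, [100] * 200, rng.choice([1.5, 3, 6, 12, 24, 48], 200)
        )
        res = an.top_ratio_analysis(table, 0.05)
        assert set(res.bulk_hist) == set(an.CN_HIST_LABELS)
        assert sum(res.bulk_hist.values()) == res.n_bulk


class TestChromosomeProfile:
    def test_planted_block_recovered(self, rng):
        """Ratio peak co-locates with a planted high-CN block (positive
        correlation of the two aligned series)."""
        n = 500
        cn = np.ones(n)
        cn[200:250] = 8
        sirna = rng.poisson(np.where(cn > 1, 40, 2))
        total = np.full(n, 100)
        table = prepared_table(sirna, total, cn)
        prof = an.chromosome_profile(table, "chrI")
        r = np.corrcoef(prof["ratio"], prof["copy_number"])[0, 1]
        assert r > 0.5

    def test_unknown_chromosome_rejected(self):
        table = prepared_table([1] * 5, [1] * 5, [1] * 5)
        with pytest.raises(an.AnalysisError):
            an.chromosome_profile(table, "chrX")

    def test_empty_table_empty_profile(self):
        table = an.make_bin_table(
            BinTrack(100, {}, {}), BinTrack(100, {}, {}), CopyNumberTrack(20, {}, {})
        )
        prof = an.chromosome_profile(table, "chrI")
        assert len(prof) == 0
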