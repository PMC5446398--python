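"""Read accounting, peak concordance, fold-differences and rank tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mitocleave.genomes import Interval
from mitocleave.metrics import (
    PeakSet,
    classify_reads,
    common_peak_fraction,
    dedup_usable,
    downsample,
    feature_overlap_fraction,
    fold_difference,
    group_concordance,
    peak_readcount_r2,
    rank_test,
    signal_noise,
    top_n,
)


def _reads(chrom, starts, width=50):
    return [Interval(chrom, s, s + width) for s in starts]


class TestDownsample:
    def test_full_sample_is_identity_as_set(self):
        reads = _reads("chr1", range(0, 1000, 10))
        out = downsample(reads, len(reads), 1)
        assert sorted(out, key=lambda r: r.start) == reads

    def test_minimal_sample(self):
        reads = _reads("chr1", [0, 100, 200])
        out = downsample(reads, 1, 2)
        assert len(out) == 1 and out[0] in reads

    def test_deficit_raises_with_amount(self):
        with pytest.raises(ValueError, match="short by 7"):
            downsample(_reads("chr1", [0, 10, 20]), 10, 3)

    def test_mito_fraction_preserved_hypergeometric(self):
        reads = _reads("chrM", range(30_000)) + _reads("chr1", range(70_000))
        out = downsample(reads, 10_000, 4)
        n_mito = sum(1 for r in out if r.chrom == "chrM")
        # hypergeometric SD for n draws from N with K successes
        N, K, n = 100_000, 30_000, 10_000
        sd = math.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
        assert abs(n_mito - n * K / N) <= 3 * sd


class TestClassifyReads:
    def test_all_mito_boundary(self):
        acc = classify_reads(_reads("chrM", [0, 5, 9]), "chrM")
        assert acc.n_usable == 0 and acc.mito_fraction == 1.0

    def test_first_occurrence_duplicate_rule(self):
        reads = _reads("chr1", [100, 100, 100]) + _reads("chr1", [500])
        acc = classify_reads(reads, "chrM")
        assert (acc.n_duplicate, acc.n_usable) == (2, 2)

    def test_clean_library(self):
        acc = classify_reads(_reads("chr1", range(0, 100, 10)), "chrM")
        assert acc.n_usable == acc.depth_sequenced == 10

    def test_partition_is_exact(self):
        rng = np.random.default_rng(5)
        reads = [
            Interval(rng.choice(["chrM", "chr1", "chr2"]),
                     int(s := rng.integers(0, 200)), int(s) + 40)
            for _ in range(500)
        ]
        acc = classify_reads(reads, "chrM")
        assert acc.n_mito + acc.n_duplicate + acc.n_usable == 500

    def test_strand_aware_dedup_configurable(self):
        reads = [Interval("chr1", 0, 50, "+"), Interval("chr1", 0, 50, "-")]
        assert classify_reads(reads, "chrM", use_strand=True).n_duplicate == 0
        assert classify_reads(reads, "chrM", use_strand=False).n_duplicate == 1

    def test_dedup_usable_returns_unique_nonmito(self):
        reads = _reads("chrM", [0]) + _reads("chr1", [10, 10, 30])
        out = dedup_usable(reads, "chrM")
        assert out == _reads("chr1", [10, 30])


class TestSignalNoise:
    def test_manual_overlap_count(self):
        union = [Interval("chr1", 0, 400), Interval("chr1", 1000, 1300)]
        in_reads = _reads("chr1", [0, 100, 399, 1000, 1100, 1200, 1249])
        out_reads = _reads("chr1", range(2000, 2000 + 13 * 60, 60))
        n_in, n_out, ratio = signal_noise(in_reads + out_reads, union)
        assert (n_in, n_out) == (7, 13)
        assert ratio == pytest.approx(7 / 13)

    def test_saturating_union_gives_infinite_ratio(self):
        union = [Interval("chr1", 0, 10_000)]
        _, n_out, ratio = signal_noise(_reads("chr1", [5, 50]), union)
        assert n_out == 0 and ratio == math.inf

    def test_empty_union_all_background(self):
        n_in, n_out, ratio = signal_noise(_reads("chr1", [0, 100]), [])
        assert (n_in, n_out, ratio) == (0, 2, 0.0)


class TestTopN:
    def test_saturation_returns_all(self):
        ps = PeakSet("s", [Interval("chr1", 0, 10, ".", 1.0)])
        assert len(top_n(ps, 100)) == 1

    def test_tie_break_by_position(self):
        peaks = [Interval("chr1", 50, 60, ".", 3.0),
                 Interval("chr1", 10, 20, ".", 3.0),
                 Interval("chr1", 0, 5, ".", 5.0),
                 Interval("chr1", 90, 95, ".", 1.0)]
        out = top_n(PeakSet("s", peaks), 2).peaks
        assert out == [Interval("chr1", 0, 5, ".", 5.0),
                       Interval("chr1", 10, 20, ".", 3.0)]

    def test_zero_n_empty(self):
        ps = PeakSet("s", [Interval("chr1", 0, 10, ".", 1.0)])
        assert len(top_n(ps, 0)) == 0


class TestCommonPeakFraction:
    def test_self_comparison_is_one(self):
        ps = PeakSet("s", [Interval("chr1", i * 100, i * 100 + 50, ".", 1.0)
                           for i in range(10)])
        assert common_peak_fraction(ps, ps) == 1.0

    def test_disjoint_chromosomes_zero(self):
        a = PeakSet("a", [Interval("chr1", 0, 50)])
        b = PeakSet("b", [Interval("chr2", 0, 50)])
        assert common_peak_fraction(a, b) == 0.0

    def test_manual_six_of_ten(self):
        a = PeakSet("a", [Interval("chr1", i * 1000, i * 1000 + 100)
                          for i in range(10)])
        # overlap the first six of a's peaks, miss the rest
        b = PeakSet("b", [Interval("chr1", i * 1000 + 50, i * 1000 + 150)
                          for i in range(6)] +
                    [Interval("chr1", 50_000 + i * 500, 50_000 + i * 500 + 100)
                     for i in range(4)])
        assert common_peak_fraction(a, b) == pytest.approx(0.6)

    def test_empty_query_undefined(self):
        a = PeakSet("a", [])
        b = PeakSet("b", [Interval("chr1", 0, 50)])
        assert math.isnan(common_peak_fraction(a, b))


class TestGroupConcordance:
    def test_identical_samples_all_ones(self):
        peaks = [Interval("chr1", i * 100, i * 100 + 50, ".", 1.0)
                 for i in range(5)]
        sets = {f"s{i}": PeakSet(f"s{i}", list(peaks)) for i in range(4)}
        groups = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        mat = group_concordance(sets, groups)
        assert (mat.to_numpy() == 1.0).all()

    def test_disjoint_groups_zero_off_diagonal(self):
        a_peaks = [Interval("chr1", i * 100, i * 100 + 50) for i in range(5)]
        b_peaks = [Interval("chr2", i * 100, i * 100 + 50) for i in range(5)]
        sets = {"a1": PeakSet("a1", a_peaks), "a2": PeakSet("a2", a_peaks),
                "b1": PeakSet("b1", b_peaks), "b2": PeakSet("b2", b_peaks)}
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        mat = group_concordance(sets, groups)
        assert mat.loc["A", "B"] == 0.0 and mat.loc["B", "A"] == 0.0
        assert mat.loc["A", "A"] == 1.0

    def test_mean_matches_hand_enumeration(self):
        p1 = [Interval("chr1", 0, 100)]
        p2 = [Interval("chr1", 50, 150)]
        p3 = [Interval("chr1", 500, 600)]
        sets = {"s1": PeakSet("s1", p1), "s2": PeakSet("s2", p2),
                "s3": PeakSet("s3", p3)}
        groups = {"s1": "A", "s2": "A", "s3": "A"}
        # ordered pairs: (1,2)=1, (2,1)=1, (1,3)=0, (3,1)=0, (2,3)=0, (3,2)=0
        mat = group_concordance(sets, groups)
        assert mat.loc["A", "A"] == pytest.approx(2 / 6)

    def test_singleton_within_group_undefined(self):
        sets = {"a": PeakSet("a", [Interval("chr1", 0, 10)]),
                "b": PeakSet("b", [Interval("chr1", 0, 10)])}
        groups = {"a": "A", "b": "B"}
        mat = group_concordance(sets, groups)
        assert math.isnan(mat.loc["A", "A"])


class TestPeakReadcountR2:
    def _samples_with_counts(self, counts_a, counts_b):
        """Three disjoint peaks; construct distinct reads giving the
        requested per-peak counts."""
        peaks = [Interval("chr1", i * 1000, i * 1000 + 200) for i in range(3)]
        def reads(counts):
            out = []
            for k, c in enumerate(counts):
                out += [Interval("chr1", k * 1000 + 2 * j, k * 1000 + 2 * j + 30)
                        for j in range(c)]
            return out
        samples = {"a": reads(counts_a), "b": reads(counts_b)}
        sets = {s: PeakSet(s, list(peaks)) for s in samples}
        return samples, sets

    def test_self_comparison_r2_one(self):
        samples, sets = self._samples_with_counts([1, 2, 3], [1, 2, 3])
        r2 = peak_readcount_r2(samples, sets)
        assert r2.loc["a", "a"] == pytest.approx(1.0)

    def test_exact_linearity_r2_one(self):
        samples, sets = self._samples_with_counts([1, 2, 3], [2, 4, 6])
        r2 = peak_readcount_r2(samples, sets)
        assert r2.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        samples, sets = self._samples_with_counts([1, 2, 3], [3, 1, 2])
        r2 = peak_readcount_r2(samples, sets)
        expected = stats.pearsonr([1, 2, 3], [3, 1, 2]).statistic ** 2
        assert r2.loc["a", "b"] == pytest.approx(expected) == pytest.approx(0.25)

    def test_zero_variance_undefined(self):
        samples, sets = self._samples_with_counts([2, 2, 2], [1, 5, 9])
        r2 = peak_readcount_r2(samples, sets)
        assert math.isnan(r2.loc["a", "b"])


class TestFeatureOverlap:
    def test_saturating_peaks(self):
        feats = [Interval("chr1", i * 100, i * 100 + 1) for i in range(5)]
        assert feature_overlap_fraction(
            feats, [Interval("chr1", 0, 10_000)]) == 1.0

    def test_empty_peaks_zero(self):
        feats = [Interval("chr1", 0, 1)]
        assert feature_overlap_fraction(feats, []) == 0.0

    def test_manual_tss_flank_expansion(self):
        # five TSS points; ±1 kb windows; peaks hit windows of TSS 0, 1, 2
        tss = [Interval("chr1", p, p + 1)
               for p in (5_000, 10_000, 15_000, 40_000, 50_000)]
        peaks = [Interval("chr1", 4_200, 4_300),     # in [4000,6000)
                 Interval("chr1", 10_500, 16_500)]   # spans windows 1 and 2
        assert feature_overlap_fraction(tss, peaks, flank=1000) == \
            pytest.approx(0.6)

    def test_monotone_in_peaks(self):
        rng = np.random.default_rng(11)
        feats = [Interval("chr1", int(p), int(p) + 1)
                 for p in rng.integers(0, 100_000, 50)]
        peaks = [Interval("chr1", int(s), int(s) + 500)
                 for s in rng.integers(0, 100_000, 30)]
        prev = 0.0
        for k in range(0, 31, 5):
            frac = feature_overlap_fraction(feats, peaks[:k], flank=1000)
            if k == 0:
                frac = 0.0
            assert frac >= prev
            prev = frac

    def test_no_features_undefined(self):
        assert math.isnan(feature_overlap_fraction([], [Interval("c", 0, 9)]))


class TestFoldDifference:
    def test_ratio_of_medians_usable_fractions(self):
        fd = fold_difference([0.45], [0.19], paired=False)
        assert fd.rounded == 2.4
        assert fd.convention == "ratio-of-medians"

    def test_ratio_of_medians_peak_counts(self):
        fd = fold_difference([26_651], [25_664], paired=False, sig_figs=3)
        assert fd.rounded == 1.04

    def test_ratio_of_medians_treated_groups(self):
        fd = fold_difference([40_682], [30_182], paired=False)
        assert fd.rounded == 1.3

    def test_paired_identity(self):
        fd = fold_difference([3.0, 5.0, 7.0], [3.0, 5.0, 7.0], paired=True)
        assert fd.value == 1.0
        assert fd.convention == "pairwise-median"

    def test_paired_uses_median_of_ratios(self):
        fd = fold_difference([2.0, 30.0], [1.0, 10.0], paired=True)
        assert fd.value == pytest.approx(2.5)  # median of {2, 3}

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_difference([1.0, 0.0], [1.0, 1.0], paired=False)


def _exact_ranksum_p_greater(a, b):
    """Full enumeration of the rank-sum null: P(rank sum of a-labels ≥ obs)
    over all label assignments."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    n = len(a)
    combos = list(itertools.combinations(range(len(pooled)), n))
    count = sum(1 for c in combos
                if sum(i + 1 for i in c) >= obs)
    return count / len(combos)


def _exact_signrank_p_greater(d):
    """Full enumeration of the signed-rank null over all 2^n sign patterns."""
    absd = sorted(abs(x) for x in d)
    ranks = {v: i + 1 for i, v in enumerate(absd)}
    obs = sum(ranks[abs(x)] for x in d if x > 0)
    n = len(d)
    count = 0
    for mask in range(2 ** n):
        w = sum(ranks[absd[i]] for i in range(n) if mask >> i & 1)
        if w >= obs:
            count += 1
    return count / 2 ** n


class TestRankTest:
    def test_paired_all_positive_exact_p(self):
        b = [1.0, 2.0, 3.5, 5.0, 7.0, 11.0, 13.0]
        a = [x + 10 for x in b]
        res = rank_test(a, b, paired=True, direction="greater")
        assert res.test == "wilcoxon-signed-rank" and res.method == "exact"
        assert res.p_value == pytest.approx(1 / 2 ** 7)

    def test_paired_matches_sign_enumeration_oracle(self):
        a = [5.0, 9.0, 1.0, 12.0, 7.0, 3.0, 15.0]
        b = [3.0, 11.5, 0.25, 6.0, 7.9, 2.0, 8.0]
        d = [x - y for x, y in zip(a, b)]
        res = rank_test(a, b, paired=True, direction="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_exact_signrank_p_greater(d))

    def test_unpaired_matches_full_enumeration(self):
        a = [12.0, 15.0, 9.0, 20.0]
        b = [8.0, 11.0, 7.0, 14.0]
        res = rank_test(a, b, paired=False, direction="greater")
        assert res.test == "wilcoxon-rank-sum" and res.method == "exact"
        assert res.p_value == pytest.approx(_exact_ranksum_p_greater(a, b))

    def test_unpaired_shuffled_identical_near_half(self):
        a = [1.0, 4.0, 6.0, 7.0]
        b = [2.0, 3.0, 5.0, 8.0]
        res = rank_test(a, b, paired=False)
        assert 0.3 <= res.p_value <= 0.7

    def test_direction_complementarity_discrete_null(self):
        a = [12.0, 15.0, 9.0, 20.0]
        b = [8.0, 11.0, 7.0, 14.0]
        pg = rank_test(a, b, paired=False, direction="greater").p_value
        pl = rank_test(a, b, paired=False, direction="less").p_value
        assert pg + pl >= 1.0

    def test_all_zero_differences_undefined(self):
        a = [1.0, 2.0, 3.0]
        res = rank_test(a, a, paired=True)
        assert math.isnan(res.p_value)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            rank_test([1.0, 2.0], [3.0, 4.0], paired=False)
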