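"""Benchmark metrics against small-instance oracles and hand-built fixtures."""

import math

import numpy as np
import pytest

from mhcgate.evaluation import (BenchmarkRecord, BenchmarkSample,
                                DegenerateTestError, MetricError, Neoantigen,
                                benchmark_report, compute_sample_metrics,
                                deconvolve_multi_allelic, filter_leakage,
                                immunogenicity_two_step, paired_wilcoxon,
                                ppv_top_k, score_benchmark, spearman_corr)


def auc_roc_oracle(scores, hits):
    """Exhaustive pairwise concordance (ties count half)."""
    pos = [s for s, h in zip(scores, hits) if h == 1]
    neg = [s for s, h in zip(scores, hits) if h == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def auc_pr_oracle(scores, hits):
    """Step-sum average precision: sum over positives of precision at their
    rank (descending scores, assuming no ties)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp, total = 0, 0.0
    for rank, i in enumerate(order, start=1):
        if hits[i] == 1:
            tp += 1
            total += tp / rank
    return total / sum(hits)


class TestDeconvolution:
    def test_maximum_over_alleles(self):
        record = BenchmarkRecord("SIINFEKL", ("A1", "A2", "A3"), hit=1)
        table = {"A1": 0.1, "A2": 0.9, "A3": 0.3}
        assert deconvolve_multi_allelic(record, lambda p, a: table[a]) == 0.9

    def test_single_allele_returns_its_score(self):
        record = BenchmarkRecord("SIINFEKL", ("A1",), hit=0)
        assert deconvolve_multi_allelic(record, lambda p, a: 0.42) == 0.42

    def test_adding_allele_never_decreases_score(self):
        table = {"A1": 0.3, "A2": 0.1, "A3": 0.8}
        small = BenchmarkRecord("SIINFEKL", ("A1", "A2"), hit=1)
        big = BenchmarkRecord("SIINFEKL", ("A1", "A2", "A3"), hit=1)
        scorer = lambda p, a: table[a]
        assert deconvolve_multi_allelic(big, scorer) >= \
            deconvolve_multi_allelic(small, scorer)

    def test_seven_alleles_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkRecord("SIINFEKL", tuple("ABCDEFG"), hit=0)


class TestSampleMetrics:
    def test_matches_exhaustive_oracles_on_small_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 20))
            scores = rng.uniform(size=n)  # continuous: ties have measure 0
            hits = (rng.uniform(size=n) < 0.4).astype(int)
            if hits.min() == hits.max():
                continue
            auc_roc, auc_pr, _ = compute_sample_metrics(scores, hits)
            assert auc_roc == pytest.approx(auc_roc_oracle(scores, hits))
            assert auc_pr == pytest.approx(auc_pr_oracle(scores, hits))

    def test_perfect_scorer_at_exact_one_percent_prevalence(self):
        n, n_pos = 1000, 10
        hits = np.array([1] * n_pos + [0] * (n - n_pos))
        scores = np.linspace(1, 0, n)  # positives get the top scores
        auc_roc, auc_pr, ppv = compute_sample_metrics(scores, hits)
        assert auc_roc == 1.0
        assert auc_pr == pytest.approx(1.0)
        assert ppv == 1.0

    def test_random_scorer_baselines(self):
        gen = np.random.default_rng(77)
        n = 10_000
        # AUC-ROC baseline at balanced prevalence (variance ~ 1/(12 n_pos))
        hits = (gen.uniform(size=n) < 0.5).astype(int)
        auc_roc, _, _ = compute_sample_metrics(gen.uniform(size=n), hits)
        assert auc_roc == pytest.approx(0.5, abs=0.02)
        # AUC-PR baseline equals prevalence for a label-independent scorer
        hits = np.zeros(n, dtype=int)
        hits[gen.choice(n, size=100, replace=False)] = 1  # 1% prevalence
        _, auc_pr, _ = compute_sample_metrics(gen.uniform(size=n), hits)
        assert auc_pr == pytest.approx(0.01, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            compute_sample_metrics([0.1, 0.9], [1, 1])

    def test_top1pct_count_is_ceiling(self):
        # n=150 -> ceil(1.5)=2 top records
        scores = np.linspace(1, 0, 150)
        hits = np.zeros(150, dtype=int)
        hits[:2] = 1
        hits[10] = 1
        _, _, ppv = compute_sample_metrics(scores, hits)
        assert ppv == 1.0


class TestPPVTopK:
    @pytest.mark.parametrize("hits,expected", [
        ([1, 1, 1, 1, 1, 0, 0], 1.0),
        ([0, 0, 0, 0, 0, 1, 1], 0.0),
        ([1, 0, 1, 0, 0, 1, 1], 0.4),
    ])
    def test_top5_fraction(self, hits, expected):
        scores = np.linspace(1, 0, len(hits))
        assert ppv_top_k(scores, hits, k=5) == pytest.approx(expected)

    def test_short_input_warns_and_uses_all(self):
        with pytest.warns(UserWarning):
            out = ppv_top_k([0.9, 0.1], [1, 0], k=5)
        assert out == 0.5


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_corr(x, x) == pytest.approx(1.0)
        assert spearman_corr(x, x[::-1]) == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        # ranks differ by d = (1,-1,1,-1,0): rho = 1 - 6*4/(5*24) = 0.8
        assert spearman_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == \
            pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(MetricError):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_eight_pair_exact_p_value(self):
        """Signed ranks {-1,-2} vs rest positive: W=3, exact two-sided
        p = 2 * 5/256 = 0.0390625 (hand enumeration of rank subsets)."""
        base = np.zeros(8)
        diffs = np.array([-1.0, -2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        assert paired_wilcoxon(base + diffs, base) == \
            pytest.approx(0.0390625)

    def test_null_type_one_error_rate_near_alpha(self):
        gen = np.random.default_rng(31)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            a = gen.normal(size=15)
            b = gen.normal(size=15)
            if paired_wilcoxon(a, b) < 0.05:
                rejections += 1
        assert rejections / n_reps == pytest.approx(0.05, abs=0.02)


def _sample(sid, records):
    return BenchmarkSample(sample_id=sid, records=records)


def _rec(pep, alleles, hit):
    return BenchmarkRecord(pep, alleles, hit=hit)


class TestLeakageFilter:
    def test_no_overlap_is_identity(self):
        samples = [_sample("s1", [_rec("AAAAAAAA", ("A1",), 1),
                                  _rec("CCCCCCCC", ("A1",), 0)])]
        out = filter_leakage(samples, {("DDDDDDDD", "A1")})
        assert len(out) == 1
        assert len(out[0].records) == 2

    def test_sample_with_only_leaked_positives_dropped(self):
        samples = [_sample("s1", [_rec("AAAAAAAA", ("A1",), 1),
                                  _rec("CCCCCCCC", ("A1",), 0)])]
        out = filter_leakage(samples, {("AAAAAAAA", "A1")})
        assert out == []  # surviving positive fraction 0 < 0.1%

    def test_hand_counted_three_sample_fixture(self):
        train = {("AAAAAAAA", "A1"), ("EEEEEEEE", "A2")}
        samples = [
            # s1: one of two positives leaked -> 3 records survive, 1/3 pos
            _sample("s1", [_rec("AAAAAAAA", ("A1",), 1),
                           _rec("DDDDDDDD", ("A1",), 1),
                           _rec("CCCCCCCC", ("A1",), 0),
                           _rec("GGGGGGGG", ("A1",), 0)]),
            # s2: positive leaked via its second allele -> dropped
            _sample("s2", [_rec("EEEEEEEE", ("A1", "A2"), 1),
                           _rec("FFFFFFFF", ("A1", "A2"), 0)]),
            # s3: untouched
            _sample("s3", [_rec("HHHHHHHH", ("A3",), 1),
                           _rec("IIIIIIII", ("A3",), 0)]),
        ]
        out = filter_leakage(samples, train)
        assert [s.sample_id for s in out] == ["s1", "s3"]
        assert sum(len(s.records) for s in out) == 5

    def test_idempotent_and_never_grows(self):
        samples = [_sample("s1", [_rec("AAAAAAAA", ("A1",), 1),
                                  _rec("CCCCCCCC", ("A1",), 0)])]
        once = filter_leakage(samples, set())
        twice = filter_leakage(once, set())
        assert sum(len(s.records) for s in once) <= \
            sum(len(s.records) for s in samples)
        assert [len(s.records) for s in twice] == \
            [len(s.records) for s in once]


class TestImmunogenicity:
    def test_agretopicity_arithmetic_and_filtering(self):
        keep = Neoantigen("n1", 0.9, mutant_nM=10.0, wildtype_nM=1000.0,
                          immunogenic=1)
        drop = Neoantigen("n2", 0.8, mutant_nM=500.0, wildtype_nM=500.0,
                          immunogenic=1)
        assert keep.agretopicity == pytest.approx(0.01)
        assert drop.agretopicity == pytest.approx(1.0)
        ranked, _ = immunogenicity_two_step([keep, drop])
        assert [n.name for n in ranked] == ["n1"]

    def test_nonpositive_wildtype_rejected(self):
        bad = Neoantigen("n", 0.5, mutant_nM=10.0, wildtype_nM=0.0,
                         immunogenic=0)
        with pytest.raises(MetricError):
            immunogenicity_two_step([bad])

    def test_ppv5_with_and_without_filter_on_hand_fixture(self):
        # 10 candidates; immunogenic ones have low agretopicity.
        # Without the filter the top 5 by score hold 2 true positives
        # (PPV5 = 0.4); the filter removes the three high-agretopicity
        # decoys from the top, leaving 4 positives in the top 5 (PPV5 = 0.8).
        neo = [
            Neoantigen("p1", 0.99, 10, 1000, 0),   # decoy, agre 0.01... kept
            Neoantigen("p2", 0.98, 900, 1000, 0),  # agre 0.9 -> filtered
            Neoantigen("p3", 0.97, 800, 1000, 0),  # filtered
            Neoantigen("p4", 0.96, 700, 1000, 0),  # filtered
            Neoantigen("p5", 0.95, 20, 1000, 1),
            Neoantigen("p6", 0.94, 30, 1000, 1),
            Neoantigen("p7", 0.93, 40, 1000, 1),
            Neoantigen("p8", 0.92, 50, 1000, 1),
            Neoantigen("p9", 0.91, 60, 1000, 0),
            Neoantigen("p10", 0.90, 70, 1000, 0),
        ]
        no_filter = ppv_top_k([n.presentation_score for n in neo],
                              [n.immunogenic for n in neo], k=5)
        assert no_filter == pytest.approx(0.2)
        _, ppv5 = immunogenicity_two_step(neo, threshold=0.1)
        assert ppv5 == pytest.approx(0.8)


class TestBenchmarkReport:
    def test_report_medians_and_scoring(self):
        samples = []
        for sid in ("a", "b", "c"):
            recs = [_rec("AAAAAAAA", ("A1",), 1), _rec("CCCCCCCC", ("A1",), 0),
                    _rec("DDDDDDDD", ("A1",), 0)]
            samples.append(_sample(sid, recs))
        scorer = lambda p, a: {"AAAAAAAA": 0.9, "CCCCCCCC": 0.2,
                               "DDDDDDDD": 0.1}[p]
        score_benchmark(samples, scorer)
        report = benchmark_report(samples)
        assert len(report.per_sample) == 3
        assert report.medians["auc_roc"] == 1.0
        assert set(report.to_json()) == {"per_sample", "medians",
                                         "paired_tests"}
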