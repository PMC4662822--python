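"""Window binning, the gap-rule cluster caller, and cluster classification.

The cluster caller is checked against an independent brute-force oracle
that enumerates all maximal qualifying window runs directly from the rule.
"""

import random

import pytest

from pirnakit import cluster_caller as cc
from pirnakit.io_formats import (
    AlignmentRecord,
    GenomicInterval,
    MaskedInterval,
)

W = 5000


def _aln(rid, chrom, start, length=27, strand="+"):
    return AlignmentRecord(
        rid, GenomicInterval(chrom, start, start + length, strand), 1
    )


def _window(index, plus, minus, chrom="chr1"):
    return cc.Window(
        chrom=chrom,
        index=index,
        interval=GenomicInterval(chrom, index * W, (index + 1) * W),
        count_plus=plus,
        count_minus=minus,
    )


def brute_force_runs(counts, min_per_window, max_gap, min_total):
    """Enumerate maximal qualifying runs directly from the rule definition.

    ``counts`` maps window index -> total count on one chromosome.  A run
    starts and ends on qualifying windows, every internal sub-threshold gap
    is at most ``max_gap`` window positions, the run is not extendable, and
    its summed count (gap windows included) reaches ``min_total``.
    """
    qual = sorted(i for i, n in counts.items() if n >= min_per_window)
    results = []
    for a in range(len(qual)):
        for b in range(a, len(qual)):
            members = qual[a : b + 1]
            if any(
                members[k + 1] - members[k] - 1 > max_gap
                for k in range(len(members) - 1)
            ):
                continue
            if a > 0 and members[0] - qual[a - 1] - 1 <= max_gap:
                continue  # extendable leftwards: not maximal
            if b < len(qual) - 1 and qual[b + 1] - members[-1] - 1 <= max_gap:
                continue  # extendable rightwards
            total = sum(counts.get(i, 0) for i in range(members[0], members[-1] + 1))
            if total >= min_total:
                results.append((members[0], members[-1], total))
    return sorted(results)


class TestBinToWindows:
    def test_plus_strand_five_prime(self):
        (w,) = cc.bin_to_windows([_aln("r", "chr1", 12003, 26)], W)
        assert (w.index, w.count_plus, w.count_minus) == (2, 1, 0)
        assert (w.interval.start, w.interval.end) == (10000, 15000)

    def test_minus_strand_five_prime_is_rightmost_base(self):
        # interval [4998, 5024): the 5' end of a minus read is base 5023
        (w,) = cc.bin_to_windows([_aln("r", "chr1", 4998, 26, "-")], W)
        assert w.index == 1
        assert w.count_minus == 1

    def test_empty_input(self):
        assert cc.bin_to_windows([], W) == []

    def test_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            cc.bin_to_windows(
                [_aln("r", "chr1", 990, 27)], W, chrom_lengths={"chr1": 1000}
            )


class TestMinTotalThreshold:
    @pytest.mark.parametrize(
        "n,expected", [(568080, 284), (202533, 101), (0, 0)]
    )
    def test_reference_thresholds(self, n, expected):
        assert cc.min_total_threshold(n, 0.0005) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cc.min_total_threshold(-1)


class TestCallClusters:
    def test_gap_of_four_continues_cluster(self):
        windows = [_window(0, 12, 0)] + [
            _window(i, 2, 0) for i in range(1, 5)
        ] + [_window(5, 15, 0)]
        (cluster,) = cc.call_clusters(windows, 10, 4, min_total=0)
        assert (cluster.interval.start, cluster.interval.end) == (0, 6 * W)
        # sub-threshold gap windows still contribute to the total
        assert cluster.n_unique_pirnas == 12 + 4 * 2 + 15

    def test_gap_of_five_splits(self):
        windows = [_window(0, 12, 0), _window(6, 15, 0)]
        clusters = cc.call_clusters(windows, 10, 4, min_total=0)
        assert len(clusters) == 2
        assert clusters[0].interval.end == W
        assert clusters[1].interval.start == 6 * W

    def test_all_below_threshold(self):
        windows = [_window(i, 4, 4) for i in range(10)]
        assert cc.call_clusters(windows, 10, 4, 0) == []

    def test_min_total_filters_candidates(self):
        windows = [_window(0, 12, 0), _window(6, 200, 100)]
        clusters = cc.call_clusters(windows, 10, 4, min_total=50)
        assert len(clusters) == 1
        assert clusters[0].n_unique_pirnas == 300

    def test_no_chromosome_crossing(self):
        windows = [_window(0, 50, 0, "chr1"), _window(1, 50, 0, "chr2")]
        clusters = cc.call_clusters(windows, 10, 4, 0)
        assert len(clusters) == 2
        assert {c.chrom for c in clusters} == {"chr1", "chr2"}

    def _random_case(self, rng):
        n = rng.randint(1, 200)
        counts = {}
        for i in range(n):
            if rng.random() < 0.3:
                counts[i] = rng.randint(1, 30)
        min_per_window = rng.randint(1, 15)
        max_gap = rng.randint(0, 6)
        min_total = rng.randint(0, 80)
        return counts, min_per_window, max_gap, min_total

    def test_equals_brute_force_on_random_vectors(self):
        rng = random.Random(2024)
        for _ in range(200):
            counts, mpw, gap, mt = self._random_case(rng)
            windows = [_window(i, c, 0) for i, c in counts.items()]
            got = sorted(
                (
                    c.interval.start // W,
                    c.interval.end // W - 1,
                    c.n_unique_pirnas,
                )
                for c in cc.call_clusters(windows, mpw, gap, mt)
            )
            assert got == brute_force_runs(counts, mpw, gap, mt)

    def test_qualifying_windows_always_covered_before_min_total(self):
        rng = random.Random(5)
        for _ in range(50):
            counts, mpw, gap, _ = self._random_case(rng)
            windows = [_window(i, c, 0) for i, c in counts.items()]
            clusters = cc.call_clusters(windows, mpw, gap, min_total=0)
            for i, c in counts.items():
                if c >= mpw:
                    assert any(
                        cl.interval.start <= i * W < cl.interval.end
                        for cl in clusters
                    )

    def test_disjoint_and_sorted(self):
        rng = random.Random(9)
        for _ in range(50):
            counts, mpw, gap, mt = self._random_case(rng)
            windows = [_window(i, c, 0) for i, c in counts.items()]
            clusters = cc.call_clusters(windows, mpw, gap, mt)
            for a, b in zip(clusters, clusters[1:]):
                assert (a.chrom, a.interval.start) <= (b.chrom, b.interval.start)
                if a.chrom == b.chrom:
                    assert a.interval.end <= b.interval.start

    def test_monotonicity_in_thresholds(self):
        # raising min_total can only drop clusters; raising max_gap can only
        # merge *candidate* runs, so its monotonicity holds before the
        # min_total filter (after it, a merge can lift two failing runs
        # above the total threshold, so no monotonicity is promised there)
        rng = random.Random(31)
        for _ in range(40):
            counts, mpw, gap, mt = self._random_case(rng)
            windows = [_window(i, c, 0) for i, c in counts.items()]
            base = len(cc.call_clusters(windows, mpw, gap, mt))
            assert len(cc.call_clusters(windows, mpw, gap, mt + 10)) <= base
            candidates = len(cc.call_clusters(windows, mpw, gap, 0))
            assert len(cc.call_clusters(windows, mpw, gap + 1, 0)) <= candidates


class TestStrandBias:
    def _cluster(self, plus, minus):
        return cc.Cluster(
            chrom="chr1",
            interval=GenomicInterval("chr1", 0, W),
            n_unique_pirnas=plus + minus,
            count_plus=plus,
            count_minus=minus,
        )

    @pytest.mark.parametrize(
        "plus,minus,fraction,bias,strand",
        [
            (76, 24, 0.76, "strong", "+"),
            (9, 91, 0.91, "near_exclusive", "-"),
            (50, 50, 0.5, "unbiased", "none"),
            (75, 25, 0.75, "unbiased", "+"),   # boundary: strictly more than
            (90, 10, 0.90, "strong", "+"),
        ],
    )
    def test_classification(self, plus, minus, fraction, bias, strand):
        got = cc.strand_bias(self._cluster(plus, minus))
        assert got == (pytest.approx(fraction), bias, strand)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cc.strand_bias(self._cluster(0, 0))


class TestAssignChromatin:
    def _cluster(self, chrom, start, end):
        return cc.Cluster(
            chrom=chrom,
            interval=GenomicInterval(chrom, start, end),
            n_unique_pirnas=100,
            count_plus=60,
            count_minus=40,
        )

    def test_majority_overlap_wins(self):
        domains = [
            (GenomicInterval("chr1", 0, 6000), "euchromatic"),
            (GenomicInterval("chr1", 6000, 20000), "pericentromeric"),
        ]
        # 60 % euchromatic, 40 % pericentromeric by bp
        (c,) = cc.assign_chromatin([self._cluster("chr1", 0, 10000)], domains)
        assert c.chromatin_class == "euchromatic"

    def test_full_containment_and_outside(self):
        domains = [(GenomicInterval("chr1", 0, 50000), "pericentromeric")]
        inside, outside = cc.assign_chromatin(
            [self._cluster("chr1", 1000, 2000), self._cluster("chr2", 0, 1000)],
            domains,
        )
        assert inside.chromatin_class == "pericentromeric"
        assert outside.chromatin_class == "unassigned"

    def test_tie_goes_to_more_heterochromatic(self):
        domains = [
            (GenomicInterval("chr1", 0, 5000), "euchromatic"),
            (GenomicInterval("chr1", 5000, 10000), "pericentromeric"),
        ]
        (c,) = cc.assign_chromatin([self._cluster("chr1", 0, 10000)], domains)
        assert c.chromatin_class == "pericentromeric"

    def test_overlapping_domains_rejected(self):
        domains = [
            (GenomicInterval("chr1", 0, 5000), "euchromatic"),
            (GenomicInterval("chr1", 4000, 9000), "pericentromeric"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            cc.assign_chromatin([self._cluster("chr1", 0, 1000)], domains)


class TestTeContent:
    def _cluster(self):
        return cc.Cluster(
            chrom="chr1",
            interval=GenomicInterval("chr1", 0, 10000),
            n_unique_pirnas=10,
            count_plus=10,
            count_minus=0,
        )

    def _mask(self, start, end):
        return MaskedInterval(GenomicInterval("chr1", start, end, "+"), "te")

    def test_overlapping_masks_merged(self):
        # union of [0,2k) and [1k,3k) is 3 kb of a 10-kb cluster
        frac = cc.cluster_te_content(
            self._cluster(), [self._mask(0, 2000), self._mask(1000, 3000)]
        )
        assert frac == pytest.approx(0.3)

    def test_extremes(self):
        assert cc.cluster_te_content(self._cluster(), [self._mask(0, 10000)]) == 1.0
        assert cc.cluster_te_content(self._cluster(), []) == 0.0


class TestProductionShares:
    def test_single_euchromatic_cluster_takes_all(self):
        cluster = cc.Cluster(
            chrom="chr1",
            interval=GenomicInterval("chr1", 0, 10000),
            n_unique_pirnas=3,
            count_plus=3,
            count_minus=0,
            chromatin_class="euchromatic",
        )
        alns = [_aln(f"r{i}", "chr1", 100 * i) for i in range(5)]
        shares = cc.production_shares([cluster], alns)
        assert shares["euchromatic"] == 1.0
        assert shares["outside_clusters"] == 0.0

    def test_no_clusters_all_outside(self):
        alns = [_aln("r", "chr1", 100)]
        shares = cc.production_shares([], alns)
        assert shares["outside_clusters"] == 1.0

    def test_shares_sum_to_one(self, pipeline_bundle):
        shares = pipeline_bundle["production_shares"]
        assert sum(shares.values()) == pytest.approx(1.0)


class TestRankClusters:
    def _cluster(self, chrom, start, n):
        return cc.Cluster(
            chrom=chrom,
            interval=GenomicInterval(chrom, start, start + W),
            n_unique_pirnas=n,
            count_plus=n,
            count_minus=0,
        )

    def test_descending_with_positional_tiebreak(self):
        clusters = [
            self._cluster("chr2", 0, 300),
            self._cluster("chr1", 5000, 500),
            self._cluster("chr1", 0, 300),
        ]
        ranked = cc.rank_clusters(clusters)
        assert [(c.n_unique_pirnas, c.chrom, c.interval.start) for c in ranked] == [
            (500, "chr1", 5000),
            (300, "chr1", 0),
            (300, "chr2", 0),
        ]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_top_n_truncates_gracefully(self):
        clusters = [self._cluster("chr1", 0, 10)]
        assert len(cc.rank_clusters(clusters, top_n=5)) == 1
        assert len(cc.rank_clusters(clusters, top_n=0)) == 0
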