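import numpy as np
import pandas as pd
import pytest

from promarch import cage


def _ctss(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "count"])


def _powerlaw_counts(n, alpha, seed, cap=10**6):
    """Discrete samples whose reverse-cumulative follows slope -alpha."""
    rng = np.random.default_rng(seed)
    x = np.floor(rng.random(n) ** (-1.0 / alpha)).astype(int)
    return x[(x >= 1) & (x <= cap)]


class TestPowerLaw:
    def test_normalized_slope_matches_reference(self):
        counts = _powerlaw_counts(200_000, 1.19, seed=11)
        df = _ctss(
            {"contig": "c", "pos": np.arange(1, len(counts) + 1),
             "strand": "+", "count": counts}
        )
        norm = cage.powerlaw_normalize(df)
        _, slope = cage.fit_powerlaw_slope(norm["count"].to_numpy(), 3, 40_000)
        assert slope == pytest.approx(-1.19, abs=0.05)

    def test_monotone_rank_preserving(self):
        counts = _powerlaw_counts(50_000, 1.3, seed=4)
        df = _ctss(
            {"contig": "c", "pos": np.arange(1, len(counts) + 1),
             "strand": "+", "count": counts}
        )
        norm = cage.powerlaw_normalize(df)["count"].to_numpy()
        order = np.argsort(counts, kind="stable")
        assert np.all(np.diff(norm[order]) >= -1e-12)

    def test_default_reference_parameters(self):
        params = cage.PowerLawParams()
        assert params.alpha_ref == 1.19
        assert params.t_ref == 1e6
        assert (params.fit_min, params.fit_max) == (3, 40_000)

    def test_too_few_distinct_counts_error(self):
        df = _ctss([("c", i, "+", 5) for i in range(1, 10)])
        with pytest.raises(ValueError):
            cage.powerlaw_normalize(df)


class TestClustering:
    def test_gap_at_most_max_dist_merges(self):
        df = _ctss([("c", 100, "+", 1), ("c", 125, "+", 1)])
        assert len(cage.cluster_ctss(df, 30)) == 1

    def test_gap_above_max_dist_splits(self):
        df = _ctss([("c", 100, "+", 1), ("c", 140, "+", 1)])
        assert len(cage.cluster_ctss(df, 30)) == 2

    def test_opposite_strands_never_merge(self):
        df = _ctss([("c", 100, "+", 1), ("c", 101, "-", 1)])
        assert len(cage.cluster_ctss(df, 30)) == 2

    def test_clusters_partition_input_positions(self, rng):
        pos = np.unique(rng.integers(1, 5000, size=300))
        df = _ctss([("c", int(p), "+", int(rng.integers(1, 9))) for p in pos])
        clusters = cage.cluster_ctss(df, 30)
        covered = np.concatenate([c.positions for c in clusters])
        assert sorted(covered) == sorted(pos)
        for a, b in zip(clusters, clusters[1:]):
            assert a.end < b.start


class TestInterquantile:
    def test_hand_enumerated_example(self):
        df = _ctss([("c", 100 + i, "+", v) for i, v in enumerate([1, 2, 4, 2, 1])])
        (cluster,) = cage.cluster_ctss(df, 30)
        # cumulative sums 1,3,7,9,10 vs thresholds 1 and 9
        assert (cluster.q_low, cluster.q_up, cluster.iq_width) == (100, 103, 4)

    def test_single_position_width_one(self):
        df = _ctss([("c", 500, "+", 7)])
        (cluster,) = cage.cluster_ctss(df, 30)
        assert cluster.iq_width == 1

    def test_uniform_ten_positions(self):
        df = _ctss([("c", 100 + i, "+", 1) for i in range(10)])
        (cluster,) = cage.cluster_ctss(df, 30)
        # thresholds 1 and 9 of total 10 -> 1st and 9th positions
        assert (cluster.q_low, cluster.q_up, cluster.iq_width) == (100, 108, 9)

    def test_interquantile_contains_at_least_80pct(self, rng):
        for _ in range(20):
            sig = rng.integers(1, 30, size=rng.integers(2, 40))
            df = _ctss([("c", 10 + i, "+", int(v)) for i, v in enumerate(sig)])
            (cluster,) = cage.cluster_ctss(df, 60)
            inside = (cluster.positions >= cluster.q_low) & (
                cluster.positions <= cluster.q_up
            )
            assert cluster.signal[inside].sum() >= 0.8 * cluster.signal.sum() - 1e-9

    def test_zero_signal_error(self):
        c = cage.TssCluster(
            "c", "+", 1, 1, np.array([1]), np.array([0.0])
        )
        with pytest.raises(ValueError):
            cage.interquantile_bounds(c)


class TestAggregation:
    def _sample(self, positions, counts, strand="+"):
        df = _ctss(
            [("c", p, strand, v) for p, v in zip(positions, counts)]
        )
        return df, cage.cluster_ctss(df, 30)

    def test_nearby_central_regions_merge(self):
        d1, s1 = self._sample(range(100, 121), [5] * 21)
        d2, s2 = self._sample(range(150, 161), [5] * 11)
        cons = cage.aggregate_clusters([s1, s2], [d1, d2], max_dist=100)
        assert len(cons) == 1

    def test_low_tpm_clusters_dropped(self):
        d1, s1 = self._sample([100], [0.4])
        d2, s2 = self._sample([100], [0.4])
        assert cage.aggregate_clusters([s1, s2], [d1, d2], tpm_min=0.5) == []

    def test_idempotent_on_identical_replicates(self):
        # identical replicates: one consensus whose span is the constituent
        # central region, dominant TSS unchanged, refined bounds nested inside
        d, s = self._sample(range(100, 110), [1, 2, 5, 9, 4, 2, 1, 1, 1, 1])
        cons = cage.aggregate_clusters([s, s], [d, d])
        assert len(cons) == 1
        assert (cons[0].start, cons[0].end) == (s[0].q_low, s[0].q_up)
        assert cons[0].dominant == s[0].dominant
        assert s[0].q_low <= cons[0].q_low <= cons[0].q_up <= s[0].q_up

    def test_sample_order_invariant(self):
        d1, s1 = self._sample(range(100, 110), [3, 1, 4, 1, 5, 9, 2, 6, 5, 3])
        d2, s2 = self._sample(range(130, 140), [2, 7, 1, 8, 2, 8, 1, 8, 2, 8])
        a = cage.aggregate_clusters([s1, s2], [d1, d2])
        b = cage.aggregate_clusters([s2, s1], [d2, d1])
        assert [(c.start, c.end, c.tpm, c.dominant) for c in a] == [
            (c.start, c.end, c.tpm, c.dominant) for c in b
        ]


class TestDominantTss:
    def test_argmax(self):
        assert cage.dominant_tss(
            np.array([10, 11, 12]), np.array([1.0, 5.0, 2.0]), "+"
        ) == 11

    @pytest.mark.parametrize("strand,expected", [("+", 10), ("-", 11)])
    def test_tie_breaks_upstream(self, strand, expected):
        assert cage.dominant_tss(
            np.array([10, 11]), np.array([3.0, 3.0]), strand
        ) == expected

    def test_single_position(self):
        assert cage.dominant_tss(np.array([42]), np.array([1.0]), "+") == 42


class TestPromoterSelection:
    def _cluster(self, tpm, iq_width, single=False, dominant=100):
        c = cage.TssCluster(
            "c", "+", 90, 110, np.array([dominant]), np.array([tpm]),
            tpm=tpm, single_tss=single, dominant=dominant,
        )
        c.iq_width = iq_width
        c.q_low, c.q_up = 95, 95 + iq_width - 1
        return c

    def test_single_tss_below_threshold_excluded(self):
        out = cage.select_promoters([self._cluster(2.9, 1, single=True)])
        assert out == []

    def test_narrow_strict_inequality(self):
        narrow = cage.select_promoters([self._cluster(5, 10)])[0]
        wide = cage.select_promoters([self._cluster(5, 11)])[0]
        assert narrow.narrow and not wide.narrow

    def test_highest_tpm_cluster_per_gene_kept(self):
        clusters = [self._cluster(5, 5), self._cluster(9, 5, dominant=300)]
        out = cage.select_promoters(clusters, gene_of={0: "gA", 1: "gA"})
        assert len(out) == 1
        assert out[0].tpm == 9
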