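"""Empirical pipeline: replicate averaging, JC distances, binning, null."""

import itertools

import numpy as np
import pandas as pd
import pytest

import guildspec as gs
from guildspec.fielddata import DistanceMatrix


def _replicate_frame():
    cols = [f"{d}_{r}" for d in (1, 2, 3) for r in (1, 2, 3)]
    data = {
        f"{d}_{r}": [0.1 * r + d * 0.0, 0.2]  # taxonA varies by replicate
        for d in (1, 2, 3)
        for r in (1, 2, 3)
    }
    return pd.DataFrame(data, index=["taxonA", "taxonB"])[cols]


class TestLoadAndAverage:
    def test_replicates_averaged(self):
        table = gs.load_and_average(_replicate_frame())
        assert np.allclose(table.values[0], 0.2)  # mean of 0.1, 0.2, 0.3
        assert np.allclose(table.values[1], 0.2)
        assert table.times.tolist() == [1, 2, 3]

    def test_single_replicate_identity(self):
        frame = pd.DataFrame(
            {"1": [0.5], "2": [0.25], "3": [0.125]}, index=["t1"]
        )
        table = gs.load_and_average(frame)
        assert table.values.tolist() == [[0.5, 0.25, 0.125]]

    def test_missing_day_reported(self):
        frame = _replicate_frame().drop(columns=["2_3"])
        with pytest.raises(ValueError, match="replicate 3: days \\[2\\]"):
            gs.load_and_average(frame)

    def test_irregular_spacing_rejected(self):
        frame = pd.DataFrame({"1": [0.1], "2": [0.1], "5": [0.1]}, index=["t"])
        with pytest.raises(ValueError, match="not equally spaced"):
            gs.load_and_average(frame)

    def test_relative_flag_detected(self):
        frame = pd.DataFrame({"1": [0.4, 0.6], "2": [0.7, 0.3]}, index=["a", "b"])
        assert gs.load_and_average(frame).is_relative
        frame10 = frame * 10
        assert not gs.load_and_average(frame10).is_relative


class TestFilterAlwaysPresent:
    def test_zero_day_drops_taxon(self):
        table = gs.AbundanceTable(
            taxa=["a", "b"], times=np.array([1, 2]), values=np.array([[0.1, 0.0], [0.2, 0.3]])
        )
        out = gs.filter_always_present(table)
        assert out.taxa == ["b"]

    def test_matches_exhaustive_scan(self, rng):
        values = rng.random((20, 15))
        values[rng.random((20, 15)) < 0.2] = 0.0
        table = gs.AbundanceTable(taxa=[f"t{i}" for i in range(20)], times=np.arange(15), values=values)
        expected = [f"t{i}" for i in range(20) if all(values[i, j] > 0 for j in range(15))]
        if expected:
            assert gs.filter_always_present(table).taxa == expected
        else:
            with pytest.raises(ValueError):
                gs.filter_always_present(table)


class TestJukesCantor:
    def test_identical_sequences(self):
        d = gs.jukes_cantor([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert d.values[0, 1] == 0.0

    def test_known_mismatch_fraction(self):
        # 30 mismatches over 100 sites: d = -(3/4) ln(1 - 0.4) = 0.3831
        s1 = "A" * 100
        s2 = "C" * 30 + "A" * 70
        d = gs.jukes_cantor([("a", s1), ("b", s2)])
        assert d.values[0, 1] == pytest.approx(0.3831, abs=2e-4)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            gs.jukes_cantor([("a", "AAAA"), ("b", "CCCC")])

    def test_pairwise_deletion_of_gaps(self):
        # gap and ambiguity columns are excluded per pair: a-b and b-c each
        # compare 5 sites with one mismatch (p = 0.2); a-c matches everywhere
        d = gs.jukes_cantor([("a", "ACGT-A"), ("b", "ACGTNC"), ("c", "ACGTAA")])
        expected = -0.75 * np.log(1 - 4 * 0.2 / 3)
        assert d.values[0, 1] == pytest.approx(expected)
        assert d.values[1, 2] == pytest.approx(expected)
        assert d.values[0, 2] == 0.0

    def test_monotone_in_mismatch_fraction(self):
        dists = []
        for k in (0, 10, 30, 50, 70):
            s2 = "C" * k + "A" * (100 - k)
            d = gs.jukes_cantor([("a", "A" * 100), ("b", s2)])
            dists.append(d.values[0, 1])
        assert all(x < y for x, y in zip(dists, dists[1:]))

    def test_unaligned_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            gs.jukes_cantor([("a", "ACGT"), ("b", "ACG")])


class TestBinning:
    def _toy(self):
        # 4 taxa, 6 pairs; distances chosen so bins are unambiguous
        dist = np.array(
            [
                [0.0, 0.1, 0.1, 0.9],
                [0.1, 0.0, 0.5, 0.9],
                [0.1, 0.5, 0.0, 0.9],
                [0.9, 0.9, 0.9, 0.0],
            ]
        )
        metric = np.array(
            [
                [0.0, 4.0, 2.0, 1.0],
                [4.0, 0.0, 3.0, 1.0],
                [2.0, 3.0, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ]
        )
        return metric, DistanceMatrix(taxa=list("abcd"), values=dist)

    def test_hand_computed_bins(self):
        metric, dist = self._toy()
        binned = gs.bin_metric_by_distance(metric, dist, n_bins=2)
        # bin 1 (d < 0.5): pairs ab, ac -> mean 3.0; bin 2: bc, ad, bd, cd -> 1.5
        assert binned.counts.tolist() == [2, 4]
        assert binned.means[0] == pytest.approx(3.0)
        assert binned.means[1] == pytest.approx(1.5)

    def test_single_bin_is_overall_mean(self):
        metric, dist = self._toy()
        binned = gs.bin_metric_by_distance(metric, dist, n_bins=1)
        assert binned.means[0] == pytest.approx(2.0)

    def test_constant_metric(self):
        _, dist = self._toy()
        const = np.ones((4, 4)) - np.eye(4)
        binned = gs.bin_metric_by_distance(const, dist, n_bins=3)
        present = binned.counts > 0
        assert np.allclose(binned.means[present], 1.0)
        assert np.allclose(binned.sds[present], 0.0)


class TestIndexShuffleNull:
    def test_preserves_value_multiset(self, rng):
        n = 8
        metric = np.abs(rng.normal(size=(n, n)))
        metric = (metric + metric.T) / 2
        np.fill_diagonal(metric, 0)
        dvals = np.abs(rng.normal(size=(n, n)))
        dist = DistanceMatrix(taxa=[str(i) for i in range(n)], values=np.triu(dvals, 1) + np.triu(dvals, 1).T)
        iu = np.triu_indices(n, 1)
        observed = np.sort(metric[iu])
        # any single permutation of the metric leaves the multiset intact
        perm = rng.permutation(n)
        shuffled = metric[perm][:, perm]
        assert np.allclose(np.sort(shuffled[iu]), observed)

    def test_anticorrelated_metric_has_small_p(self, rng):
        n = 12
        dvals = np.abs(rng.normal(size=(n, n))) + 0.01
        dist_m = np.triu(dvals, 1) + np.triu(dvals, 1).T
        dist = DistanceMatrix(taxa=[str(i) for i in range(n)], values=dist_m)
        metric = -dist_m
        binned = gs.index_shuffle_null(metric, dist, n_bins=4, n_shuffles=3000, seed=5)
        assert binned.first_bin_p < 0.02

    def test_p_matches_exhaustive_enumeration(self, rng):
        # N = 6: compare the sampled p value with enumeration over all 720
        # permutations
        n = 6
        metric = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        metric[iu] = rng.normal(size=iu[0].size)
        metric += metric.T
        dvals = np.sort(rng.random(iu[0].size))
        dist_m = np.zeros((n, n))
        dist_m[iu] = dvals
        dist_m += dist_m.T
        dist = DistanceMatrix(taxa=[str(i) for i in range(n)], values=dist_m)

        n_bins = 3
        edges = np.linspace(dvals.min(), dvals.max(), n_bins + 1)
        bin_idx = np.clip(np.digitize(dvals, edges[1:-1]), 0, n_bins - 1)
        observed = metric[iu][bin_idx == 0].mean()
        count = total = 0
        for perm in itertools.permutations(range(n)):
            perm = np.array(perm)
            vals = metric[perm[iu[0]], perm[iu[1]]]
            total += 1
            if vals[bin_idx == 0].mean() > observed:
                count += 1
        exact = count / total

        est = gs.index_shuffle_null(metric, dist, n_bins=n_bins, n_shuffles=4000, seed=9)
        se = np.sqrt(max(exact * (1 - exact), 1e-6) / 4000)
        assert abs(est.first_bin_p - exact) < 4 * se + 1e-9

    def test_degenerate_single_shuffle(self, rng):
        _, dist = TestBinning()._toy()
        metric = np.abs(rng.normal(size=(4, 4)))
        metric = (metric + metric.T) / 2
        np.fill_diagonal(metric, 0)
        est = gs.index_shuffle_null(metric, dist, n_bins=2, n_shuffles=1, seed=0)
        assert est.first_bin_p in (0.0, 1.0)


class TestClusterToK:
    def test_extremes(self, rng):
        n = 10
        metric = np.abs(rng.normal(size=(n, n)))
        metric = (metric + metric.T) / 2
        np.fill_diagonal(metric, 0)
        assert gs.cluster_to_k(metric, n).n_clusters == n
        assert gs.cluster_to_k(metric, 1).n_clusters == 1

    def test_matches_linear_scan(self, rng):
        n, k_target = 10, 4
        for trial in range(10):
            metric = np.abs(rng.normal(size=(n, n)))
            metric = (metric + metric.T) / 2
            np.fill_diagonal(metric, 0)
            part = gs.cluster_to_k(metric, k_target)
            assert part.n_clusters == k_target
            # brute-force: scan all unique thresholds for reachable counts
            iu = np.triu_indices(n, 1)
            reachable = {
                gs.single_linkage_partition(gs.threshold_links(metric, th)).n_clusters
                for th in np.concatenate([[metric.max() + 1], metric[iu]])
            }
            assert k_target in reachable
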