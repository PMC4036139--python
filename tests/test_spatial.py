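"""Spatial maps, fEOD statistics, conditionals, and group tests."""

import numpy as np
import pytest
from scipy import stats

import electrokin as ek
from electrokin.spatial import occupancy_and_value_maps


class TestFEOD:
    def test_constant_train(self):
        t = 0.04 * np.arange(100)
        f = ek.instantaneous_feod(t)
        assert np.isnan(f[0])
        np.testing.assert_allclose(f[1:], 25.0)
        z = ek.zscore_per_night(f, np.zeros(100))
        np.testing.assert_allclose(z[1:], 0.0)

    def test_hand_reciprocals(self):
        f = ek.instantaneous_feod([0.0, 0.05, 0.09])
        np.testing.assert_allclose(f[1:], [20.0, 25.0])

    def test_duplicate_timestamps_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            ek.instantaneous_feod([0.0, 0.1, 0.1])

    def test_per_night_zscore_centers_each_night(self):
        rng = np.random.default_rng(0)
        f = np.concatenate([rng.normal(25, 2, 500), rng.normal(40, 5, 500)])
        nights = np.repeat(["n1", "n2"], 500)
        z = ek.zscore_per_night(f, nights)
        assert np.mean(z[:500]) == pytest.approx(0.0, abs=1e-12)
        assert np.mean(z[500:]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z[:500], ddof=1) == pytest.approx(1.0)


class TestMaps:
    def test_point_mass(self):
        m = occupancy_and_value_maps(np.full(7, 3.2), np.full(7, -1.7),
                                     extent=(10, 10))
        assert m.counts.sum() == 7
        assert (m.counts > 0).sum() == 1

    def test_bin_mean(self):
        m = occupancy_and_value_maps([0.2, 0.3], [0.2, 0.3], values=[1.0, 3.0],
                                     extent=(4, 4))
        assert np.nanmax(m.mean_value) == pytest.approx(2.0)

    def test_count_conservation_and_drop_logging(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-40, 40, 1000)
        y = rng.uniform(-40, 40, 1000)
        m = occupancy_and_value_maps(x, y, extent=(64, 48))
        inside = (np.abs(x) <= 32) & (np.abs(y) <= 24)
        assert m.counts.sum() == inside.sum()
        assert m.n_dropped == (~inside).sum()

    def test_constant_value_map_constant(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(-5, 5, (2, 500))
        m = occupancy_and_value_maps(x, y, values=np.full(500, 4.2), extent=(12, 12))
        vals = m.mean_value[~np.isnan(m.mean_value)]
        np.testing.assert_allclose(vals, 4.2)

    def test_nonpositive_bin_raises(self):
        with pytest.raises(ValueError):
            occupancy_and_value_maps([0.0], [0.0], extent=(4, 4), bin_cm=0.0)


class TestDistanceProfile:
    def test_all_flagged_profile_is_one(self):
        d = np.linspace(0.1, 9.9, 200)
        p = ek.distance_profile(np.ones(200, bool), d)
        good = p.denominator > 0
        np.testing.assert_allclose(p.fraction[good], 1.0)

    def test_none_flagged_profile_is_zero(self):
        d = np.linspace(0.1, 9.9, 200)
        p = ek.distance_profile(np.zeros(200, bool), d)
        np.testing.assert_allclose(p.fraction[p.denominator > 0], 0.0)

    def test_hand_counts(self):
        d = np.array([0.5, 0.6, 0.7, 1.5, 1.6, 2.5, 2.6, 2.7, 2.8, 3.5])
        flags = np.array([1, 0, 1, 1, 0, 0, 0, 1, 1, 0], bool)
        p = ek.distance_profile(flags, d, bin_cm=1.0)
        np.testing.assert_allclose(p.fraction[:4], [2 / 3, 1 / 2, 2 / 4, 0.0])
        np.testing.assert_allclose(p.denominator[:4], [3, 2, 4, 1])
        np.testing.assert_allclose(p.fraction_of_total[:4],
                                   np.array([2, 1, 2, 0]) / 10)

    def test_exhaustive_flags_sum_to_one(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 20, 2000)
        labels = rng.integers(0, 3, 2000)
        total = None
        for g in range(3):
            p = ek.distance_profile(labels == g, d)
            total = p.fraction if total is None else total + p.fraction
        good = ~np.isnan(total)
        np.testing.assert_allclose(total[good], 1.0)


class TestApproachFilter:
    def occ(self, start, end):
        return {"start": start, "end": end}

    def test_closing_occurrence_kept(self):
        d = np.linspace(12.0, 3.5, 10)
        assert ek.approach_filter([self.occ(0, 10)], d, d_max=4.0) == [self.occ(0, 10)]

    def test_far_occurrence_rejected(self):
        d = np.linspace(12.0, 6.0, 10)
        assert ek.approach_filter([self.occ(0, 10)], d, d_max=4.0) == []

    def test_matches_direct_two_condition_scan(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 15, 400)
        occs = []
        for _ in range(20):
            s = rng.integers(0, 380)
            occs.append(self.occ(int(s), int(s + rng.integers(5, 20))))
        got = ek.approach_filter(occs, d, d_max=4.0)
        expected = [o for o in occs if d[o["end"] - 1] < 4.0 and d[o["end"] - 1] < d[o["start"]]]
        assert got == expected

    def test_approach_departure_disjoint(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 15, 400)
        occs = [self.occ(int(s), int(s + 10)) for s in rng.integers(0, 380, 30)]
        app = ek.approach_filter(occs, d, d_max=4.0)
        dep = ek.approach_filter(occs, d, d_max=4.0, invert=True)
        ids = lambda lst: {(o["start"], o["end"]) for o in lst}
        assert ids(app) & ids(dep) == set()


class TestDistanceReferencedAverage:
    def test_constant_signal_flat(self):
        d = np.linspace(0.1, 9.9, 300)
        v = np.full(300, 5.0)
        tr = ek.distance_referenced_average(v, [{"start": 0, "end": 300}], d)
        np.testing.assert_allclose(tr.mean[tr.n > 0], 5.0)

    def test_single_frame_bin_sd_masked(self):
        d = np.array([0.5, 5.5])
        v = np.array([1.0, 2.0])
        tr = ek.distance_referenced_average(v, [{"start": 0, "end": 2}], d)
        assert np.isnan(tr.sd[0]) and np.isnan(tr.sd[5])

    def test_no_occurrences_raises(self):
        with pytest.raises(ValueError):
            ek.distance_referenced_average(np.zeros(5), [], np.zeros(5))


class TestPostChainTransitions:
    def test_uniform_labels_trivial(self):
        labels = np.ones(500, dtype=int)
        df = ek.post_chain_transitions(labels, [100, 300], n_perm=99, seed=0)
        assert df.loc[0, "excess"] == pytest.approx(0.0)
        assert df.loc[0, "p"] > 0.9

    def test_constructed_enrichment_detected(self):
        # PM 9 occurs only right after the chain ends, never elsewhere
        rng = np.random.default_rng(6)
        labels = rng.integers(1, 4, 600)
        ends = [100, 250, 400]
        for e in ends:
            labels[e:e + 10] = 9
        df = ek.post_chain_transitions(labels, ends, horizon=10, n_perm=199, seed=0)
        row = df[df["pm"] == 9].iloc[0]
        assert row["excess"] > 0.5
        assert row["p"] <= 2 / (199 + 1)

    def test_null_mean_matches_global_frequency(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(1, 5, 2000)
        df = ek.post_chain_transitions(labels, [500, 1000, 1500], horizon=10,
                                       n_perm=299, seed=1)
        for _, row in df.iterrows():
            global_f = (labels == row["pm"]).mean()
            assert row["null_mean"] == pytest.approx(global_f, abs=0.02)

    def test_permutation_p_uniform_under_exchangeable_null(self):
        # windows placed in an i.i.d. label stream: p-values ~ uniform
        rng = np.random.default_rng(8)
        pvals = []
        for rep in range(60):
            labels = rng.integers(1, 4, 400)
            ends = rng.integers(0, 390, 5)
            df = ek.post_chain_transitions(labels, ends, horizon=10,
                                           n_perm=199, seed=rep)
            pvals.append(df["p"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestGroupCompare:
    def test_identical_groups_high_p(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=40)
        rep = ek.group_compare(np.concatenate([v, v]), np.repeat(["a", "b"], 40))
        assert rep["p"] > 0.9

    def test_exact_rank_sum_p(self):
        # complete separation at n=3 vs 3: two-sided exact p = 2/20 = 0.1
        rep = ek.group_compare([1, 2, 3, 101, 102, 103],
                               ["a", "a", "a", "b", "b", "b"])
        assert rep["test"] == "mann-whitney-u"
        assert rep["p"] == pytest.approx(0.1)

    def test_three_groups_flags_only_shifted(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        c = rng.normal(5, 1, 30)
        rep = ek.group_compare(np.concatenate([a, b, c]),
                               np.repeat(["a", "b", "c"], 30))
        assert rep["test"] == "kruskal-wallis"
        assert rep["p"] < 0.05
        for row in rep["posthoc"]:
            involved = {row["group_a"], row["group_b"]}
            if "c" in involved:
                assert row["p_holm"] < 0.05
            else:
                assert row["p_holm"] > 0.05

    def test_small_group_excluded(self):
        rep = ek.group_compare([1.0, 2.0, 3.0, 4.0, 9.0],
                               ["a", "a", "b", "b", "c"])
        assert rep["excluded"] == ["c"]
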