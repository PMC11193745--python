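"""Sample pools: merging/dedup, stratified draws, truth labeling."""

import numpy as np
import pandas as pd
import pytest

import croplandsyn as cs


def random_pool(n, source, seed, extent=10_000.0):
    rng = np.random.default_rng(seed)
    return cs.SamplePool.from_arrays(rng.uniform(0, extent, n),
                                     rng.uniform(0, extent, n),
                                     rng.integers(0, 2, n), source)


class TestMergePools:
    def test_collision_free_merge_is_concatenation(self):
        pools = [random_pool(n, f"s{i}", seed=i)
                 for i, n in enumerate([200, 150, 100])]
        merged = cs.merge_pools(pools, dedup_tolerance=1e-6)
        assert len(merged) == 450
        assert merged.sources.to_dict() == {"s0": 200, "s1": 150, "s2": 100}

    def test_identical_point_in_two_pools_survives_once(self):
        a = cs.SamplePool.from_arrays([10.0], [10.0], [1], "first")
        b = cs.SamplePool.from_arrays([10.0], [10.0], [1], "second")
        merged = cs.merge_pools([a, b], dedup_tolerance=1.0)
        assert len(merged) == 1
        assert merged.df.loc[0, "source"] == "first"  # pool-order priority

    def test_matches_brute_force_dedup(self):
        rng = np.random.default_rng(3)
        base = random_pool(150, "base", seed=7, extent=500.0)
        # plant near-duplicates of random base points
        idx = rng.choice(150, 40)
        dup = cs.SamplePool.from_arrays(
            base.df["x"].to_numpy()[idx] + rng.uniform(-5, 5, 40),
            base.df["y"].to_numpy()[idx] + rng.uniform(-5, 5, 40),
            np.ones(40, dtype=int), "dup")
        tol = 8.0
        merged = cs.merge_pools([base, dup], tol)
        # O(n^2) greedy oracle in the same priority order
        xy = pd.concat([base.df, dup.df])[["x", "y"]].to_numpy()
        kept = []
        for i in range(len(xy)):
            if all(np.hypot(*(xy[i] - xy[j])) > tol for j in kept):
                kept.append(i)
        assert len(merged) == len(kept)

    def test_mixed_crs_rejected(self):
        a = cs.SamplePool.from_arrays([0.0], [0.0], [1], "a", crs_tag="x")
        b = cs.SamplePool.from_arrays([9.0], [9.0], [1], "b", crs_tag="y")
        with pytest.raises(ValueError, match="CRS"):
            cs.merge_pools([a, b], 1.0)

    def test_order_insensitive_size_without_duplicates(self):
        pools = [random_pool(n, f"s{i}", seed=50 + i) for i, n in enumerate([80, 120])]
        assert len(cs.merge_pools(pools, 1e-9)) == \
            len(cs.merge_pools(pools[::-1], 1e-9))


class TestStratifiedSample:
    def vote_of(self, scene):
        return cs.vote_map(scene.products)

    def test_quota_arithmetic_largest_remainder(self, small_scene):
        from croplandsyn.sampling import _quotas
        q = _quotas(np.array([900, 100]), 100, "proportional", 0)
        assert list(q) == [90, 10]
        # remainders decide the extra point
        q = _quotas(np.array([905, 95]), 10, "proportional", 0)
        assert q.sum() == 10

    def test_quotas_sum_and_strata_match(self, small_scene):
        vote = self.vote_of(small_scene)
        pool = cs.stratified_sample(vote, 600, seed=1)
        assert len(pool) == 600
        # every drawn point's vote value equals its assigned stratum
        row, col = vote.spec.rowcol(pool.df["x"].to_numpy(),
                                    pool.df["y"].to_numpy())
        np.testing.assert_array_equal(vote.votes[row, col],
                                      pool.df["stratum"].to_numpy())
        assert (vote.votes[row, col] >= 1).all()  # maximum cropland extent

    def test_seed_determinism(self, small_scene):
        vote = self.vote_of(small_scene)
        a = cs.stratified_sample(vote, 300, seed=9)
        b = cs.stratified_sample(vote, 300, seed=9)
        c = cs.stratified_sample(vote, 300, seed=10)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert not a.df[["x", "y"]].equals(c.df[["x", "y"]])

    def test_single_stratum_is_simple_random_sample(self, grid_factory):
        g = grid_factory(np.ones((20, 20)))
        pool = cs.stratified_sample(g, 50, seed=0)
        assert len(pool) == 50
        assert not pool.df[["x", "y"]].duplicated().any()  # without replacement

    def test_proportional_share_tracks_area_share(self, small_scene):
        # chi-square goodness of fit over repeated draws, alpha = 0.01
        from scipy.stats import chisquare
        vote = self.vote_of(small_scene)
        flat = vote.votes[vote.votes >= 1]
        vals, sizes = np.unique(flat, return_counts=True)
        observed = np.zeros(len(vals))
        n_total, reps = 400, 30
        for r in range(reps):
            pool = cs.stratified_sample(vote, n_total, seed=100 + r)
            counts = pool.df["stratum"].value_counts()
            observed += np.array([counts.get(v, 0) for v in vals])
        expected = reps * n_total * sizes / sizes.sum()
        _, p = chisquare(observed, expected)
        assert p > 0.01

    def test_infeasible_minimum_rejected(self, small_scene):
        vote = self.vote_of(small_scene)
        with pytest.raises(ValueError):
            cs.stratified_sample(vote, 5, min_per_stratum=10)


class TestLabelFromTruth:
    def test_label_lookup_and_idempotence(self, small_scene):
        vote = cs.vote_map(small_scene.products)
        pool = cs.stratified_sample(vote, 200, restrict_to_extent=False, seed=2)
        labeled = cs.label_from_truth(pool, small_scene.truth)
        twice = cs.label_from_truth(labeled, small_scene.truth)
        pd.testing.assert_frame_equal(labeled.df, twice.df)
        # brute-force lookup oracle
        t = small_scene.truth
        for _, p in labeled.df.head(50).iterrows():
            col = int((p.x - t.spec.origin_x) // t.spec.pixel_size)
            row = int((t.spec.origin_y - p.y) // t.spec.pixel_size)
            assert p.label == t.labels[row, col]

    def test_out_of_extent_rejected(self, small_scene):
        pool = cs.SamplePool.from_arrays([1e9], [1e9], None, "stray")
        with pytest.raises(ValueError, match="outside"):
            cs.label_from_truth(pool, small_scene.truth)


class TestPoolSummary:
    def test_grand_total_and_label_split(self, small_scene, labeled_pool):
        tab = cs.pool_summary(labeled_pool)
        assert tab.loc["total", "total"] == len(labeled_pool)
        assert tab.loc["total", "cropland"] + tab.loc["total", "non_cropland"] \
            == len(labeled_pool)

    def test_zonal_counts_sum_to_pool_size(self, small_scene, labeled_pool):
        tab = cs.pool_summary(labeled_pool, small_scene.zones,
                              zone_spec=small_scene.truth.spec)
        per_zone = tab.drop(index="total")
        assert per_zone["total"].sum() == len(labeled_pool)

    def test_empty_pool(self):
        tab = cs.pool_summary(cs.SamplePool())
        assert tab.loc["total", "total"] == 0


class TestCsvIO:
    def test_round_trip_and_foreign_label_coding(self, tmp_path, labeled_pool):
        path = tmp_path / "pool.csv"
        cs.write_pool_csv(labeled_pool, path)
        back = cs.read_pool_csv(path)
        assert len(back) == len(labeled_pool)
        np.testing.assert_allclose(back.df["x"], labeled_pool.df["x"])
        # archives coding cropland as 10 are remapped on ingest
        df = labeled_pool.df.copy()
        df["label"] = df["label"].astype(int) * 10
        df.to_csv(tmp_path / "coded.csv", index=False)
        remapped = cs.read_pool_csv(tmp_path / "coded.csv", {0: 0, 10: 1})
        np.testing.assert_array_equal(remapped.df["label"].astype(int),
                                      labeled_pool.df["label"].astype(int))
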