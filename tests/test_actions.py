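"""Tracklets, features, DTW, embedding, clustering, action labels."""

import math

import numpy as np
import pytest

from ivmotion.actions import (
    ClusterProfile, FeatureScaler, FeatureSeries, annotate_actions,
    build_feature_series, cluster_tracks, condition_percentages,
    cross_distance_matrix, dtw_distance, embed_2d, make_tracklets,
    profile_clusters, tracklet_features, ActionAssignment, FEATURE_NAMES,
)
from ivmotion.tracks import Track
from .conftest import random_track


def make_track(points, dt=60.0, track_id="t", condition=""):
    pos = np.asarray(points, dtype=float)
    return Track(track_id, pos, np.arange(len(pos)) * dt, condition)


def straight_track(n, step=5.0, track_id="t", condition=""):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * step
    return make_track(pos, track_id=track_id, condition=condition)


def dtw_brute_force(a, b):
    """Exhaustive enumeration of all monotone warping paths (tiny series)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    best = [math.inf]

    def cost(i, j):
        return float(np.linalg.norm(a[i] - b[j]))

    def rec(i, j, acc):
        acc += cost(i, j)
        if acc >= best[0]:
            return
        if i == na - 1 and j == nb - 1:
            best[0] = acc
            return
        if i + 1 < na:
            rec(i + 1, j, acc)
        if j + 1 < nb:
            rec(i, j + 1, acc)
        if i + 1 < na and j + 1 < nb:
            rec(i + 1, j + 1, acc)

    rec(0, 0, 0.0)
    return best[0]


class TestMakeTracklets:
    @pytest.mark.parametrize("n,expected", [(8, 1), (12, 5), (20, 13)])
    def test_count_is_n_minus_window_plus_one(self, n, expected):
        tls = make_tracklets(straight_track(n), window=8)
        assert len(tls) == expected
        assert [t.start_index for t in tls] == list(range(expected))

    def test_short_track_yields_empty_list(self):
        assert make_tracklets(straight_track(7), window=8) == []

    def test_stride(self):
        tls = make_tracklets(straight_track(12), window=8, stride=2)
        assert [t.start_index for t in tls] == [0, 2, 4]
        with pytest.raises(ValueError):
            make_tracklets(straight_track(12), window=8, stride=0)


class TestTrackletFeatures:
    def test_constant_velocity(self):
        (tl,) = make_tracklets(straight_track(8, step=5.0), window=8)
        f = tracklet_features(tl, arrest_threshold=2.0)
        assert f.mean_speed == pytest.approx(5.0)
        assert f.directionality == pytest.approx(1.0)
        assert f.arrest_coefficient == 0.0
        assert f.displacement == pytest.approx(35.0)

    def test_stationary(self):
        (tl,) = make_tracklets(make_track(np.zeros((8, 3))), window=8)
        f = tracklet_features(tl)
        assert (f.mean_speed, f.displacement, f.directionality,
                f.arrest_coefficient) == (0.0, 0.0, 0.0, 1.0)

    def test_zigzag_matches_brute_force(self):
        rng = np.random.default_rng(3)
        t = random_track(rng, n_points=8, scale=4.0)
        (tl,) = make_tracklets(t, window=8)
        f = tracklet_features(tl, arrest_threshold=2.0)
        pts = [tuple(p) for p in t.positions]
        dists = [math.dist(pts[i], pts[i + 1]) for i in range(7)]
        speeds = [d / 1.0 for d in dists]
        assert f.mean_speed == pytest.approx(sum(speeds) / 7)
        assert f.displacement == pytest.approx(math.dist(pts[0], pts[-1]))
        assert f.directionality == pytest.approx(
            math.dist(pts[0], pts[-1]) / sum(dists))
        assert f.arrest_coefficient == pytest.approx(
            sum(s < 2.0 for s in speeds) / 7)


class TestBuildFeatureSeries:
    def test_single_track_single_window(self):
        series = build_feature_series([straight_track(8)])
        assert len(series) == 1 and len(series[0]) == 1

    def test_standardization_zero_mean_unit_sd(self):
        # mixed step scales so every feature (incl. arrest) varies
        tracks = [random_track(np.random.default_rng(s), n_points=14,
                               scale=(0.8 if s % 2 else 10.0),
                               track_id=f"t{s}") for s in range(6)]
        series = build_feature_series(tracks)
        stacked = np.vstack([s.standardized for s in series])
        assert np.allclose(stacked.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(stacked.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_identical_tracks_identical_series(self):
        tracks = [straight_track(10, track_id="a"),
                  straight_track(10, track_id="b")]
        sa, sb = build_feature_series(tracks)
        assert np.array_equal(sa.raw, sb.raw)

    def test_all_short_raises(self):
        with pytest.raises(ValueError, match="points"):
            build_feature_series([straight_track(5)])

    def test_frozen_scaler_keeps_feature_space(self):
        tracks = [random_track(np.random.default_rng(s), n_points=12,
                               track_id=f"t{s}", condition="u" if s < 4 else "x")
                  for s in range(8)]
        series = build_feature_series(tracks)
        scaler = series[0].scaler
        subset = [t for t in tracks if t.condition == "u"]
        sub_series = build_feature_series(subset, scaler=scaler)
        for full, sub in zip(series[:4], sub_series):
            assert np.allclose(full.standardized, sub.standardized)
        D_full = cross_distance_matrix(series[:4])
        D_sub = cross_distance_matrix(sub_series)
        assert np.allclose(D_full, D_sub)


class TestDtwDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(size=(rng.integers(1, 9), 4))
            b = rng.normal(size=(rng.integers(1, 9), 4))
            assert dtw_distance(a, a) == pytest.approx(0.0, abs=1e-12)
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_matches_exhaustive_enumeration_example(self):
        a = np.array([[0.0], [1.0], [2.0]])
        b = np.array([[0.0], [2.0]])
        assert dtw_distance(a, b) == pytest.approx(dtw_brute_force(a, b))
        assert dtw_distance(a, b) == pytest.approx(1.0)  # 0-0,1-0|1-2,2-2 path

    def test_matches_enumeration_on_random_short_series(self):
        rng = np.random.default_rng(1)
        series = [rng.normal(size=(rng.integers(1, 6), 4)) for _ in range(12)]
        for i in range(len(series)):
            for j in range(i + 1, len(series)):
                assert dtw_distance(series[i], series[j]) == pytest.approx(
                    dtw_brute_force(series[i], series[j]))

    def test_dimension_mismatch_and_empty(self):
        with pytest.raises(ValueError, match="dimension"):
            dtw_distance(np.zeros((3, 4)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            dtw_distance(np.zeros((0, 4)), np.zeros((3, 4)))

    def test_normalized_variant(self):
        a, b = np.zeros((3, 2)), np.ones((2, 2))
        raw = dtw_distance(a, b)
        assert dtw_distance(a, b, normalize=True) == pytest.approx(raw / 5)


class TestCrossDistanceMatrix:
    @staticmethod
    def _series(arrs):
        scaler = FeatureScaler(np.zeros(4), np.ones(4))
        return [FeatureSeries(f"t{i}", np.asarray(a, float), scaler)
                for i, a in enumerate(arrs)]

    def test_identical_series_all_zero(self):
        s = self._series([np.ones((3, 4))] * 3)
        assert np.array_equal(cross_distance_matrix(s), np.zeros((3, 3)))

    def test_symmetry_and_pairwise_consistency(self):
        rng = np.random.default_rng(2)
        s = self._series([rng.normal(size=(rng.integers(2, 7), 4))
                          for _ in range(10)])
        D = cross_distance_matrix(s)
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)
        for i in range(10):
            for j in range(10):
                assert D[i, j] == pytest.approx(
                    dtw_distance(s[i].raw, s[j].raw), abs=1e-12)


class TestEmbedding:
    @staticmethod
    def _block_matrix(rng, n_per=12, sep=50.0):
        n = 2 * n_per
        D = rng.uniform(0.5, 1.5, size=(n, n))
        D = (D + D.T) / 2
        D[:n_per, n_per:] += sep
        D[n_per:, :n_per] += sep
        np.fill_diagonal(D, 0.0)
        return D

    def test_shape_and_determinism(self):
        D = self._block_matrix(np.random.default_rng(0))
        e1 = embed_2d(D, seed=5, n_neighbors=6)
        e2 = embed_2d(D, seed=5, n_neighbors=6)
        assert e1.shape == (24, 2)
        assert np.array_equal(e1, e2)

    def test_preserves_block_structure(self):
        D = self._block_matrix(np.random.default_rng(1))
        emb = embed_2d(D, seed=0, n_neighbors=6)
        same_block = 0
        for i in range(24):
            d = np.linalg.norm(emb - emb[i], axis=1)
            d[i] = np.inf
            nn = int(d.argmin())
            same_block += (nn < 12) == (i < 12)
        assert same_block >= 0.9 * 24

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_2d(np.zeros((5, 5)), seed=0, n_neighbors=15)


class TestClustering:
    def test_k_one_trivial(self):
        emb = np.random.default_rng(0).normal(size=(10, 2))
        assert set(cluster_tracks(emb, k=1, seed=0)) == {0}

    def test_separable_blobs(self):
        rng = np.random.default_rng(1)
        emb = np.vstack([rng.normal(0, 0.1, (15, 2)),
                         rng.normal(10, 0.1, (15, 2))])
        ids = cluster_tracks(emb, k=2, seed=0)
        assert len(set(ids[:15])) == 1 and len(set(ids[15:])) == 1
        assert ids[0] != ids[15]

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            cluster_tracks(np.zeros((3, 2)), k=5, seed=0)


class TestProfilesAndLabels:
    @staticmethod
    def _series_from_raw(raws):
        scaler = FeatureScaler(np.zeros(4), np.ones(4))
        return [FeatureSeries(f"t{i}", np.asarray(r, float), scaler)
                for i, r in enumerate(raws)]

    def test_single_cluster_profile_equals_cohort_mean(self):
        raws = [np.arange(8, dtype=float).reshape(2, 4),
                np.arange(4, dtype=float).reshape(1, 4) + 10]
        series = self._series_from_raw(raws)
        (p,) = profile_clusters(np.zeros(2, dtype=int), series)
        stacked = np.vstack(raws)
        for i, name in enumerate(FEATURE_NAMES):
            assert p.mean_features[name] == pytest.approx(stacked[:, i].mean())
        assert p.member_count == 3

    def test_two_cluster_hand_computation(self):
        raws = [[[2, 0, 0, 0]], [[4, 0, 0, 0]],          # cluster 0: speeds 2,4
                [[10, 0, 0, 0]], [[20, 0, 0, 0]], [[30, 0, 0, 0]]]
        series = self._series_from_raw(raws)
        p0, p1 = profile_clusters(np.array([0, 0, 1, 1, 1]), series)
        assert p0.mean_features["mean_speed"] == pytest.approx(3.0)
        assert p1.mean_features["mean_speed"] == pytest.approx(20.0)
        assert p0.member_count + p1.member_count == 5

    @staticmethod
    def _profile(cid, speed, disp, direc, arrest):
        return ClusterProfile(cid, {
            "mean_speed": speed, "displacement": disp,
            "directionality": direc, "arrest_coefficient": arrest}, 10)

    def test_exaggerated_profiles_recover_canonical_labels(self):
        profiles = [
            self._profile(0, 15.0, 200.0, 0.9, 0.05),   # flowing
            self._profile(1, 3.0, 20.0, 0.3, 0.60),     # focused patrolling
            self._profile(2, 6.0, 60.0, 0.5, 0.25),     # patrolling
            self._profile(3, 0.5, 2.0, 0.1, 0.95),      # arrested
            self._profile(4, 10.0, 120.0, 0.85, 0.10),  # directed
        ]
        labels = annotate_actions(profiles)
        assert labels == {0: "flowing", 4: "directed", 2: "patrolling",
                          1: "focused_patrolling", 3: "arrested"}

    def test_identical_profiles_tie_break_by_cluster_id(self):
        profiles = [self._profile(i, 5.0, 50.0, 0.5, 0.3) for i in range(5)]
        labels = annotate_actions(profiles)
        assert labels == {0: "arrested", 1: "flowing", 2: "directed",
                          3: "patrolling", 4: "focused_patrolling"}
        assert labels == annotate_actions(profiles)  # deterministic

    def test_requires_five_profiles(self):
        with pytest.raises(ValueError):
            annotate_actions([self._profile(0, 1, 1, 1, 1)] * 4)


class TestConditionPercentages:
    @staticmethod
    def _assign(cluster, condition):
        return ActionAssignment("t", cluster, np.zeros(2), "flowing", condition)

    def test_single_condition_single_cluster(self):
        pct = condition_percentages([self._assign(0, "untreated")] * 3)
        assert pct.loc[:, "untreated"].tolist() == [100.0]

    def test_hand_built_crosstab(self):
        assigns = ([self._assign(0, "untreated")] * 3 +
                   [self._assign(1, "untreated")] +
                   [self._assign(0, "treated")] +
                   [self._assign(1, "treated")] * 3)
        pct = condition_percentages(assigns)
        assert pct["untreated"].tolist() == pytest.approx([75.0, 25.0])
        assert pct["treated"].tolist() == pytest.approx([25.0, 75.0])
        assert pct.sum(axis=0).tolist() == pytest.approx([100.0, 100.0])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            condition_percentages([])
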