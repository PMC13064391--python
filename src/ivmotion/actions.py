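"""Behavioral action recognition from track dynamics.

The pipeline mirrors how intravital T-cell recordings are classified into
motility behaviors: each track is cut into overlapping 8-point tracklets;
every tracklet is summarized by four features (mean speed, net displacement,
directionality, arrest coefficient); the resulting multivariate feature
series are compared with dynamic time warping (DTW), which tolerates tracks
of different lengths; the DTW cross-distance matrix is embedded in 2-D with
UMAP; k-means (k = 5) partitions the embedding; and a deterministic rule on
the cluster feature profiles names each cluster as one of five actions:
flowing, directed, patrolling, focused patrolling, arrested.

Features are standardized cohort-wide (z-scores) before DTW so that the four
features contribute comparably; cluster profiles are reported on the raw
(unstandardized) scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Track, DEFAULT_ARREST_THRESHOLD

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 8
DEFAULT_STRIDE = 1
DEFAULT_K = 5
FEATURE_NAMES = ("mean_speed", "displacement", "directionality", "arrest_coefficient")
ACTION_LABELS = ("flowing", "directed", "patrolling", "focused_patrolling", "arrested")


@dataclass
class Tracklet:
    """A fixed-length contiguous sub-window of a parent track."""

    parent_id: str
    start_index: int
    positions: np.ndarray  # (window, 3) µm
    dt: float  # s/frame


@dataclass
class TrackletFeatures:
    """Four-feature summary of one tracklet.

    mean_speed µm/min; displacement (net, start to end of the window) µm;
    directionality = net displacement / within-window path length, in [0, 1];
    arrest_coefficient = fraction of within-window steps below the arrest
    threshold, in [0, 1].
    """

    mean_speed: float
    displacement: float
    directionality: float
    arrest_coefficient: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_speed, self.displacement,
                         self.directionality, self.arrest_coefficient])


@dataclass
class FeatureScaler:
    """Cohort-wide per-feature standardization constants."""

    mean: np.ndarray  # (4,)
    sd: np.ndarray    # (4,) zeros replaced by 1 for constant features

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.mean) / self.sd


@dataclass
class FeatureSeries:
    """Ordered tracklet-feature sequence of one track.

    ``raw`` is (m, 4) with one row per window position; ``standardized`` is
    the z-scored copy using the cohort-wide :class:`FeatureScaler` stored in
    ``scaler``.
    """

    track_id: str
    raw: np.ndarray
    scaler: FeatureScaler
    condition: str = ""

    @property
    def standardized(self) -> np.ndarray:
        return self.scaler.transform(self.raw)

    def __len__(self) -> int:
        return len(self.raw)


@dataclass
class ClusterProfile:
    """Per-cluster mean of each raw feature over member tracklets."""

    cluster_id: int
    mean_features: dict[str, float]
    member_count: int


@dataclass
class ActionAssignment:
    """Final per-track classification."""

    track_id: str
    cluster_id: int
    embedding: np.ndarray  # (2,)
    label: str
    condition: str = ""


def make_tracklets(track: Track, window: int = DEFAULT_WINDOW,
                   stride: int = DEFAULT_STRIDE) -> list[Tracklet]:
    """Slide a ``window``-point window across the track.

    Windows start at indices 0, stride, 2·stride, … while they fit. A track
    shorter than ``window`` yields an empty list (logged as flagged): such
    tracks pass the duration filter but cannot be featurized.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n = track.n_points
    if n < window:
        logger.info("track %s: %d points < window %d, no tracklets",
                    track.track_id, n, window)
        return []
    return [
        Tracklet(track.track_id, s, track.positions[s:s + window], track.dt)
        for s in range(0, n - window + 1, stride)
    ]


def tracklet_features(tracklet: Tracklet,
                      arrest_threshold: float = DEFAULT_ARREST_THRESHOLD,
                      ) -> TrackletFeatures:
    """Compute the four-feature summary of one tracklet."""
    steps = np.diff(tracklet.positions, axis=0)
    dists = np.linalg.norm(steps, axis=1)
    speeds = dists / tracklet.dt * 60.0
    path = float(dists.sum())
    disp = float(np.linalg.norm(tracklet.positions[-1] - tracklet.positions[0]))
    return TrackletFeatures(
        mean_speed=float(speeds.mean()),
        displacement=disp,
        directionality=disp / path if path > 0 else 0.0,
        arrest_coefficient=float(np.mean(speeds < arrest_threshold)),
    )


def build_feature_series(
    tracks: list[Track],
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    arrest_threshold: float = DEFAULT_ARREST_THRESHOLD,
    scaler: FeatureScaler | None = None,
) -> list[FeatureSeries]:
    """One feature series per track long enough to hold a tracklet.

    Standardization constants (per-feature mean and population SD over all
    tracklets of the cohort) are computed once and shared by every returned
    series. Pass a frozen ``scaler`` to reuse constants from a previous
    cohort, e.g. when re-scoring a subset without shifting the feature
    space.
    """
    per_track: list[tuple[Track, np.ndarray]] = []
    for t in tracks:
        tl = make_tracklets(t, window, stride)
        if not tl:
            continue
        feats = np.array([tracklet_features(w, arrest_threshold).as_array()
                          for w in tl])
        per_track.append((t, feats))
    if not per_track:
        raise ValueError(
            f"no track has >= {window} points; cannot build feature series"
        )
    if scaler is None:
        all_feats = np.vstack([f for _, f in per_track])
        sd = all_feats.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        scaler = FeatureScaler(mean=all_feats.mean(axis=0), sd=sd)
    return [FeatureSeries(t.track_id, feats, scaler, t.condition)
            for t, feats in per_track]


def _dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-programming DTW cumulative cost (Euclidean local cost)."""
    na, nb = len(a), len(b)
    # local cost matrix, then classic O(na*nb) recursion
    diff = a[:, None, :] - b[None, :, :]
    cost = np.sqrt((diff * diff).sum(axis=2))
    acc = np.full((na + 1, nb + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, na + 1):
        row = acc[i]
        prev = acc[i - 1]
        ci = cost[i - 1]
        for j in range(1, nb + 1):
            row[j] = ci[j - 1] + min(prev[j], prev[j - 1], row[j - 1])
    return float(acc[na, nb])


def dtw_distance(a: FeatureSeries | np.ndarray, b: FeatureSeries | np.ndarray,
                 normalize: bool = False) -> float:
    """DTW dissimilarity between two (standardized) feature series.

    Classic monotone, continuity-constrained warping with Euclidean local
    cost between feature vectors; returns the minimal cumulative cost. With
    ``normalize=True`` the cost is divided by ``len(a) + len(b)``.

    The result is non-negative, zero on identical series and symmetric, but
    is not a metric (no triangle inequality).
    """
    xa = a.standardized if isinstance(a, FeatureSeries) else np.asarray(a, float)
    xb = b.standardized if isinstance(b, FeatureSeries) else np.asarray(b, float)
    if xa.ndim == 1:
        xa = xa[:, None]
    if xb.ndim == 1:
        xb = xb[:, None]
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("series must be non-empty")
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {xa.shape[1]} vs {xb.shape[1]}"
        )
    d = _dtw_cost(xa, xb)
    return d / (len(xa) + len(xb)) if normalize else d


def cross_distance_matrix(series: list[FeatureSeries],
                          normalize: bool = False) -> np.ndarray:
    """Symmetric DTW distance matrix over all unordered series pairs."""
    n = len(series)
    if n < 2:
        raise ValueError("need >= 2 series")
    std = [s.standardized for s in series]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(std[i], std[j], normalize=normalize)
            if not np.isfinite(d):
                raise RuntimeError(
                    f"non-finite DTW distance between series "
                    f"{series[i].track_id!r} and {series[j].track_id!r}"
                )
            D[i, j] = D[j, i] = d
    return D


def embed_2d(D: np.ndarray, seed: int, n_neighbors: int = 15,
             min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP embedding of a precomputed distance matrix."""
    import warnings
    n = len(D)
    if n < n_neighbors + 1:
        raise ValueError(
            f"{n} samples is too few for n_neighbors={n_neighbors}; "
            f"reduce n_neighbors to at most {n - 1}"
        )
    import umap
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, metric="precomputed",
            n_neighbors=n_neighbors, min_dist=min_dist,
            random_state=seed,
        )
        emb = reducer.fit_transform(D)
    return np.asarray(emb, dtype=float)


def cluster_tracks(embedding: np.ndarray, k: int = DEFAULT_K,
                   seed: int = 0, n_init: int = 10) -> np.ndarray:
    """k-means partition of the 2-D embedding (k-means++ init, restarts)."""
    from sklearn.cluster import KMeans
    n = len(embedding)
    if n < k:
        raise ValueError(f"{n} samples < k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    ids = km.fit_predict(embedding)
    sizes = np.bincount(ids, minlength=k)
    if np.any(sizes == 0):
        logger.warning("empty k-means cluster(s): %s", np.where(sizes == 0)[0])
    return ids


def profile_clusters(cluster_ids: np.ndarray,
                     series: list[FeatureSeries]) -> list[ClusterProfile]:
    """Per-cluster mean of each raw feature over member tracklets."""
    if len(cluster_ids) != len(series):
        raise ValueError("one cluster id per series required")
    profiles = []
    for c in sorted(set(int(c) for c in cluster_ids)):
        members = [s.raw for s, ci in zip(series, cluster_ids) if ci == c]
        if members:
            stacked = np.vstack(members)
            means = dict(zip(FEATURE_NAMES, stacked.mean(axis=0)))
            count = len(stacked)
        else:
            means = dict.fromkeys(FEATURE_NAMES, float("nan"))
            count = 0
            logger.warning("cluster %d is empty; profile means undefined", c)
        profiles.append(ClusterProfile(c, means, count))
    return profiles


def annotate_actions(profiles: list[ClusterProfile]) -> dict[int, str]:
    """Name the five clusters by their feature profiles.

    Deterministic rule on min-max–normalized profile means: the cluster with
    the highest arrest coefficient is *arrested*; among the rest the lowest
    arrest (ties broken by highest mean speed) is *flowing*; the remaining
    three are ranked by a composite motility score — the mean of normalized
    speed, directionality and displacement minus normalized arrest — giving
    *directed* (highest), *patrolling* (middle), *focused_patrolling*
    (lowest). Residual ties break by ascending cluster id.
    """
    if len(profiles) != 5:
        raise ValueError(
            f"action labeling is defined for exactly 5 clusters, got {len(profiles)}"
        )
    M = np.array([[p.mean_features[f] for f in FEATURE_NAMES] for p in profiles])
    lo, hi = M.min(axis=0), M.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    N = (M - lo) / span  # columns: speed, displacement, directionality, arrest
    ids = [p.cluster_id for p in profiles]
    order = list(range(5))

    arrest = N[:, 3]
    speed = N[:, 0]
    # highest arrest -> arrested (ties: ascending cluster id)
    arrested_i = min(order, key=lambda i: (-arrest[i], ids[i]))
    rest = [i for i in order if i != arrested_i]
    # lowest arrest among the rest -> flowing (ties: highest speed, then id)
    flowing_i = min(rest, key=lambda i: (arrest[i], -speed[i], ids[i]))
    remaining = [i for i in rest if i != flowing_i]
    composite = (N[:, 0] + N[:, 1] + N[:, 2]) / 3.0 - N[:, 3]
    ranked = sorted(remaining, key=lambda i: (-composite[i], ids[i]))
    labels = {ids[arrested_i]: "arrested", ids[flowing_i]: "flowing",
              ids[ranked[0]]: "directed", ids[ranked[1]]: "patrolling",
              ids[ranked[2]]: "focused_patrolling"}
    logger.info("cluster label map: %s", labels)
    return labels


def condition_percentages(assignments: list[ActionAssignment]) -> pd.DataFrame:
    """Percentage of tracks in each cluster, per condition.

    Rows are (cluster_id, label), columns are conditions; each column sums
    to 100.
    """
    if not assignments:
        raise ValueError("no assignments")
    df = pd.DataFrame({
        "cluster_id": [a.cluster_id for a in assignments],
        "label": [a.label for a in assignments],
        "condition": [a.condition for a in assignments],
    })
    counts = df.groupby(["cluster_id", "label", "condition"]).size().unstack(
        "condition", fill_value=0)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"condition(s) with zero tracks: {empty}")
    return counts / totals * 100.0


def run_action_recognition(
    tracks: list[Track],
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    arrest_threshold: float = DEFAULT_ARREST_THRESHOLD,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    n_init: int = 10,
) -> tuple[list[ActionAssignment], list[ClusterProfile], dict[int, str], list[FeatureSeries]]:
    """Full tracklet → DTW → UMAP → k-means → label pipeline.

    Tracks are processed in canonical track_id order so the result does not
    depend on input ordering. Returns (assignments in input order restricted
    to featurizable tracks, cluster profiles, cluster→label map, feature
    series in the same order as assignments).
    """
    ordered = sorted(tracks, key=lambda t: t.track_id)
    series = build_feature_series(ordered, window, stride, arrest_threshold)
    D = cross_distance_matrix(series)
    emb = embed_2d(D, seed=seed, n_neighbors=min(n_neighbors, len(series) - 1),
                   min_dist=min_dist)
    ids = cluster_tracks(emb, k=k, seed=seed, n_init=n_init)
    profiles = profile_clusters(ids, series)
    label_map = annotate_actions(profiles) if k == 5 else {
        p.cluster_id: f"cluster_{p.cluster_id}" for p in profiles}
    assignments = [
        ActionAssignment(s.track_id, int(c), emb[i], label_map[int(c)], s.condition)
        for i, (s, c) in enumerate(zip(series, ids))
    ]
    return assignments, profiles, label_map, series
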