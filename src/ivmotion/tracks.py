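"""Cell tracks and per-track motility statistics.

A :class:`Track` is one cell's time-ordered centroid trajectory sampled at a
uniform frame interval, as produced by upstream detection/linking software
(e.g. an Imaris export). :func:`compute_metrics` scores a track with the
standard intravital-imaging motility statistics: duration, path length, net
displacement, mean/max speed, straightness, speed variation and arrest
coefficient.

Units: positions in micrometers, times in seconds, speeds in µm/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Default instantaneous-speed cutoff (µm/min) below which a step counts as
#: arrested. Common practice in T-cell imaging; configurable everywhere.
DEFAULT_ARREST_THRESHOLD = 2.0

#: Minimum number of time points for a track to enter the analysis.
DEFAULT_MIN_FRAMES = 5


class TrackValidationError(ValueError):
    """Raised when a track violates its structural invariants."""


@dataclass
class Track:
    """Time-ordered 3-D centroid positions of one cell.

    Parameters
    ----------
    track_id : str
        Identifier, unique within a cohort.
    positions : (n, 3) array
        Centroid positions in µm. For planar data pass z = 0.
    times : (n,) array
        Acquisition times in seconds, strictly increasing with uniform
        spacing (relative tolerance 1e-6 on the frame interval).
    condition : str
        Free-text recording condition (e.g. ``"untreated"``).
    """

    track_id: str
    positions: np.ndarray
    times: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrackValidationError(
                f"track {self.track_id!r}: positions must be (n, 3), "
                f"got {self.positions.shape}"
            )
        n = len(self.positions)
        if n < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: needs >= 2 time points, got {n}"
            )
        if self.times.shape != (n,):
            raise TrackValidationError(
                f"track {self.track_id!r}: times shape {self.times.shape} "
                f"does not match {n} positions"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite positions"
            )
        if not np.all(np.isfinite(self.times)):
            raise TrackValidationError(f"track {self.track_id!r}: non-finite times")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: times must be strictly increasing"
            )
        dt = steps[0]
        if np.any(np.abs(steps - dt) > 1e-6 * dt):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-uniform frame interval "
                f"(expected {dt} s)"
            )

    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return float(self.times[1] - self.times[0])

    def dropping_z(self) -> "Track":
        """Copy of the track with the z coordinate zeroed (planar analysis)."""
        planar = self.positions.copy()
        planar[:, 2] = 0.0
        return Track(self.track_id, planar, self.times.copy(), self.condition)


@dataclass
class TrackMetrics:
    """The per-track motility statistics.

    duration s; length, displacement µm; mean/max speed and speed variation
    µm/min; straightness and arrest coefficient dimensionless in [0, 1].
    """

    track_id: str
    duration: float
    length: float
    displacement: float
    mean_speed: float
    max_speed: float
    straightness: float
    speed_variation: float
    arrest_coefficient: float
    condition: str = ""

    def as_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "condition": self.condition,
            "duration_s": self.duration,
            "length_um": self.length,
            "displacement_um": self.displacement,
            "mean_speed_um_min": self.mean_speed,
            "max_speed_um_min": self.max_speed,
            "straightness": self.straightness,
            "speed_variation_um_min": self.speed_variation,
            "arrest_coefficient": self.arrest_coefficient,
        }


def filter_tracks(tracks: list[Track], min_frames: int = DEFAULT_MIN_FRAMES) -> list[Track]:
    """Drop tracks observed for fewer than ``min_frames`` time points.

    A track with exactly ``min_frames`` points is retained (strict ``<``
    exclusion). Order is preserved; the number removed is logged.
    """
    if min_frames < 2:
        raise ValueError(f"min_frames must be >= 2, got {min_frames}")
    kept = [t for t in tracks if t.n_points >= min_frames]
    removed = len(tracks) - len(kept)
    logger.info(
        "duration filter (min %d frames): kept %d of %d tracks (%d removed)",
        min_frames, len(kept), len(tracks), removed,
    )
    return kept


def step_speeds(track: Track) -> np.ndarray:
    """Instantaneous speeds (µm/min) for each consecutive position pair.

    Returns ``n_points - 1`` values: Euclidean step distance divided by the
    frame interval, converted from µm/s to µm/min.
    """
    disp = np.diff(track.positions, axis=0)
    dist = np.linalg.norm(disp, axis=1)
    return dist / track.dt * 60.0


def compute_metrics(
    track: Track,
    arrest_threshold: float = DEFAULT_ARREST_THRESHOLD,
) -> TrackMetrics:
    """Score one track with the full set of motility statistics.

    duration = t_last - t_first; length = summed step distances;
    displacement = |p_last - p_first|; mean speed = length / duration;
    max speed = largest step speed; straightness = displacement / length
    (0 for a zero-length track); speed variation = population standard
    deviation of the step speeds; arrest coefficient = fraction of steps
    slower than ``arrest_threshold`` µm/min.
    """
    speeds = step_speeds(track)
    dist = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    duration = float(track.times[-1] - track.times[0])
    length = float(dist.sum())
    displacement = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    mean_speed = length / duration * 60.0
    straightness = displacement / length if length > 0 else 0.0
    return TrackMetrics(
        track_id=track.track_id,
        duration=duration,
        length=length,
        displacement=displacement,
        mean_speed=mean_speed,
        max_speed=float(speeds.max()),
        straightness=straightness,
        speed_variation=float(speeds.std(ddof=0)),
        arrest_coefficient=float(np.mean(speeds < arrest_threshold)),
        condition=track.condition,
    )


def compare_groups(
    values_a,
    values_b,
    test: str = "mann_whitney",
) -> tuple[float, float]:
    """Two-sided comparison of a metric between two groups.

    ``test`` is ``"mann_whitney"`` (rank-based; ties handled by midranks,
    asymptotic normal approximation *without* continuity correction, so two
    identical groups give p = 1) or ``"t_test"`` (two-sample Student t).

    Returns ``(statistic, p_value)``. The Mann–Whitney statistic is the U of
    the first group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    elif test == "t_test":
        res = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test {test!r}; use 'mann_whitney' or 't_test'")
    return float(res.statistic), float(res.pvalue)
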