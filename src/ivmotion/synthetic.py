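"""Ground-truth track cohorts and rendered timelapses.

Five behavioral archetypes of migrating T cells — flowing, directed,
patrolling, focused patrolling, arrested — are generated by a two-state
(move/pause) persistent random walk. While moving, the step direction is the
previous direction rotated by a wrapped-normal turning angle whose
concentration is set by ``persistence`` (1 = ballistic), optionally blended
toward a target point; step length is a truncated-normal speed times the
frame interval. The pause state follows a two-state Markov chain, so the
long-run paused fraction is ``pause_on / (pause_on + pause_off)``.

Tracks are 3-D but the default presets confine z to small jitter, because
rendering and optical flow operate on a planar field of view.

The renderer paints each cell as an isotropic Gaussian blob over a constant
background with additive Gaussian noise, and a disk mask stands in for a
manually drawn tumor region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tracks import Track

ARCHETYPE_NAMES = (
    "flowing",
    "directed",
    "patrolling",
    "focused_patrolling",
    "arrested",
)


@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of one behavioral archetype.

    speed_mean / speed_sd in µm/min; ``persistence`` in [0, 1] is the mean
    resultant length of the wrapped-normal turning-angle distribution;
    ``pause_on_prob`` / ``pause_off_prob`` are the per-step Markov transition
    probabilities into and out of the paused state; ``target_bias`` in [0, 1]
    weights a drift toward a target point (directed migration only);
    ``z_sd`` (µm) is the per-step out-of-plane jitter; ``dt`` in seconds.
    """

    name: str
    speed_mean: float
    speed_sd: float
    persistence: float
    pause_on_prob: float
    pause_off_prob: float
    target_bias: float = 0.0
    n_steps: int = 30
    dt: float = 60.0
    z_sd: float = 0.0

    def __post_init__(self) -> None:
        for p in ("persistence", "pause_on_prob", "pause_off_prob", "target_bias"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {p}={v} must be in [0, 1]")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError(f"{self.name}: speeds must be non-negative")
        if self.n_steps < 2:
            raise ValueError(f"{self.name}: n_steps must be >= 2")
        if self.dt <= 0:
            raise ValueError(f"{self.name}: dt must be positive")
        if self.z_sd < 0:
            raise ValueError(f"{self.name}: z_sd must be non-negative")

    @property
    def stationary_pause_fraction(self) -> float:
        """Long-run fraction of paused steps of the two-state chain."""
        tot = self.pause_on_prob + self.pause_off_prob
        return self.pause_on_prob / tot if tot > 0 else 0.0


def default_presets(n_steps: int = 30, dt: float = 60.0) -> list[ArchetypeParams]:
    """The shipped archetype presets.

    Constants are fixed so that mean track speeds are strictly ordered
    flowing > directed > patrolling > focused patrolling > arrested, and the
    stationary pause fraction is largest for arrested, then focused
    patrolling. They emulate the qualitative behavior classes, not any
    in vivo measurement.
    """
    common = dict(n_steps=n_steps, dt=dt, z_sd=0.05)
    return [
        ArchetypeParams("flowing", 15.0, 2.0, 0.85, 0.02, 0.50, 0.0, **common),
        ArchetypeParams("directed", 10.0, 1.5, 0.90, 0.05, 0.50, 0.6, **common),
        ArchetypeParams("patrolling", 6.0, 1.5, 0.30, 0.10, 0.40, 0.0, **common),
        ArchetypeParams("focused_patrolling", 3.5, 1.0, 0.15, 0.35, 0.25, 0.0, **common),
        ArchetypeParams("arrested", 1.0, 0.3, 0.05, 0.60, 0.10, 0.0, **common),
    ]


@dataclass
class SyntheticCohort:
    """A generated track cohort with per-track ground-truth archetype labels."""

    tracks: list[Track]
    true_labels: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.tracks) != len(self.true_labels):
            raise ValueError("one label per track required")


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and photometry of a rendered timelapse.

    ``image_shape`` is (height, width) px; ``pixel_size`` µm/px; cells are
    Gaussian blobs of sigma ``psf_sigma`` px and peak ``amplitude`` over
    ``background``, with additive Gaussian noise of sd ``noise_sd``. The
    tumor is a disk of ``tumor_radius`` px at ``tumor_center`` = (x, y) px.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 1.0
    psf_sigma: float = 2.0
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    tumor_center: tuple[float, float] = (64.0, 64.0)
    tumor_radius: float = 40.0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        cx, cy = self.tumor_center
        r = self.tumor_radius
        if r < 0:
            raise ValueError("tumor_radius must be non-negative")
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            raise ValueError("tumor_center must lie within the frame")


def _turning_sigma(persistence: float) -> float:
    # wrapped-normal mean resultant length rho = exp(-sigma^2/2)
    if persistence >= 1.0:
        return 0.0
    if persistence <= 0.0:
        return np.inf  # caller falls back to a uniform angle
    return float(np.sqrt(-2.0 * np.log(persistence)))


def simulate_track(
    params: ArchetypeParams,
    start,
    seed: int,
    target=None,
    track_id: str | None = None,
    condition: str = "",
) -> Track:
    """Simulate one track of ``params.n_steps`` positions at spacing ``dt``.

    The cell begins in the move state with a uniformly random heading; each
    step first updates the pause chain, then (if moving) rotates the heading
    by a wrapped-normal angle, blends it toward ``target`` with weight
    ``target_bias``, and advances by a non-negative Gaussian speed × dt.
    Paused steps leave the position unchanged. z receives independent
    Gaussian jitter of sd ``z_sd`` per moving step.
    """
    start = np.asarray(start, dtype=float)
    if start.shape == (2,):
        start = np.append(start, 0.0)
    if start.shape != (3,) or not np.all(np.isfinite(start)):
        raise ValueError(f"start must be a finite 2- or 3-vector, got {start!r}")
    if target is not None:
        target = np.asarray(target, dtype=float)
        if target.shape == (2,):
            target = np.append(target, 0.0)
    elif params.target_bias > 0:
        raise ValueError(f"{params.name}: target_bias > 0 requires a target point")

    rng = np.random.default_rng(seed)
    n = params.n_steps
    pos = np.empty((n, 3))
    pos[0] = start
    theta = rng.uniform(0.0, 2.0 * np.pi)
    sigma = _turning_sigma(params.persistence)
    step_per_min = params.dt / 60.0  # µm/min -> µm per frame
    paused = False
    for i in range(1, n):
        # transition before moving, so pause_on_prob=1 pins the cell at start
        if paused:
            if rng.random() < params.pause_off_prob:
                paused = False
        else:
            if rng.random() < params.pause_on_prob:
                paused = True
        if paused:
            pos[i] = pos[i - 1]
            continue
        if np.isinf(sigma):
            theta = rng.uniform(0.0, 2.0 * np.pi)
        elif sigma > 0:
            theta += rng.normal(0.0, sigma)
        direction = np.array([np.cos(theta), np.sin(theta)])
        if params.target_bias > 0:
            to_target = target[:2] - pos[i - 1, :2]
            norm = np.linalg.norm(to_target)
            if norm > 0:
                blended = (1 - params.target_bias) * direction + \
                    params.target_bias * (to_target / norm)
                bn = np.linalg.norm(blended)
                if bn > 0:
                    direction = blended / bn
                    theta = np.arctan2(direction[1], direction[0])
        speed = max(rng.normal(params.speed_mean, params.speed_sd), 0.0) \
            if params.speed_sd > 0 else params.speed_mean
        step = speed * step_per_min
        pos[i, :2] = pos[i - 1, :2] + step * direction
        pos[i, 2] = pos[i - 1, 2] + (rng.normal(0.0, params.z_sd)
                                     if params.z_sd > 0 else 0.0)
    times = np.arange(n) * params.dt
    return Track(track_id or f"{params.name}-{seed}", pos, times, condition)


def simulate_cohort(
    presets: list[ArchetypeParams],
    n_per_archetype: int,
    seed: int,
    field_size: float = 300.0,
    condition: str = "",
) -> SyntheticCohort:
    """Generate ``n_per_archetype`` tracks per preset with derived seeds.

    Start positions are uniform over a ``field_size`` × ``field_size`` µm
    field; directed cells share a target at the field center. Output order
    and all positions are a pure function of ``seed``.
    """
    if not presets:
        raise ValueError("presets must be non-empty")
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be >= 1")
    tracks: list[Track] = []
    labels: list[str] = []
    target = np.array([field_size / 2.0, field_size / 2.0, 0.0])
    idx = 0
    for preset in presets:
        for j in range(n_per_archetype):
            ss = np.random.SeedSequence([seed, idx])
            start_rng = np.random.default_rng(ss.spawn(1)[0])
            start = start_rng.uniform(0.0, field_size, size=2)
            track_seed = int(ss.generate_state(1)[0] % (2**31))
            tracks.append(simulate_track(
                preset, start, track_seed,
                target=target if preset.target_bias > 0 else None,
                track_id=f"{preset.name}-{j:03d}",
                condition=condition,
            ))
            labels.append(preset.name)
            idx += 1
    return SyntheticCohort(tracks, labels, seed)


def render_timelapse(
    tracks: list[Track],
    spec: RenderSpec,
    seed: int,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render tracks into a (T, H, W) float timelapse.

    Each frame is the sum of isotropic Gaussian blobs (sigma ``psf_sigma``,
    peak ``amplitude``) at the cells' positions that frame, plus
    ``background``, plus seeded Gaussian noise of sd ``noise_sd``, clipped
    at zero. Track coordinates divided by ``pixel_size`` must fall inside
    the frame.
    """
    h, w = spec.image_shape
    if n_frames is None:
        n_frames = max((t.n_points for t in tracks), default=2)
    for t in tracks:
        px = t.positions[:, 0] / spec.pixel_size
        py = t.positions[:, 1] / spec.pixel_size
        if px.min() < 0 or px.max() > w - 1 or py.min() < 0 or py.max() > h - 1:
            raise ValueError(
                f"track {t.track_id!r} extends outside the {h}x{w} frame"
            )
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.full((n_frames, h, w), float(spec.background))
    inv2s2 = 1.0 / (2.0 * spec.psf_sigma**2)
    for t in tracks:
        for f in range(min(n_frames, t.n_points)):
            cx = t.positions[f, 0] / spec.pixel_size
            cy = t.positions[f, 1] / spec.pixel_size
            frames[f] += spec.amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) * inv2s2
            )
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
    return np.clip(frames, 0.0, None)


def make_tumor_mask(spec: RenderSpec) -> np.ndarray:
    """Binary (H, W) disk mask of the tumor region.

    A pixel (row, col) is inside when its center lies within
    ``tumor_radius`` of ``tumor_center`` (inclusive), so radius 0 with an
    integer-valued center yields a single-pixel mask.
    """
    h, w = spec.image_shape
    cx, cy = spec.tumor_center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.tumor_radius**2


def infiltration_scenario(
    seed: int,
    n_frames: int = 8,
    n_cells: int = 3,
    speed_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, "RenderSpec"]:
    """Paired pre/post timelapses emulating tumor-core infiltration.

    Before treatment, cells circulate in the peripheral band of the tumor;
    after treatment, the same number of cells move only within the core.
    Cells travel tangentially at ``speed_px`` px/frame on circles, so the
    per-band ground truth is: peripheral motility high→low, core motility
    low→high. Stationary cells scattered around the field provide static
    texture. Returns ``(frames_pre, frames_post, mask, spec)`` with a
    160×160 px field at 2 µm/px and a 70 px tumor disk (four 20-px bands
    at the default 40 µm spacing).
    """
    spec = RenderSpec(
        image_shape=(160, 160), pixel_size=2.0, psf_sigma=2.0,
        amplitude=100.0, background=10.0, noise_sd=0.0,
        tumor_center=(80.0, 80.0), tumor_radius=70.0,
    )
    mask = make_tumor_mask(spec)
    center_um = 80.0 * spec.pixel_size
    times = np.arange(n_frames) * 60.0

    def stationary(px, py, tag):
        pos = np.tile(np.array([px, py, 0.0]) * spec.pixel_size, (n_frames, 1))
        return Track(tag, pos, times)

    anchors = [stationary(px, py, f"anchor-{i}")
               for i, (px, py) in enumerate(
                   [(15, 15), (145, 15), (15, 145), (145, 145),
                    (80, 6), (6, 80)])]

    def circling(radius_px: float, tag: str) -> list[Track]:
        omega = speed_px / radius_px  # rad/frame for the target speed
        tracks = []
        for i in range(n_cells):
            phase = 2.0 * np.pi * i / n_cells
            theta = phase + omega * np.arange(n_frames)
            pos = np.column_stack([
                center_um + radius_px * spec.pixel_size * np.cos(theta),
                center_um + radius_px * spec.pixel_size * np.sin(theta),
                np.zeros(n_frames),
            ])
            tracks.append(Track(f"{tag}-{i}", pos, times))
        return tracks

    frames_pre = render_timelapse(circling(60.0, "pre") + anchors, spec, seed,
                                  n_frames=n_frames)
    frames_post = render_timelapse(circling(6.0, "post") + anchors, spec,
                                   seed + 1, n_frames=n_frames)
    return frames_pre, frames_post, mask, spec


def presets_with(presets: list[ArchetypeParams], **overrides) -> list[ArchetypeParams]:
    """Copies of ``presets`` with fields replaced (e.g. ``n_steps=50``)."""
    return [replace(p, **overrides) for p in presets]
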