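# Methods

## Scope and data model

The package analyzes cell tracks (time-ordered 3-D centroids at a uniform
frame interval, micrometers) and single-channel timelapse stacks with a
pixel size in µm/px, as produced upstream by detection/linking software
such as Imaris. It does not build tracks from images. Coordinates are µm in
a right-handed image frame with the origin at the top-left pixel center;
image pixel (row, col) maps to (y, x).

## Track metrics

For a track with positions p₀…pₙ at spacing Δt: duration = tₙ − t₀; length
L = Σ|pᵢ₊₁ − pᵢ|; displacement D = |pₙ − p₀|; mean speed = L/duration;
max speed = max step speed; straightness = D/L; speed variation = population
SD (n denominator) of the instantaneous step speeds; arrest coefficient =
fraction of steps below the arrest threshold.

Decisions where conventions were open:

- **Arrest threshold 2 µm/min** by default. The cutoff is not a universal
  constant; 2 µm/min is common practice in T-cell imaging. It is exposed in
  the config and recorded in every run manifest.
- **Speed variation = SD of step speeds.** The name alone does not fix a
  formula; SD (not variance or CV) was chosen and is what the tests pin.
- **Straightness of a zero-length track is 0**: a cell that never moved is
  maximally non-directed. This also keeps the value defined without special
  cases downstream.
- **Metrics are 3-D when z is present**; a `planar` flag zeroes z first.
- Tracks shorter than 5 time points are dropped before any statistic is
  computed (strict `<` cutoff: a 5-point track stays). With ≥ 2 points and
  strictly increasing times, no metric can divide by zero.

Group comparisons use the Mann–Whitney U test (midranks for ties,
asymptotic normal approximation without continuity correction, so two
identical samples give p = 1) or Student's t, both two-sided.

## Action recognition

1. **Tracklets**: an 8-point window slides with stride 1; a track with n
   points yields n − 7 tracklets. Tracks with 5–7 points pass the duration
   filter but cannot be featurized; they stay in the metrics output and are
   flagged out of action recognition.
2. **Features** per tracklet: mean step speed; net displacement
   (|p_end − p_start| of the window); directionality (net displacement over
   within-window path length — i.e. tracklet straightness); arrest
   coefficient. "Displacement" is the tracklet's net displacement; cluster
   averages over member tracklets then give per-cluster means.
3. **Standardization**: features are z-scored with cohort-wide mean and
   population SD, computed once and stored. Re-scoring a subset with the
   frozen scaler reproduces identical standardized features and DTW
   distances — removing one condition cannot shift the other's feature
   space. Constant features keep SD 1 to stay finite.
4. **DTW**: classic dynamic programming with Euclidean local cost between
   standardized 4-vectors; monotone, continuity-constrained path; the
   returned value is the unnormalized cumulative cost (a path-length
   normalized variant — cost / (len(a)+len(b)) — is available behind a
   flag). DTW here is a premetric: non-negative, zero on identical series,
   symmetric; the triangle inequality does not hold and is not relied on.
   An exhaustive warping-path enumeration for short series is kept in the
   test suite as the independent oracle.
5. **Embedding and clustering**: UMAP in precomputed-distance mode
   (n_neighbors 15, min_dist 0.1, fixed seed) to 2-D; k-means with
   k-means++ and 10 restarts on the embedding, k = 5. Clustering operates
   on the 2-D embedding (not on the distance matrix); this keeps the
   clusters aligned with what the embedding shows. UMAP is not equivariant
   under permutation of its input rows, so the pipeline sorts tracks by
   track_id before embedding; per-track results are therefore independent
   of input file order by construction.
6. **Labels**: min-max–normalize the five cluster profiles per feature,
   then: highest arrest → *arrested*; lowest arrest among the rest (ties:
   highest speed) → *flowing*; the remaining three ranked by composite
   score (mean of normalized speed, displacement, directionality, minus
   normalized arrest) → *directed* / *patrolling* / *focused patrolling*.
   Residual ties break by ascending cluster id, making the rule total and
   deterministic. Cluster ids themselves are arbitrary; reporting keys on
   the action label and the id→label map is logged and stored.

## Spatial motility

Dense optical flow is estimated between consecutive frames; the per-pixel
flow magnitude is averaged over all T−1 frame pairs ("max" available as an
alternative temporal statistic) and rescaled to [0, 1] by
(x − min)/(max − min). A constant raw map (e.g. a static scene) is rendered
as zeros and flagged rather than divided by zero. 4-D stacks are reduced by
maximum-intensity projection before flow, matching the planar heatmaps the
field uses.

The default estimator is iterative Lucas–Kanade (window radius 7, 10
warps), with TV-L1 as an alternative. The module's contract is
algorithm-independent and is what the tests enforce: a rigid translation of
a textured scene by 0.5–5 px/frame is recovered within ±20% median error
over the object support. Lucas–Kanade assigns the translation to a halo
around a moving object (its window sees the object's gradients), so maps
should be read as motility fields, not segmentations.

Concentric bands: the tumor mask is repeatedly eroded by a discrete disk of
radius round(spacing/pixel size) px (default spacing 40 µm); each band is
the set difference of consecutive erosions, the last non-empty remainder is
the core, and the bands exactly partition the mask. The disk structuring
element gives isotropic (Euclidean) distance semantics; tests verify band
counts against a Euclidean distance transform within ±1 px discretization.
Band labels are Roman numerals from periphery to core. Paired pre/post
quantification uses one band decomposition and identical flow parameters
for both recordings.

## Synthetic data

Tracks: a two-state (move/pause) persistent random walk. Per step the pause
chain transitions first (so `pause_on_prob=1` pins a cell at its start);
while moving, the heading rotates by a wrapped-normal angle with
concentration σ = √(−2 ln ρ) where ρ is the `persistence` parameter (the
mean resultant length; ρ = 1 is ballistic, ρ = 0 a uniform angle), is
optionally blended toward a target point with weight `target_bias`
(directed migration), and the step length is a non-negative Gaussian speed
× Δt. The long-run paused fraction is pause_on/(pause_on+pause_off).
Tracks are 3-D with small z jitter (0.05 µm/step by default) because the
rendering and flow analysis are planar.

Defaults: Δt = 60 s (so the 5-frame duration filter equals 300 s of
observation), 30 steps per track, starts uniform in a 300 µm field. The
five presets (speed mean/SD in µm/min; persistence; pause on/off):

| archetype          | speed      | persistence | pause on/off | bias |
|--------------------|-----------|-------------|--------------|------|
| flowing            | 15 ± 2    | 0.85        | 0.02 / 0.50  | 0    |
| directed           | 10 ± 1.5  | 0.90        | 0.05 / 0.50  | 0.6  |
| patrolling         | 6 ± 1.5   | 0.30        | 0.10 / 0.40  | 0    |
| focused patrolling | 3.5 ± 1   | 0.15        | 0.35 / 0.25  | 0    |
| arrested           | 1 ± 0.3   | 0.05        | 0.60 / 0.10  | 0    |

These constants are fixed package defaults chosen so that the archetypes
are strictly ordered in mean speed and the arrested/focused-patrolling
pause fractions dominate; they model the qualitative behavior classes, not
any in vivo measurement.

Rendering: per frame, each cell is an isotropic Gaussian blob (σ 2 px, peak
100) over a constant background, plus optional additive Gaussian noise,
clipped at 0. Additive Gaussian (rather than Poisson) noise keeps the
photometry analytically checkable (total above-background mass = 2πAσ²);
Poisson statistics, PSF physics, tumor growth, division, and cell–cell
contact are deliberately out of scope. The infiltration scenario renders
cells circling in the peripheral band before treatment and only in the core
after, with stationary anchor cells for texture — giving known per-band
ground truth for the pre/post comparison.

What passing on synthetic data does and does not show: the generator
produces clean, well-separated behaviors with stationary parameters, no
detection noise, no track fragmentation or drift, and blob-shaped cells on
a flat background. Results demonstrate the correctness and stability of the
computations, not classification performance on real intravital recordings.

## Determinism and problem sizes

Every stochastic step flows from explicit seeds (per-track seeds derive
from the cohort seed; UMAP and k-means take fixed random states), and two
runs with equal config produce byte-identical CSVs. The shipped study sizes
— 5 × 40 tracks of 30 frames for behavioral recovery, 160² px timelapses of
8 frames for flow scenarios — were chosen as the smallest cohorts at which
the five archetypes separate cleanly and flow statistics stabilize.
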