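# ivmotion

Motility analysis for intravital two-photon imaging of T cells in tumor
tissue. The package answers a recurring question in tumor immunology: when a
therapy is delivered, do cytotoxic CD8⁺ T cells around and inside the lesion
actually change how they move — and where? It provides, as one tested
pipeline:

- **Track metrics** — the standard per-track statistics computed from cell
  trajectories: duration, track length *L* (summed step distances), net
  displacement *D*, mean speed *L/T*, maximum instantaneous speed,
  straightness *D/L*, speed variation (SD of instantaneous speeds), and the
  arrest coefficient (fraction of steps slower than a threshold, default
  2 µm/min). Tracks observed for fewer than 5 frames are excluded.
- **Behavioral action recognition** — each track is cut into sliding
  8-point tracklets; each tracklet is summarized by four features (mean
  speed, net displacement, directionality, arrest coefficient); tracks are
  compared as multivariate feature series with dynamic time warping (DTW),
  which tolerates unequal track lengths; the DTW cross-distance matrix is
  embedded in 2-D with UMAP, partitioned by k-means (k = 5), and each
  cluster is named by a deterministic rule on its feature profile as one of
  five actions: *flowing*, *directed*, *patrolling*, *focused patrolling*,
  *arrested*.
- **Pixel motility maps** — dense optical flow between consecutive frames
  of the T-cell channel, time-averaged per pixel and min-max rescaled to
  [0, 1] (mat2gray), then quantified over equidistant concentric bands
  (default 40 µm) obtained by progressively eroding a tumor mask — so
  motility can be resolved from the tumor periphery to its core.
- **A synthetic-data generator** — a two-state persistent random walk with
  five behavioral archetypes, plus a Gaussian-blob timelapse renderer and
  disk tumor masks, providing ground truth that in vivo recordings cannot.

## Worked example

```python
import numpy as np
from ivmotion import (default_presets, simulate_cohort, compute_metrics,
                      run_action_recognition)

cohort = simulate_cohort(default_presets(), 40, seed=1)   # 5 x 40 tracks
metrics = {}
for track, label in zip(cohort.tracks, cohort.true_labels):
    metrics.setdefault(label, []).append(compute_metrics(track))
for label, ms in metrics.items():
    print(f"{label:>18}: speed {np.mean([m.mean_speed for m in ms]):5.1f} um/min, "
          f"displacement {np.mean([m.displacement for m in ms]):6.1f} um, "
          f"arrest {np.mean([m.arrest_coefficient for m in ms]):.2f}")

assignments, profiles, label_map, _ = run_action_recognition(cohort.tracks, seed=0)
print("cluster -> action:", label_map)
```

prints

```
           flowing: speed  14.3 um/min, displacement  239.7 um, arrest 0.04
          directed: speed   9.1 um/min, displacement  108.4 um, arrest 0.08
        patrolling: speed   4.7 um/min, displacement   34.0 um, arrest 0.23
focused_patrolling: speed   1.6 um/min, displacement   12.0 um, arrest 0.58
          arrested: speed   0.1 um/min, displacement    1.8 um, arrest 1.00
cluster -> action: {3: 'arrested', 0: 'flowing', 2: 'directed', 4: 'patrolling', 1: 'focused_patrolling'}
```

The five archetypes are cleanly ordered in speed and displacement, and the
unsupervised pipeline recovers them: the adjusted Rand index between the
k-means clusters and the generating archetypes on this cohort is 0.917,
with all five clusters named correctly.

## Command line

```
ivmotion simulate --seed 2 --out sim --render   # cohort CSV + timelapse + mask
ivmotion run sim/tracks.csv --seed 0 --out run  # filter -> metrics -> actions
ivmotion spatial sim/timelapse.tif sim/tumor_mask.tif --out sp
ivmotion report run                             # Markdown summary
```

`ivmotion run` writes `track_metrics.csv`, `metrics_summary.json`,
`embedding.csv` (track, UMAP coordinates, cluster, action label),
`cluster_profiles.csv`, `condition_percentages.csv`, and a `manifest.json`
that records the config, seeds, library versions and track counts at every
filter, so a run can be reproduced exactly.

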