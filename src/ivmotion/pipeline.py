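"""Pipeline driver: filter → metrics → action recognition → spatial motility.

Outputs land in a run directory: per-track metrics CSV, group-comparison
JSON summary, embedding CSV (track, 2-D coordinates, cluster, label),
cluster-profile CSV, condition-percentage CSV, optional motility map
(float32 TIFF + PNG) and band table, and a JSON manifest recording the
config, seeds, library versions and track counts at every filter so a run
can be replayed.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actions import condition_percentages, run_action_recognition, FEATURE_NAMES
from .config import RunConfig
from .io import read_mask, read_timelapse, read_tracks, write_timelapse
from .spatial import FlowParams, ImageSequence, before_after_bands, erode_bands, \
    band_motility, motility_map
from .tracks import compare_groups, compute_metrics, filter_tracks

logger = logging.getLogger(__name__)


def _lib_versions() -> dict:
    import numpy, scipy, pandas, sklearn, skimage, umap
    return {
        "ivmotion": __version__, "numpy": numpy.__version__,
        "scipy": scipy.__version__, "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-image": skimage.__version__, "umap-learn": umap.__version__,
    }


def metrics_stage(tracks, config: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Score every retained track and compare conditions where possible."""
    if config.planar:
        tracks = [t.dropping_z() for t in tracks]
    rows = [compute_metrics(t, config.arrest_threshold).as_dict() for t in tracks]
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "track_metrics.csv", index=False)

    summary: dict = {"n_tracks": len(df)}
    conditions = sorted(set(df["condition"])) if len(df) else []
    metric_cols = [c for c in df.columns if c not in ("track_id", "condition")]
    summary["group_means"] = {
        cond: df[df["condition"] == cond][metric_cols].mean().to_dict()
        for cond in conditions
    }
    if len(conditions) == 2:
        a = df[df["condition"] == conditions[0]]
        b = df[df["condition"] == conditions[1]]
        tests = {}
        for col in metric_cols:
            if len(a) >= 3 and len(b) >= 3:
                stat, p = compare_groups(a[col], b[col], "mann_whitney")
                tests[col] = {"U": stat, "p_value": p}
        summary["mann_whitney"] = {"groups": conditions, "tests": tests}
    with open(out_dir / "metrics_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return df


def actions_stage(tracks, config: RunConfig, out_dir: Path):
    """Run action recognition and write embedding/profile/percentage tables."""
    assignments, profiles, label_map, series = run_action_recognition(
        tracks,
        window=config.window, stride=config.stride,
        arrest_threshold=config.arrest_threshold,
        k=config.k, seed=config.seed,
        n_neighbors=config.umap["n_neighbors"],
        min_dist=config.umap["min_dist"],
        n_init=config.kmeans["n_init"],
    )
    emb = pd.DataFrame({
        "track_id": [a.track_id for a in assignments],
        "u1": [a.embedding[0] for a in assignments],
        "u2": [a.embedding[1] for a in assignments],
        "cluster": [a.cluster_id for a in assignments],
        "label": [a.label for a in assignments],
        "condition": [a.condition for a in assignments],
    })
    emb.to_csv(out_dir / "embedding.csv", index=False, float_format="%.8g")
    prof = pd.DataFrame([
        {"cluster_id": p.cluster_id, "label": label_map[p.cluster_id],
         "member_tracklets": p.member_count, **p.mean_features}
        for p in profiles
    ])
    prof.to_csv(out_dir / "cluster_profiles.csv", index=False, float_format="%.8g")
    if any(a.condition for a in assignments):
        pct = condition_percentages(assignments)
        pct.to_csv(out_dir / "condition_percentages.csv", float_format="%.8g")
    scaler = series[0].scaler
    extras = {
        "label_map": {str(k): v for k, v in label_map.items()},
        "standardization": {
            "feature_names": list(FEATURE_NAMES),
            "mean": scaler.mean.tolist(), "sd": scaler.sd.tolist(),
        },
        "n_tracks_featurized": len(assignments),
    }
    return assignments, extras


def spatial_stage(images_path, mask_path, config: RunConfig, out_dir: Path,
                  images_post_path=None) -> dict:
    """Motility map(s) and concentric-band quantification."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flow = FlowParams(**config.flow)
    mask = read_mask(mask_path)
    seq = ImageSequence(read_timelapse(images_path), config.pixel_size, config.dt)
    if images_post_path is not None:
        seq_post = ImageSequence(read_timelapse(images_post_path),
                                 config.pixel_size, config.dt)
        table = before_after_bands(seq, seq_post, mask,
                                   config.band_spacing_um, flow)
        mmap = motility_map(seq_post, flow)
    else:
        mmap = motility_map(seq, flow)
        bands = erode_bands(mask, config.band_spacing_um, config.pixel_size)
        table = band_motility(mmap, bands)
    table.to_csv(out_dir / "band_motility.csv", index=False, float_format="%.8g")
    write_timelapse(mmap.values[None], out_dir / "motility_map.tif")
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(mmap.values, cmap="inferno", vmin=0, vmax=1)
    ax.contour(mask, levels=[0.5], colors="cyan", linewidths=0.8)
    fig.colorbar(im, ax=ax, label="normalized pixel motility")
    ax.set_axis_off()
    fig.savefig(out_dir / "motility_map.png", dpi=150, bbox_inches="tight")
    plt.close(fig)
    return {"n_bands": len(table), "constant_map": bool(mmap.constant)}


def run_pipeline(config: RunConfig, tracks_path, images_path=None,
                 mask_path=None, images_post_path=None) -> Path:
    """Execute the full analysis; returns the run directory.

    The spatial stage runs only when both an image stack and a mask are
    given. Any stage failure is recorded in the manifest before the
    exception propagates; partial outputs are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": _lib_versions(),
        "inputs": {"tracks": str(tracks_path),
                   "images": str(images_path) if images_path else None,
                   "mask": str(mask_path) if mask_path else None},
        "stages": {},
    }

    def _save_manifest():
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)

    try:
        tracks = read_tracks(tracks_path, dt=config.dt)
        manifest["counts"] = {"n_input": len(tracks)}
        kept = filter_tracks(tracks, config.min_frames)
        manifest["counts"]["n_after_duration_filter"] = len(kept)
        manifest["stages"]["filter"] = "ok"

        metrics_stage(kept, config, out_dir)
        manifest["stages"]["metrics"] = "ok"

        featurizable = [t for t in kept if t.n_points >= config.window]
        manifest["counts"]["n_after_tracklet_filter"] = len(featurizable)
        if len(featurizable) >= max(config.k, 3):
            _, extras = actions_stage(featurizable, config, out_dir)
            manifest["actions"] = extras
            manifest["stages"]["actions"] = "ok"
        else:
            manifest["stages"]["actions"] = "skipped (too few featurizable tracks)"

        if images_path is not None and mask_path is not None:
            manifest["spatial"] = spatial_stage(
                images_path, mask_path, config, out_dir, images_post_path)
            manifest["stages"]["spatial"] = "ok"
        else:
            manifest["stages"]["spatial"] = "skipped (no images/mask)"
    except Exception as exc:
        failed = next((s for s in ("filter", "metrics", "actions", "spatial")
                       if s not in manifest["stages"]), "unknown")
        manifest["stages"][failed] = f"failed: {exc}"
        _save_manifest()
        raise
    _save_manifest()
    logger.info("run complete: %s", out_dir)
    return out_dir


def write_report(run_dir) -> Path:
    """Render a Markdown summary of a completed run from its CSV outputs."""
    run_dir = Path(run_dir)
    lines = ["# ivmotion run report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        counts = manifest.get("counts", {})
        lines += [f"- tracks read: {counts.get('n_input', '?')}",
                  f"- after duration filter: {counts.get('n_after_duration_filter', '?')}",
                  f"- featurizable (>= window points): "
                  f"{counts.get('n_after_tracklet_filter', '?')}", ""]
    for name, title in [("track_metrics.csv", "Track metrics (first rows)"),
                        ("cluster_profiles.csv", "Cluster profiles"),
                        ("condition_percentages.csv", "Cluster percentages per condition"),
                        ("band_motility.csv", "Band motility")]:
        path = run_dir / name
        lines.append(f"## {title}")
        if path.exists():
            df = pd.read_csv(path)
            lines.append(df.head(10).to_markdown(index=False))
        else:
            lines.append("_stage output missing_")
        lines.append("")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
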