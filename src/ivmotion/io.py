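"""Track tables, image stacks, and masks on disk.

Two CSV dialects are understood: ``plain`` (columns ``track_id, frame,
time_s, x_um, y_um, z_um, condition``) and ``imaris`` (the common Imaris
export convention ``TrackID, Time, Position X, Position Y, Position Z``).
Coordinates are micrometers in a right-handed image frame with the origin at
the top-left pixel center; image pixel (row, col) corresponds to (y, x).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracks import Track

logger = logging.getLogger(__name__)

PLAIN_COLUMNS = {
    "track_id": "track_id", "frame": "frame", "time": "time_s",
    "x": "x_um", "y": "y_um", "z": "z_um", "condition": "condition",
}
IMARIS_COLUMNS = {
    "track_id": "TrackID", "frame": "Time", "time": None,
    "x": "Position X", "y": "Position Y", "z": "Position Z",
    "condition": "condition",
}
DIALECTS = {"plain": PLAIN_COLUMNS, "imaris": IMARIS_COLUMNS}


def _resolve_dialect(columns, dialect: str | dict) -> dict:
    if isinstance(dialect, dict):
        return {**PLAIN_COLUMNS, **dialect}
    if dialect in DIALECTS:
        return DIALECTS[dialect]
    if dialect != "auto":
        raise ValueError(f"unknown dialect {dialect!r}; use 'plain', 'imaris', "
                         "'auto', or an explicit column map")
    cols = set(columns)
    if {"track_id", "x_um"} <= cols:
        return PLAIN_COLUMNS
    if {"TrackID", "Position X"} <= cols:
        return IMARIS_COLUMNS
    raise ValueError(
        f"cannot auto-detect CSV dialect from columns {sorted(cols)}; "
        "pass dialect='plain', 'imaris', or a column map"
    )


def read_tracks(path, dialect: str | dict = "auto",
                dt: float | None = None) -> list[Track]:
    """Read a track table into validated :class:`Track` objects.

    Within each track, rows are sorted by frame. Time is taken from the time
    column when the dialect provides one, otherwise as frame index × ``dt``
    (required in that case). Duplicate (track, frame) pairs and non-numeric
    coordinates raise errors naming the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cmap = _resolve_dialect(df.columns, dialect)
    for key in ("track_id", "frame", "x", "y"):
        if cmap[key] not in df.columns:
            raise ValueError(f"{path}: missing required column {cmap[key]!r}")
    for key in ("x", "y", "z"):
        col = cmap[key]
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric coordinate in column {col!r} "
                    f"at data row(s) {list(bad + 2)[:5]}"  # 1-based incl. header
                )
            df[col] = vals
    dup = df.duplicated(subset=[cmap["track_id"], cmap["frame"]])
    if dup.any():
        rows = list(df.index[dup] + 2)
        raise ValueError(f"{path}: duplicate (track, frame) pair at row(s) {rows[:5]}")

    have_time = cmap["time"] is not None and cmap["time"] in df.columns
    if not have_time and dt is None:
        raise ValueError(f"{path}: no time column; pass dt (s/frame)")

    tracks = []
    for tid, g in df.groupby(cmap["track_id"], sort=False):
        g = g.sort_values(cmap["frame"])
        pos = np.column_stack([
            g[cmap["x"]].to_numpy(float),
            g[cmap["y"]].to_numpy(float),
            g[cmap["z"]].to_numpy(float) if cmap["z"] in g.columns
            else np.zeros(len(g)),
        ])
        times = (g[cmap["time"]].to_numpy(float) if have_time
                 else g[cmap["frame"]].to_numpy(float) * dt)
        cond = ""
        if cmap["condition"] in g.columns:
            cond = str(g[cmap["condition"]].iloc[0])
        tracks.append(Track(str(tid), pos, times, cond))
    logger.info("read %d tracks from %s", len(tracks), path)
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks in the ``plain`` CSV dialect."""
    rows = []
    for t in tracks:
        for f in range(t.n_points):
            rows.append({
                "track_id": t.track_id, "frame": f, "time_s": t.times[f],
                "x_um": t.positions[f, 0], "y_um": t.positions[f, 1],
                "z_um": t.positions[f, 2], "condition": t.condition,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_timelapse(frames: np.ndarray, path) -> None:
    """Write a (T, H, W) stack as a multi-page grayscale float32 TIFF."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_timelapse(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0
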