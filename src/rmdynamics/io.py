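"""CSV readers/writers binding the pipeline stages together.

All files are comma-separated UTF-8 with a header row and '.' decimals.
Writers prepend a schema-version comment line (``# rmdynamics-schema:
<name> v1``); readers skip comment lines, validate required columns and
report the offending row/column on failure.  Coordinates are um (written
to 1e-6), track times seconds, expression times minutes (1e-3).

A TrackMate-style spot export can be ingested by supplying a column-name
mapping (see :data:`TRACKMATE_MAPPING`).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from rmdynamics.geometry import CellGeometry
from rmdynamics.simulate.tracks import TrackSet

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_geometries",
    "write_geometries",
    "read_traces",
    "write_traces",
    "read_assays",
    "TRACKMATE_MAPPING",
]

TRACK_COLUMNS = ["track_id", "cell_id", "frame", "t_s", "x_um", "y_um"]
GEOMETRY_COLUMNS = ["cell_id", "cx_um", "cy_um", "angle_rad", "length_um", "width_um"]
TRACE_COLUMNS = ["cell_id", "t_min", "channel", "intensity"]
ASSAY_COLUMNS = ["label", "replicate", "numerator", "denominator", "dilution"]

#: Column mapping for a TrackMate spot-table export (positions already in um).
TRACKMATE_MAPPING = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_T": "t_s",
    "POSITION_X": "x_um",
    "POSITION_Y": "y_um",
}


def _write_csv(df: pd.DataFrame, path: str | Path, schema: str, floats: dict[str, int]) -> None:
    df = df.copy()
    for col, dec in floats.items():
        if col in df:
            df[col] = df[col].map(lambda v: f"{v:.{dec}f}" if pd.notna(v) else "")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# rmdynamics-schema: {schema} v1\n")
        df.to_csv(fh, index=False)


def _read_csv(path: str | Path, required: list[str], schema: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for {schema}")
    return df


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    cols = TRACK_COLUMNS + (["state_true"] if "state_true" in tracks.table else [])
    _write_csv(
        tracks.table[cols],
        path,
        "tracks",
        {"t_s": 6, "x_um": 6, "y_um": 6},
    )


def read_tracks(
    path: str | Path,
    frame_interval: float | None = None,
    geometries: dict[str, CellGeometry] | None = None,
    column_mapping: dict[str, str] | None = None,
) -> TrackSet:
    """Load a track table; ``column_mapping`` adapts foreign exports.

    When the mapped table lacks a cell_id column (TrackMate exports
    don't have one), all tracks are assigned to a single cell "cell0".
    The frame interval is inferred from the time column unless given.
    """
    df = pd.read_csv(path, comment="#")
    if column_mapping:
        df = df.rename(columns=column_mapping)
        if "cell_id" not in df.columns:
            df["cell_id"] = "cell0"
        df = df[[c for c in df.columns if c in TRACK_COLUMNS + ["state_true"]]]
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for tracks")
    df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    for tid, sub in df.groupby("track_id", sort=False):
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            bad = int(np.argmax(np.diff(frames) <= 0)) + 1
            raise ValueError(
                f"{path}: track {tid!r} row {sub.index[bad]}: frames not strictly increasing"
            )
    if frame_interval is None:
        dts = df.groupby("track_id", sort=False)["t_s"].diff().dropna()
        frame_interval = float(dts.median()) if len(dts) else 0.02
    return TrackSet(
        table=df,
        frame_interval=frame_interval,
        geometries=geometries or {},
    )


def write_geometries(geometries: dict[str, CellGeometry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_id": g.cell_id,
                "cx_um": g.cx,
                "cy_um": g.cy,
                "angle_rad": g.angle,
                "length_um": g.length,
                "width_um": g.width,
            }
            for g in geometries.values()
        ],
        columns=GEOMETRY_COLUMNS,
    )
    _write_csv(
        df,
        path,
        "geometries",
        {c: 6 for c in GEOMETRY_COLUMNS if c != "cell_id"},
    )


def read_geometries(path: str | Path) -> dict[str, CellGeometry]:
    df = _read_csv(path, GEOMETRY_COLUMNS, "geometries")
    return {
        str(r.cell_id): CellGeometry(
            str(r.cell_id), r.cx_um, r.cy_um, r.angle_rad, r.length_um, r.width_um
        )
        for r in df.itertuples()
    }


def write_traces(traces: pd.DataFrame, path: str | Path) -> None:
    cols = TRACE_COLUMNS + (["od600"] if "od600" in traces else [])
    _write_csv(traces[cols], path, "traces", {"t_min": 3, "intensity": 6, "od600": 6})


def read_traces(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, TRACE_COLUMNS, "traces")
    bad = ~df["channel"].isin(["green", "red"])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"{path}: row {row}, column 'channel': expected green/red")
    if (df["intensity"] < 0).any():
        warnings.warn(f"{path}: negative intensities present")
    for sid, sub in df.groupby(["cell_id", "channel"], sort=False):
        t = sub["t_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: {sid}: t_min not strictly increasing")
    return df


def read_assays(path: str | Path) -> pd.DataFrame:
    """Count-assay table: label, replicate, numerator, denominator, dilution."""
    df = _read_csv(path, ASSAY_COLUMNS, "assays")
    if (df["denominator"] <= 0).any():
        row = int(df.index[df["denominator"] <= 0][0])
        raise ValueError(f"{path}: row {row}, column 'denominator': must be > 0")
    return df
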