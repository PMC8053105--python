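"""Confined-motion detection and standardized-cell projection.

A molecule is *confined* while it stays within a fixed radius (default
120 nm, i.e. four times the 30 nm localization error) of its local
centroid for a minimum number of consecutive steps.  Two thresholds are
in common use and both ship as named presets: 9 steps ("results") and 5
steps ("legend"); the default is 9.  Tracks are labelled confined / free
/ transition from the step coverage of their confined segments.

For population views, tracks from many cells are affinely mapped into a
standardized 3x1 um cell (translate to the cell center, rotate the long
axis onto x, scale each axis) and binned into a heat-map grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rmdynamics.geometry import CellGeometry
from rmdynamics.simulate.tracks import TrackSet

__all__ = [
    "ConfinementParams",
    "TrackClassification",
    "confined_segments",
    "classify_track",
    "classify_tracks",
    "StandardCellProjection",
    "project_to_standard_cell",
    "fraction_in_region",
    "CONFINEMENT_PRESETS",
]

STANDARD_LENGTH = 3.0
STANDARD_WIDTH = 1.0


@dataclass(frozen=True)
class ConfinementParams:
    """Radius (um) and minimum consecutive steps defining confinement."""

    radius: float = 0.12
    min_consecutive_steps: int = 9
    coverage_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.min_consecutive_steps < 2:
            raise ValueError("min_consecutive_steps must be >= 2")
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must be in (0, 1]")


CONFINEMENT_PRESETS = {
    "results": ConfinementParams(min_consecutive_steps=9),
    "legend": ConfinementParams(min_consecutive_steps=5),
}


@dataclass(frozen=True)
class TrackClassification:
    track_id: str
    label: str  # confined | free | transition
    confined_segments: tuple[tuple[int, int], ...]
    coverage: float


def _window_ok(xy: np.ndarray, radius: float) -> bool:
    """Every point within ``radius`` of the window centroid."""
    c = xy.mean(axis=0)
    return bool(np.all(np.linalg.norm(xy - c, axis=1) <= radius + 1e-12))


def confined_segments(
    xy: np.ndarray, params: ConfinementParams = ConfinementParams()
) -> list[tuple[int, int]]:
    """Maximal confined segments of a track, as (start, end) frame indices.

    For each start index the longest window whose points all lie within
    ``params.radius`` of the window centroid is found; windows spanning
    at least ``min_consecutive_steps`` steps are kept, non-maximal
    windows dropped, and overlapping or touching windows merged into
    maximal segments.  Segments are closed intervals of localization
    indices; their step count is end - start.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    min_steps = params.min_consecutive_steps
    if n - 1 < min_steps:
        return []
    windows = []
    for i in range(n - min_steps):
        best_j = -1
        for j in range(i + min_steps, n):
            if _window_ok(xy[i : j + 1], params.radius):
                best_j = j
        if best_j >= 0:
            windows.append((i, best_j))
    if not windows:
        return []
    # drop windows contained in another, then merge overlaps
    maximal = [
        w
        for w in windows
        if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in windows)
    ]
    maximal.sort()
    merged = [maximal[0]]
    for s, e in maximal[1:]:
        ps, pe = merged[-1]
        if s <= pe:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def classify_track(
    xy: np.ndarray,
    params: ConfinementParams = ConfinementParams(),
    track_id: str = "",
) -> TrackClassification:
    """Label one track confined / free / transition.

    Confined: confined segments cover at least ``coverage_threshold`` of
    the track's steps.  Free: no confined segment.  Transition: some but
    not enough coverage.
    """
    xy = np.asarray(xy, dtype=float)
    segs = confined_segments(xy, params)
    n_steps = len(xy) - 1
    covered = sum(e - s for s, e in segs)
    coverage = covered / n_steps if n_steps > 0 else 0.0
    if not segs:
        label = "free"
    elif coverage >= params.coverage_threshold:
        label = "confined"
    else:
        label = "transition"
    return TrackClassification(
        track_id=track_id,
        label=label,
        confined_segments=tuple(segs),
        coverage=coverage,
    )


def classify_tracks(
    tracks: TrackSet,
    params: ConfinementParams = ConfinementParams(),
    min_steps: int = 5,
) -> pd.DataFrame:
    """Classify every admissible track; returns one row per track."""
    rows = []
    for tid, sub in tracks.iter_tracks():
        if len(sub) - 1 < min_steps:
            continue
        cls = classify_track(sub[["x_um", "y_um"]].to_numpy(), params, track_id=tid)
        rows.append(
            {
                "track_id": tid,
                "label": cls.label,
                "n_segments": len(cls.confined_segments),
                "coverage": cls.coverage,
            }
        )
    return pd.DataFrame(rows, columns=["track_id", "label", "n_segments", "coverage"])


@dataclass(frozen=True)
class StandardCellProjection:
    """Heat-map grid plus the transformed localizations behind it."""

    counts: np.ndarray  # (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray
    points: pd.DataFrame  # track_id, cell_id, x_std, y_std
    n_out_of_bounds: int


def project_to_standard_cell(
    tracks: TrackSet,
    geometries: dict[str, CellGeometry] | None = None,
    bins: tuple[int, int] = (60, 20),
) -> StandardCellProjection:
    """Project all localizations into the standardized 3x1 um cell.

    Each localization is mapped into its cell's frame and scaled per axis
    by (3/length, 1/width), then binned on a (nx, ny) grid over
    [-1.5, 1.5] x [-0.5, 0.5] um.  The transform is affine and exactly
    invertible for in-bounds points.
    """
    geoms = geometries if geometries is not None else tracks.geometries
    missing = set(tracks.table["cell_id"]) - set(geoms)
    if missing:
        raise KeyError(f"no geometry for cell_id(s): {sorted(missing)}")
    nx, ny = bins
    out = []
    for cid, sub in tracks.table.groupby("cell_id", sort=False):
        g = geoms[cid]
        local = g.to_cell_frame(sub[["x_um", "y_um"]].to_numpy())
        local[:, 0] *= STANDARD_LENGTH / g.length
        local[:, 1] *= STANDARD_WIDTH / g.width
        out.append(
            pd.DataFrame(
                {
                    "track_id": sub["track_id"].to_numpy(),
                    "cell_id": cid,
                    "x_std": local[:, 0],
                    "y_std": local[:, 1],
                }
            )
        )
    points = pd.concat(out, ignore_index=True)
    hx = STANDARD_LENGTH / 2.0
    hy = STANDARD_WIDTH / 2.0
    in_bounds = (
        (points["x_std"] >= -hx)
        & (points["x_std"] <= hx)
        & (points["y_std"] >= -hy)
        & (points["y_std"] <= hy)
    )
    counts, x_edges, y_edges = np.histogram2d(
        points.loc[in_bounds, "x_std"],
        points.loc[in_bounds, "y_std"],
        bins=bins,
        range=[[-hx, hx], [-hy, hy]],
    )
    return StandardCellProjection(
        counts=counts.T,
        x_edges=x_edges,
        y_edges=y_edges,
        points=points,
        n_out_of_bounds=int((~in_bounds).sum()),
    )


def fraction_in_region(
    projection: StandardCellProjection | pd.DataFrame,
    region: tuple[float, float, float, float] = (-1.0, 1.0, -0.35, 0.35),
) -> float:
    """Fraction of standardized-cell localizations inside a rectangle.

    ``region`` is (xmin, xmax, ymin, ymax) in standardized-cell um; the
    default is a central 2.0 x 0.7 um nucleoid-sized box.  Used to
    quantify nucleoid enrichment of slow molecules.
    """
    pts = projection.points if isinstance(projection, StandardCellProjection) else projection
    if len(pts) == 0:
        raise ValueError("no localizations to evaluate")
    xmin, xmax, ymin, ymax = region
    hx, hy = STANDARD_LENGTH / 2.0, STANDARD_WIDTH / 2.0
    if not (-hx <= xmin < xmax <= hx and -hy <= ymin < ymax <= hy):
        raise ValueError("region must lie within the standardized cell bounds")
    inside = (
        (pts["x_std"] >= xmin)
        & (pts["x_std"] <= xmax)
        & (pts["y_std"] >= ymin)
        & (pts["y_std"] <= ymax)
    )
    return float(inside.mean())
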