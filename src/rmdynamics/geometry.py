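"""Cell geometry: spherocylinder outline, containment and reflection.

Bacterial cells are modelled as 2-D spherocylinders (a rectangle of
length ``length - width`` capped by two semicircles of diameter
``width``), the standard projected outline of a rod-shaped bacterium.
The same shape, scaled down, serves as the optional nucleoid subregion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CellGeometry:
    """Pose and size of one segmented cell in the lab frame.

    Coordinates in um, angle in radians (orientation of the long axis).
    """

    cell_id: str
    cx: float
    cy: float
    angle: float
    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"cell {self.cell_id}: require length >= width > 0, "
                f"got length={self.length}, width={self.width}"
            )

    def to_cell_frame(self, xy: np.ndarray) -> np.ndarray:
        """Map lab-frame points (n, 2) into the cell frame (centered, axis on x)."""
        xy = np.asarray(xy, dtype=float)
        shifted = xy - np.array([self.cx, self.cy])
        c, s = np.cos(-self.angle), np.sin(-self.angle)
        rot = np.array([[c, -s], [s, c]])
        return shifted @ rot.T

    def to_lab_frame(self, xy: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_cell_frame`."""
        xy = np.asarray(xy, dtype=float)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return xy @ rot.T + np.array([self.cx, self.cy])


@dataclass(frozen=True)
class CellModelParams:
    """Shape parameters of the simulated cell and optional nucleoid.

    Defaults follow the standardized-cell convention of a 3x1 um rod; the
    nucleoid is a central 2.0x0.7 um subregion.  When
    ``confine_slow_states_to_nucleoid`` is set, molecules in the slowest
    diffusive state are seeded in -- and reflected at -- the nucleoid
    outline instead of the cell outline (MTase-like behaviour); otherwise
    all states use the full cell (REase-like).
    """

    length: float = 3.0
    width: float = 1.0
    nucleoid_length: float = 2.0
    nucleoid_width: float = 0.7
    confine_slow_states_to_nucleoid: bool = False

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("require length >= width > 0")
        if not (
            0 < self.nucleoid_length < self.length
            and 0 < self.nucleoid_width < self.width
        ):
            raise ValueError("nucleoid region must lie strictly inside the cell")


def _axis_foot(xy: np.ndarray, length: float, width: float) -> np.ndarray:
    """Closest point on the spherocylinder axis segment for each point."""
    a = (length - width) / 2.0
    foot = np.zeros_like(xy)
    foot[..., 0] = np.clip(xy[..., 0], -a, a)
    return foot


def contains(xy: np.ndarray, length: float, width: float, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask: points (cell frame) inside the spherocylinder outline."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    d = np.linalg.norm(xy - _axis_foot(xy, length, width), axis=-1)
    return d <= width / 2.0 + tol


def reflect_into(xy: np.ndarray, length: float, width: float, max_iter: int = 64) -> np.ndarray:
    """Specular reflection of points into the spherocylinder.

    A point at radial distance d > w/2 from the axis segment is mirrored
    across the wall to distance w - d; repeated until inside.  Points far
    outside (d > w) fall back to radial clamping onto the wall, which only
    occurs for pathological step sizes comparable to the cell width.
    """
    xy = np.array(np.atleast_2d(xy), dtype=float)
    r = width / 2.0
    for _ in range(max_iter):
        foot = _axis_foot(xy, length, width)
        delta = xy - foot
        d = np.linalg.norm(delta, axis=-1)
        out = d > r
        if not np.any(out):
            break
        far = out & (d > width)
        fix = out & ~far
        if np.any(fix):
            scale = (width - d[fix]) / d[fix]
            xy[fix] = foot[fix] + delta[fix] * scale[:, None]
        if np.any(far):
            scale = r / d[far]
            xy[far] = foot[far] + delta[far] * scale[:, None]
    return xy


def uniform_points(
    rng: np.random.Generator, n: int, length: float, width: float
) -> np.ndarray:
    """Sample n points uniformly inside the spherocylinder by rejection."""
    pts = np.empty((n, 2))
    filled = 0
    half_l, half_w = length / 2.0, width / 2.0
    while filled < n:
        m = max(2 * (n - filled), 16)
        cand = rng.uniform([-half_l, -half_w], [half_l, half_w], size=(m, 2))
        good = cand[contains(cand, length, width)]
        take = min(len(good), n - filled)
        pts[filled : filled + take] = good[:take]
        filled += take
    return pts
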