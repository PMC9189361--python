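"""Tumor shape-regularity (F-value) morphometry and caliper volume.

The F-value compares the tumor outline with its minimum enclosing circle:
F = (A_selected - A_tumor) / A_selected, where A_tumor is the foreground
pixel count and A_selected the area of the smallest circle enclosing the
tumor boundary.  F is 0 for a perfect circle and grows as the outline
departs from circularity (an ellipse with axis ratio b/a has F = 1 - b/a).
The long axis is the maximum Feret diameter.  Caliper volume follows the
standard xenograft formula V = width^2 * length / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "TumorMask",
    "ShapeMetrics",
    "TumorMeasurement",
    "long_axis",
    "minimum_enclosing_circle",
    "shape_metrics",
    "tumor_volume",
    "regularity_report",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class TumorMask:
    """Binary tumor outline mask (row-major, origin top-left).

    The foreground must be a single 4-connected component; interior holes
    are tolerated on input and filled before measurement (gross tumor
    outlines are solid).
    """

    mask: np.ndarray
    pixel_scale: float | None = None  # mm per pixel, informational

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask has no foreground")
        _, n = ndimage.label(self.mask, structure=_CROSS)
        if n != 1:
            raise ValueError(f"mask must have exactly one 4-connected component, found {n}")

    @property
    def filled(self) -> np.ndarray:
        return ndimage.binary_fill_holes(self.mask)


def _boundary_points(filled: np.ndarray) -> np.ndarray:
    """Centers (row, col) of boundary pixels of a hole-free mask."""
    inner = ndimage.binary_erosion(filled, structure=_CROSS, border_value=0)
    boundary = filled & ~inner
    return np.argwhere(boundary).astype(float)


def _hull_points(points: np.ndarray) -> np.ndarray:
    if len(points) < 3:
        return points
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear
        return points
    return points[hull.vertices]


def long_axis(mask: TumorMask) -> float:
    """Maximum Feret diameter: largest distance between boundary pixel
    centers, computed over convex-hull vertices."""
    pts = _hull_points(_boundary_points(mask.filled))
    if len(pts) == 1:
        return 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    return float(np.sqrt(d2.max()))


# -- minimum enclosing circle (Welzl, move-to-front) ------------------------

def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2
    return c, float(np.linalg.norm(p - q) / 2)


def _circle_three(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, float] | None:
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - p))


def _in_circle(pt: np.ndarray, center: np.ndarray, radius: float) -> bool:
    return np.linalg.norm(pt - center) <= radius * (1 + 1e-10) + 1e-10


def minimum_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest circle enclosing the given 2-D points (Welzl's algorithm
    with a deterministic seeded shuffle; exact up to float tolerance)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    pts = pts[np.random.default_rng(0).permutation(len(pts))]

    center, radius = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        if _in_circle(pts[i], center, radius):
            continue
        center, radius = pts[i].copy(), 0.0
        for j in range(i):
            if _in_circle(pts[j], center, radius):
                continue
            center, radius = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(pts[k], center, radius):
                    continue
                circ = _circle_three(pts[i], pts[j], pts[k])
                if circ is not None:
                    center, radius = circ
    return center, radius


def _trace_perimeter(filled: np.ndarray) -> float:
    """Outer 8-connected contour chain length; diagonal steps weigh sqrt(2).

    Moore-neighbor tracing from the first foreground pixel in scan order,
    stopping on return to the start pixel from the start direction.
    """
    if filled.sum() == 1:
        return 0.0
    padded = np.pad(filled, 1)
    start = tuple(np.argwhere(padded)[0])
    # neighbor order: clockwise starting from West
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    lengths = [1.0, math.sqrt(2), 1.0, math.sqrt(2), 1.0, math.sqrt(2), 1.0, math.sqrt(2)]
    perimeter = 0.0
    current = start
    backtrack = 0  # came from West
    first_move: tuple | None = None
    while True:
        found = None
        for step in range(8):
            k = (backtrack + step) % 8
            nr, nc = current[0] + nbrs[k][0], current[1] + nbrs[k][1]
            if padded[nr, nc]:
                found = (k, (nr, nc))
                break
        if found is None:  # isolated pixel (not reachable: handled above)
            return 0.0
        k, nxt = found
        perimeter += lengths[k]
        move = (current, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            return perimeter - lengths[k]
        current = nxt
        backtrack = (k + 5) % 8  # rotate: one past the reverse direction


@dataclass(frozen=True)
class ShapeMetrics:
    area_tumor: float  # px^2 (foreground pixel count)
    perimeter: float  # px
    long_axis: float  # px
    area_selected: float  # px^2 (minimum enclosing circle)
    f_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_value < 1.0):
            raise ValueError("F must lie in [0, 1)")


def shape_metrics(mask: TumorMask) -> ShapeMetrics:
    """Area, perimeter, Feret long axis, enclosing-circle area and F-value.

    The enclosing circle is fitted to boundary pixel centers and its radius
    inflated by half a pixel so that it encloses the pixel squares, keeping
    A_selected >= A_tumor for rasterized shapes.
    """
    filled = mask.filled
    area = float(filled.sum())
    pts = _boundary_points(filled)
    hull = _hull_points(pts)
    _, radius = minimum_enclosing_circle(hull)
    radius += 0.5  # pixel extent
    area_selected = math.pi * radius**2
    f = (area_selected - area) / area_selected
    if len(hull) == 1:
        axis = 0.0
    else:
        diff = hull[:, None, :] - hull[None, :, :]
        axis = float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).max()))
    return ShapeMetrics(
        area_tumor=area,
        perimeter=_trace_perimeter(filled),
        long_axis=axis,
        area_selected=area_selected,
        f_value=f,
    )


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement of one xenograft tumor."""

    width_mm: float
    length_mm: float
    weight_g: float | None = None

    def __post_init__(self) -> None:
        tumor_volume(self.width_mm, self.length_mm)  # validates

    @property
    def volume_mm3(self) -> float:
        return tumor_volume(self.width_mm, self.length_mm)


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Caliper volume: width^2 * length / 2 (width is the short axis)."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("width and length must be positive")
    if width_mm > length_mm:
        raise ValueError("width must not exceed length")
    return width_mm * width_mm * length_mm / 2


def regularity_report(
    masks_by_group: Mapping[str, Sequence[TumorMask | None]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tumor F table and per-group summary.

    ``None`` entries mark animals that grew no tumor (N.A.); they keep their
    row in the table and are excluded from the summary.  Returns
    ``(per_tumor, summary)`` where per_tumor has one row per tumor number
    and one column per group, and summary has mean, sd and n per group.
    """
    if not masks_by_group:
        raise ValueError("no groups given")
    columns: dict[str, list[float]] = {}
    for group, masks in masks_by_group.items():
        if len(masks) == 0:
            raise ValueError(f"group {group!r} is empty")
        columns[group] = [math.nan if m is None else shape_metrics(m).f_value for m in masks]
    n_rows = max(len(v) for v in columns.values())
    table = pd.DataFrame(
        {g: v + [math.nan] * (n_rows - len(v)) for g, v in columns.items()},
        index=pd.RangeIndex(1, n_rows + 1, name="tumor_no"),
    )
    summary = pd.DataFrame(
        {
            "mean_f": table.mean(),
            "sd_f": table.std(ddof=1),
            "n": table.notna().sum(),
        }
    )
    summary.index.name = "group"
    return table, summary
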