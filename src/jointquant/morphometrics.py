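"""Signed interzone intervals, element lengths and cell-type proportion ratios.

The interzone interval is the signed distance between the facing edges of
the two cartilage elements (Meckel's cartilage medially/laterally against
the palatoquadrate) along a user-supplied oriented measurement axis, with
the MC edge at the lower coordinate by convention: positive values are a
gap, zero is abutment, and negative values mean the elements overlap.
Lengths of measurement polylines (jaw length, element length, cell-type
segment lengths) are plain Euclidean path lengths in µm, and cell-type
composition is reported as the ratio of a segment length to the full
element length.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .errors import DomainError, GeometryError

__all__ = [
    "JointMeasurement",
    "Polyline",
    "interzone_interval",
    "polyline_length",
    "celltype_ratio",
    "joint_outline",
    "load_landmarks",
]


@dataclass(frozen=True)
class JointMeasurement:
    """Signed medial and lateral interzone intervals for one joint (µm)."""

    sample_id: str
    condition: str
    medial_interval_um: float
    lateral_interval_um: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.medial_interval_um) and np.isfinite(self.lateral_interval_um)):
            raise DomainError("intervals must be finite")


@dataclass(frozen=True)
class Polyline:
    """An ordered 2D measurement path in µm (>= 1 point)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 1 or pts.shape[1] != 2 or not np.all(np.isfinite(pts)):
            raise DomainError("polyline needs >= 1 finite (x, y) point")
        object.__setattr__(self, "points", pts)


def interzone_interval(mc_edge_um: float, pq_edge_um: float) -> float:
    """Signed interval pq_edge − mc_edge along the oriented measurement axis.

    Positive = gap between the elements, 0 = abutment, negative = overlap.
    """
    return float(pq_edge_um) - float(mc_edge_um)


def polyline_length(path: Polyline | np.ndarray) -> float:
    """Euclidean length of a measurement polyline (µm); a single point is 0."""
    pts = path.points if isinstance(path, Polyline) else Polyline(path).points
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def celltype_ratio(subtype_length_um: float, total_length_um: float) -> float:
    """Proportion of the element length occupied by one cell type, in [0, 1]."""
    if total_length_um <= 0:
        raise DomainError(f"total length must be > 0, got {total_length_um}")
    if subtype_length_um < 0 or subtype_length_um > total_length_um:
        raise DomainError(
            f"subtype length {subtype_length_um} outside [0, {total_length_um}]"
        )
    return float(subtype_length_um) / float(total_length_um)


def joint_outline(mask: np.ndarray, pixel_size: tuple[float, float] = (1.0, 1.0)) -> list[np.ndarray]:
    """Closed boundary polygons of the connected regions of a 2D mask.

    Each True pixel contributes its full (dy × dx) footprint, so the
    shoelace area of each returned polygon equals the region's pixel count
    times the pixel area exactly.  Polygons are (n, 2) arrays of (x, y) µm
    vertices (closed: first vertex repeated last), one per 8-connected
    region, for overlay export.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise GeometryError("mask must be 2D")
    if not m.any():
        raise GeometryError("empty mask has no outline")
    dy, dx = pixel_size
    # 4-connectivity so every labelled region unions into one valid polygon
    labels, n = ndimage.label(m)
    outlines = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        cells = [box(c * dx, r * dy, (c + 1) * dx, (r + 1) * dy) for r, c in zip(rows, cols)]
        region = unary_union(cells)
        parts = region.geoms if region.geom_type == "MultiPolygon" else [region]
        outlines.extend(np.asarray(p.exterior.coords) for p in parts)
    return outlines


def load_landmarks(path: str | Path) -> dict:
    """Read a landmark JSON: measurement axis endpoints and edge coordinates.

    Expected keys: ``axis`` ({"p0": [x, y], "p1": [x, y]}), ``mc_edge_um``,
    ``pq_edge_um``, ``side`` ("medial" | "lateral").
    """
    data = json.loads(Path(path).read_text())
    for key in ("mc_edge_um", "pq_edge_um", "side"):
        if key not in data:
            raise DomainError(f"landmark file {path} missing {key!r}")
    if data["side"] not in ("medial", "lateral"):
        raise DomainError(f"side must be 'medial' or 'lateral', got {data['side']!r}")
    return data
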