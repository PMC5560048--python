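"""Calibrated multi-channel 3D stacks: I/O, projections and polygon ROI masks.

Conventions owned by this module
--------------------------------
* Voxel indices are 0-based with axis order ``(z, channel, y, x)``.
* World coordinates are in µm; the world position of voxel index
  ``(iz, iy, ix)`` is ``origin + index * voxel_size`` per axis (the index
  maps to the voxel *center*).
* Stacks are stored as plain multi-page TIFF, page order z-major then
  channel, with a mandatory JSON sidecar carrying the calibration::

      {"voxel_size_um": [dz, dy, dx],
       "channel_names": ["GFP", "mCherry"],
       "origin_um": [x, y, z]}

* Polygon ROIs are drawn in world (x, y) µm on a projection and extruded
  through z (optionally restricted to an inclusive slice interval).
  Membership uses the even-odd rule on voxel centers, with points on the
  polygon boundary counting as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import CalibrationError, FormatError, GeometryError

__all__ = [
    "ImageStack",
    "PolygonROI",
    "read_stack",
    "write_stack",
    "max_intensity_projection",
    "roi_mask",
    "points_in_polygon",
]


@dataclass(frozen=True)
class ImageStack:
    """A calibrated multi-channel 3D intensity grid.

    Parameters
    ----------
    voxels
        Array of shape ``(z, channel, y, x)`` with finite, non-negative
        intensities in arbitrary units.
    voxel_size
        ``(dz, dy, dx)`` in µm, each strictly positive.
    channel_names
        Ordered channel labels, one per channel axis entry.
    origin
        World coordinate ``(x, y, z)`` in µm of voxel index (0, 0, 0).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 4:
            raise FormatError(f"voxels must be 4D (z, channel, y, x); got ndim={vox.ndim}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise CalibrationError(f"voxel_size must be three strictly positive µm values, got {self.voxel_size}")
        if len(self.channel_names) != vox.shape[1]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for {vox.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel names must be unique")
        if not np.all(np.isfinite(vox)):
            raise FormatError("intensities must be finite")
        if vox.size and vox.min() < 0:
            raise FormatError("intensities must be non-negative")

    # -- geometry ----------------------------------------------------------
    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        z, _, y, x = self.voxels.shape
        return z, y, x

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; stack has {list(self.channel_names)}"
            ) from None

    def channel(self, channel: str) -> np.ndarray:
        """Return the (z, y, x) intensity grid of one channel."""
        return self.voxels[:, self.channel_index(channel)]

    def world_coords(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Map 0-based (z, y, x) voxel indices to world (x, y, z) µm points."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
        dz, dy, dx = self.voxel_size
        ox, oy, oz = self.origin
        out = np.empty_like(idx)
        out[:, 0] = ox + idx[:, 2] * dx
        out[:, 1] = oy + idx[:, 1] * dy
        out[:, 2] = oz + idx[:, 0] * dz
        return out


@dataclass(frozen=True)
class PolygonROI:
    """A simple polygon in world (x, y) µm, extruded through a z interval.

    ``z_range`` is either the string ``"all"`` or an inclusive 0-based slice
    index interval ``(z0, z1)``.
    """

    vertices: np.ndarray
    z_range: tuple[int, int] | str = "all"
    label: str = ""

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise GeometryError("polygon needs >= 3 (x, y) vertices")
        poly = _ShapelyPolygon(verts)
        if not poly.is_simple or poly.area == 0:
            raise GeometryError("polygon must be simple with non-zero area")
        object.__setattr__(self, "vertices", verts)
        if self.z_range != "all":
            z0, z1 = (int(v) for v in self.z_range)
            if z1 < z0:
                raise GeometryError(f"z_range upper bound below lower: ({z0}, {z1})")
            object.__setattr__(self, "z_range", (z0, z1))

    def z_slice_indices(self, n_z: int) -> np.ndarray:
        if self.z_range == "all":
            return np.arange(n_z)
        z0, z1 = self.z_range
        if z0 < 0 or z1 >= n_z:
            raise GeometryError(f"z_range {self.z_range} outside stack depth {n_z}")
        return np.arange(z0, z1 + 1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PolygonROI":
        """Load an ROI from ``{"vertices_um": [[x, y], ...], "z_range": [z0, z1]|"all"}``."""
        data = json.loads(Path(path).read_text())
        z_range = data.get("z_range", "all")
        if z_range != "all":
            z_range = tuple(z_range)
        return cls(
            vertices=np.asarray(data["vertices_um"], dtype=float),
            z_range=z_range,
            label=data.get("label", Path(path).stem),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, meta_path: str | Path) -> ImageStack:
    """Read a multi-page TIFF plus its JSON calibration sidecar.

    Pages are interpreted z-major then channel: page ``k`` holds slice
    ``k // n_channels`` of channel ``k % n_channels``.  The page count must
    be an exact multiple of the sidecar's channel count.
    """
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise CalibrationError(f"calibration sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    try:
        voxel_size = tuple(float(v) for v in meta["voxel_size_um"])
        channel_names = tuple(str(c) for c in meta["channel_names"])
    except KeyError as exc:
        raise CalibrationError(f"sidecar {meta_path} missing key {exc}") from None
    if any(v <= 0 for v in voxel_size):
        raise CalibrationError(f"non-positive voxel size in sidecar: {voxel_size}")
    origin = tuple(float(v) for v in meta.get("origin_um", (0.0, 0.0, 0.0)))

    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    n_channels = len(channel_names)
    if pages.shape[0] % n_channels != 0:
        raise FormatError(
            f"{pages.shape[0]} TIFF pages not divisible by {n_channels} channels"
        )
    declared_z = meta.get("n_z")
    n_z = pages.shape[0] // n_channels
    if declared_z is not None and int(declared_z) != n_z:
        raise FormatError(
            f"sidecar declares n_z={declared_z} but file holds {n_z} slices"
        )
    voxels = pages.reshape(n_z, n_channels, *pages.shape[1:])
    return ImageStack(voxels=voxels, voxel_size=voxel_size, channel_names=channel_names, origin=origin)


def write_stack(stack: ImageStack, path: str | Path, meta_path: str | Path) -> None:
    """Write a stack as plain multi-page TIFF (z-major then channel) + sidecar."""
    z, c, y, x = stack.voxels.shape
    tifffile.imwrite(str(path), stack.voxels.reshape(z * c, y, x), photometric="minisblack")
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "channel_names": list(stack.channel_names),
        "origin_um": list(stack.origin),
        "n_z": z,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Projections and masks
# ---------------------------------------------------------------------------

def max_intensity_projection(stack: ImageStack, channel: str) -> np.ndarray:
    """Maximum intensity projection of one channel along z → (y, x) image."""
    return stack.channel(channel).max(axis=0)


def points_in_polygon(points_xy: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd polygon membership with boundary-inclusive semantics.

    A point is inside iff a ray to +x crosses the edges an odd number of
    times, or the point lies exactly on an edge (boundary counts as inside).
    Vectorised over points; edges are processed one at a time.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    verts = np.asarray(vertices, dtype=float)
    n = len(verts)
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # exact on-segment test: collinear and within the bounding box
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (np.minimum(x1, x2) <= px) & (px <= np.maximum(x1, x2))
            & (np.minimum(y1, y2) <= py) & (py <= np.maximum(y1, y2))
        )
        on_edge |= (cross == 0) & within
        # even-odd ray cast: half-open in y so shared vertices count once
        straddles = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at_y = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
        inside ^= straddles & (px < np.where(straddles, x_at_y, np.inf))
    return inside | on_edge


def roi_mask(roi: PolygonROI, stack: ImageStack) -> np.ndarray:
    """Boolean (z, y, x) mask of voxels whose center lies in the extruded ROI."""
    n_z, n_y, n_x = stack.shape_zyx
    dz, dy, dx = stack.voxel_size
    ox, oy, _ = stack.origin
    xs = ox + np.arange(n_x) * dx
    ys = oy + np.arange(n_y) * dy
    gx, gy = np.meshgrid(xs, ys)  # (y, x) grids
    plane = points_in_polygon(np.column_stack([gx.ravel(), gy.ravel()]), roi.vertices)
    plane = plane.reshape(n_y, n_x)
    mask = np.zeros((n_z, n_y, n_x), dtype=bool)
    mask[roi.z_slice_indices(n_z)] = plane
    return mask
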