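"""Synthetic two-channel confocal stacks of a larval jaw joint, with ground truth.

The generator emulates the imaging this package quantifies: two rod-like
cartilage elements (Meckel's cartilage and the palatoquadrate) rendered in
an mCherry channel, separated by a configurable interzone gap (negative =
overlap); nuclear-localised Wnt-reporter signal as Gaussian blobs clustered
around the joint in a GFP channel; and, for tracking experiments, a small
photoconverted population (10-12 cells by default, matching the
photoconversion protocol being emulated) whose red Kaede label is inherited
by daughter cells.  Between the two timepoints of a tracking pair each cell
divides with a condition-dependent probability and migrates by a
condition-dependent displacement, and every planted event is recorded in
the returned truth object.

Noise is shot noise (Poisson resampling of the clean signal) plus additive
Gaussian read noise, after which intensities are quantised to uint16 so
that stacks survive I/O round-trips bit-exactly.  A fixed seed gives
bit-identical voxel data.

Condition presets scale division and migration (and, for cohort
simulation, reporter volume) downward for the immobilised and Wnt16
loss-of-function conditions relative to control.  The preset effect sizes
are module defaults chosen to be detectable at realistic sample sizes
(n ≈ 10-30 joints per group); they are synthetic, not estimates of any
measured biological effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .cell_census import CountWindow, count_in_window
from .errors import DomainError
from .image_io import ImageStack, PolygonROI

__all__ = [
    "SceneParams",
    "SyntheticTruth",
    "CONDITION_PRESETS",
    "generate_joint_stack",
    "generate_tracking_pair",
    "generate_cohort",
    "joint_roi",
]


def joint_roi(
    params: "SceneParams",
    half_width_um: float = 25.0,
    z_range: tuple[int, int] | str = "all",
    label: str = "joint",
) -> PolygonROI:
    """Square ROI centered on the scene's joint, analogous to the
    user-drawn region on a maximum-intensity projection."""
    jx, jy, _ = params.joint_center_um
    h = half_width_um
    return PolygonROI(
        vertices=[[jx - h, jy - h], [jx + h, jy - h], [jx + h, jy + h], [jx - h, jy + h]],
        z_range=z_range,
        label=label,
    )


@dataclass(frozen=True)
class ConditionPreset:
    """Multiplicative scalings a condition applies to the control scene."""

    division_factor: float
    migration_factor: float
    gfp_volume_factor: float
    gfp_count_factor: float
    interval_shift_um: float


CONDITION_PRESETS: dict[str, ConditionPreset] = {
    # control: the unscaled scene
    "control": ConditionPreset(1.0, 1.0, 1.0, 1.0, 0.0),
    # immobilisation suppresses division/migration and reporter activity
    "immobilised": ConditionPreset(0.2, 0.2, 0.6, 0.6, -2.0),
    # Wnt16 loss: same cell-behaviour suppression, joint elements overlap
    "wnt16_loss": ConditionPreset(0.2, 0.25, 0.8, 0.8, -6.0),
}


@dataclass(frozen=True)
class SceneParams:
    """Full parameterisation of one synthetic joint scene.

    Geometry is in µm in the stack's world frame (origin at voxel (0,0,0)).
    The two cartilage rods run along x and meet at the joint at the field
    center, separated by ``interzone_gap_um`` (negative = overlap).  The
    seed is mandatory: every stochastic choice in the scene flows from it.
    """

    seed: int
    shape_vox: tuple[int, int, int] = (24, 112, 160)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (1.0, 0.8, 0.8)  # (dz, dy, dx) µm
    rod_radius_um: float = 8.0
    interzone_gap_um: float = 4.0
    n_gfp_nuclei: int = 15
    nucleus_radius_um: float = 2.5
    cluster_sd_um: float = 8.0  # spread of reporter nuclei around the joint
    min_nucleus_separation_um: Optional[float] = None  # None: free clustering
    n_photoconverted: Optional[int] = None  # None: drawn uniform from 10-12
    red_spacing_um: float = 15.0  # photoconverted-batch grid pitch (resolvable)
    red_jitter_um: float = 0.8
    daughter_separation_um: float = 12.0  # parent-daughter offset at t1
    division_prob: float = 0.5  # per cell per 3->5 dpf interval (control)
    migration_scale_um: float = 6.0  # displacement scale (control)
    gfp_amplitude: float = 1000.0
    mcherry_amplitude: float = 800.0
    red_amplitude: float = 1000.0
    background: float = 100.0
    gaussian_noise_sd: float = 20.0
    poisson_gain: float = 1.0  # photons per intensity unit; 0 disables shot noise

    def __post_init__(self) -> None:
        if self.rod_radius_um <= 0 or self.nucleus_radius_um <= 0:
            raise DomainError("radii must be > 0")
        if not 0.0 <= self.division_prob <= 1.0:
            raise DomainError("division_prob must be in [0, 1]")
        if self.migration_scale_um < 0 or self.gaussian_noise_sd < 0:
            raise DomainError("scales must be >= 0")
        if self.seed is None:
            raise DomainError("seed is mandatory")
        fz, fy, fx = self.field_um
        if 2 * self.rod_radius_um >= min(fy, fz):
            raise DomainError("rod diameter exceeds field; geometry outside stack")
        if abs(self.interzone_gap_um) >= fx / 2:
            raise DomainError("interzone gap exceeds field; geometry outside stack")

    @property
    def field_um(self) -> tuple[float, float, float]:
        """Physical field extent (z, y, x) in µm."""
        return tuple(n * s for n, s in zip(self.shape_vox, self.voxel_size))

    @property
    def joint_center_um(self) -> tuple[float, float, float]:
        """(x, y, z) of the joint at the field center."""
        fz, fy, fx = self.field_um
        return fx / 2, fy / 2, fz / 2

    @property
    def blob_sigma_um(self) -> float:
        """Gaussian σ of a rendered nucleus.

        Nuclei are rendered with σ equal to the nominal radius, so the
        half-maximum isocontour sits at ≈1.18σ — a nucleus of nominal
        radius 2.5 µm appears ~6 µm across at half maximum, matching how
        nuclear reporter signal looks at confocal resolution.
        """
        return self.nucleus_radius_um


@dataclass
class SyntheticTruth:
    """Everything planted in a scene, for validating pipeline output.

    ``events`` (tracking pairs only) lists one dict per division with the
    parent cell index; migration displacements are per-cell (x, y, z) µm.
    """

    params: SceneParams
    condition: str = "control"
    nuclei_centers_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    nucleus_sigma_um: float = 0.0
    interzone_gap_um: float = 0.0
    red_t0_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    red_t1_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    events: list = field(default_factory=list)
    migrations_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    # -- truth-side readouts ----------------------------------------------
    @property
    def true_count_t0(self) -> int:
        return len(self.red_t0_um)

    @property
    def true_count_t1(self) -> int:
        return len(self.red_t1_um)

    @property
    def true_pct_count_increase(self) -> float:
        return 100.0 * (self.true_count_t1 - self.true_count_t0) / self.true_count_t0

    def count_nuclei_in_window(self, window: CountWindow) -> int:
        """Planted-truth analogue of the pipeline's windowed count."""
        return count_in_window(self.nuclei_centers_um, window)

    def noiseless_gfp(self) -> np.ndarray:
        """Clean (z, y, x) GFP render: background + planted blobs, no noise."""
        clean = np.full(self.params.shape_vox, self.params.background)
        for c in self.nuclei_centers_um:
            _add_blob(clean, c, self.nucleus_sigma_um, self.params.gfp_amplitude, self.params.voxel_size)
        return clean

    def suprathreshold_hull_volume(self, threshold: float) -> float:
        """Convex-hull volume (µm³) of noiseless GFP voxel centers above a level.

        Independent ground-truth route for the volume pipeline: rendered
        without noise and measured with a convex hull, not an alpha shape.
        """
        clean = self.noiseless_gfp()
        idx = np.argwhere(clean > threshold)
        if len(idx) < 4:
            return 0.0
        dz, dy, dx = self.params.voxel_size
        pts = idx[:, ::-1] * np.array([dx, dy, dz])  # (x, y, z) µm
        return float(ConvexHull(pts).volume)

    def to_json(self, path: str | Path) -> None:
        data = {
            "seed": self.params.seed,
            "condition": self.condition,
            "interzone_gap_um": self.interzone_gap_um,
            "nucleus_sigma_um": self.nucleus_sigma_um,
            "nuclei_centers_um": np.asarray(self.nuclei_centers_um).tolist(),
            "red_t0_um": np.asarray(self.red_t0_um).tolist(),
            "red_t1_um": np.asarray(self.red_t1_um).tolist(),
            "events": self.events,
            "migrations_um": np.asarray(self.migrations_um).tolist(),
        }
        Path(path).write_text(json.dumps(data, indent=1))


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _grid_axes(params: SceneParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = params.shape_vox
    dz, dy, dx = params.voxel_size
    return np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx


def _add_blob(grid: np.ndarray, center_xyz_um, sigma_um: float, amplitude: float, voxel_size) -> None:
    """Add one isotropic Gaussian blob in place, on a ±4σ local patch."""
    dz, dy, dx = voxel_size
    cx, cy, cz = center_xyz_um
    nz, ny, nx = grid.shape
    iz = int(round(cz / dz)); iy = int(round(cy / dy)); ix = int(round(cx / dx))
    rz = int(np.ceil(4 * sigma_um / dz)); ry = int(np.ceil(4 * sigma_um / dy)); rx = int(np.ceil(4 * sigma_um / dx))
    z0, z1 = max(0, iz - rz), min(nz, iz + rz + 1)
    y0, y1 = max(0, iy - ry), min(ny, iy + ry + 1)
    x0, x1 = max(0, ix - rx), min(nx, ix + rx + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zs = (np.arange(z0, z1) * dz - cz) ** 2
    ys = (np.arange(y0, y1) * dy - cy) ** 2
    xs = (np.arange(x0, x1) * dx - cx) ** 2
    d2 = zs[:, None, None] + ys[None, :, None] + xs[None, None, :]
    grid[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2 * sigma_um**2))


def _render_rods(params: SceneParams) -> np.ndarray:
    """Clean mCherry channel: two x-aligned rods meeting at the joint."""
    zs, ys, xs = _grid_axes(params)
    jx, jy, jz = params.joint_center_um
    _, _, fx = params.field_um
    half_gap = params.interzone_gap_um / 2.0
    margin = 6.0
    segments = [
        (margin, jx - half_gap),  # Meckel's cartilage
        (jx + half_gap, fx - margin),  # palatoquadrate
    ]
    grid = np.zeros(params.shape_vox)
    dy2 = (ys - jy) ** 2
    dz2 = (zs - jz) ** 2
    for x_lo, x_hi in segments:
        if x_hi <= x_lo:
            continue
        dx2 = np.clip(x_lo - xs, 0, None) ** 2 + np.clip(xs - x_hi, 0, None) ** 2
        d2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        grid[d2 <= params.rod_radius_um**2] = params.mcherry_amplitude
    return grid


def _apply_noise(clean: np.ndarray, rng: np.random.Generator, params: SceneParams) -> np.ndarray:
    """Shot noise + Gaussian read noise, quantised to uint16."""
    if params.poisson_gain > 0:
        signal = rng.poisson(clean * params.poisson_gain) / params.poisson_gain
    else:
        signal = clean
    noisy = signal + rng.normal(0.0, params.gaussian_noise_sd, clean.shape)
    return np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)


def _place_reporter_nuclei(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Cluster reporter-positive nuclei around the joint, inside the field."""
    jx, jy, jz = params.joint_center_um
    fz, fy, fx = params.field_um
    sd = params.cluster_sd_um
    pad = 2 * params.nucleus_radius_um
    min_sep = params.min_nucleus_separation_um
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < params.n_gfp_nuclei:
        c = np.array(
            [
                np.clip(rng.normal(jx, sd), pad, fx - pad),
                np.clip(rng.normal(jy, sd), pad, fy - pad),
                np.clip(rng.normal(jz, sd / 3), pad, fz - pad),
            ]
        )
        attempts += 1
        if min_sep is not None and centers and min(
            np.linalg.norm(c - np.asarray(centers), axis=1).min(), np.inf
        ) < min_sep:
            if attempts > 1000 * params.n_gfp_nuclei:
                raise DomainError("cannot satisfy min_nucleus_separation_um in this field")
            continue
        centers.append(c)
    return np.asarray(centers)


def generate_joint_stack(params: SceneParams) -> tuple[ImageStack, SyntheticTruth]:
    """Render one two-channel (GFP + mCherry) joint scene with ground truth.

    Identical parameters and seed give bit-identical voxel data.
    """
    rng = np.random.default_rng(params.seed)
    truth = SyntheticTruth(
        params=params,
        interzone_gap_um=params.interzone_gap_um,
        nucleus_sigma_um=params.blob_sigma_um,
        nuclei_centers_um=_place_reporter_nuclei(params, rng),
    )
    gfp = truth.noiseless_gfp()
    mcherry = _render_rods(params) + params.background
    voxels = np.stack(
        [_apply_noise(gfp, rng, params), _apply_noise(mcherry, rng, params)], axis=1
    )
    stack = ImageStack(
        voxels=voxels,
        voxel_size=params.voxel_size,
        channel_names=("GFP", "mCherry"),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# tracking pairs
# ---------------------------------------------------------------------------

def _effective(params: SceneParams, condition: str) -> tuple[float, float]:
    try:
        preset = CONDITION_PRESETS[condition]
    except KeyError:
        raise DomainError(f"unknown condition {condition!r}; choose from {sorted(CONDITION_PRESETS)}") from None
    return (
        min(1.0, params.division_prob * preset.division_factor),
        params.migration_scale_um * preset.migration_factor,
    )


def generate_tracking_pair(
    params: SceneParams,
    condition: str = "control",
    render: bool = True,
) -> tuple[Optional[ImageStack], Optional[ImageStack], SyntheticTruth]:
    """Paired-timepoint red-Kaede scene: photoconversion, division, migration.

    At t0 a batch of 10-12 medially located cells carries the red label; by
    t1 each has divided with the condition's division probability (daughters
    inherit the label) and migrated, predominantly along the
    anterior-posterior (x) axis.  With ``render=False`` only the ground
    truth is produced (stacks are None) — the event draws are identical to
    the rendered path, so truth-level simulation is exact and fast.
    """
    rng = np.random.default_rng(params.seed)
    p_div, mig = _effective(params, condition)
    n0 = params.n_photoconverted if params.n_photoconverted is not None else int(rng.integers(10, 13))
    if n0 < 1:
        raise DomainError("need at least one photoconverted cell")

    jx, jy, jz = params.joint_center_um
    # medially located batch close to the retroarticular process, laid out
    # on a jittered grid at resolvable spacing so automated counting can
    # separate the cells (the real batch is contiguous and was counted by eye)
    anchor = np.array([jx, jy + 0.6 * params.rod_radius_um, jz])
    per_row = 6
    idx = np.arange(n0)
    row, col = np.divmod(idx, per_row)
    s = params.red_spacing_um
    offsets = np.column_stack(
        [(col - (per_row - 1) / 2) * s, (row - 0.5) * s, np.zeros(n0)]
    )
    t0 = anchor + offsets + rng.normal(0, params.red_jitter_um, size=(n0, 3))

    divides = rng.random(n0) < p_div
    migrations = rng.normal(0, [mig, mig / 2, mig / 4], size=(n0, 3))
    moved = t0 + migrations
    daughters = []
    events = []
    sep = params.daughter_separation_um
    batch_y = moved[:, 1].mean()
    for i in np.flatnonzero(divides):
        # daughters placed outward of the batch (away from its y midline) so
        # they stay resolvable from the other cells when migration is small
        outward = 1.0 if moved[i, 1] >= batch_y else -1.0
        daughters.append(moved[i] + np.array([0.0, outward * sep, 0.0]))
        events.append({"parent": int(i), "type": "division"})
    t1 = np.vstack([moved] + [np.asarray(daughters)]) if daughters else moved

    fz, fy, fx = params.field_um
    pad = params.nucleus_radius_um
    t1 = np.clip(t1, [pad, pad, pad], [fx - pad, fy - pad, fz - pad])

    truth = SyntheticTruth(
        params=params,
        condition=condition,
        interzone_gap_um=params.interzone_gap_um,
        nucleus_sigma_um=params.blob_sigma_um,
        red_t0_um=t0,
        red_t1_um=t1,
        events=events,
        migrations_um=migrations,
    )
    if not render:
        return None, None, truth

    rods = _render_rods(params) + params.background

    def _render_red(centers: np.ndarray, noise_rng: np.random.Generator) -> ImageStack:
        red = np.full(params.shape_vox, params.background)
        for c in centers:
            _add_blob(red, c, params.blob_sigma_um, params.red_amplitude, params.voxel_size)
        voxels = np.stack(
            [_apply_noise(red, noise_rng, params), _apply_noise(rods, noise_rng, params)], axis=1
        )
        return ImageStack(voxels=voxels, voxel_size=params.voxel_size, channel_names=("redKaede", "mCherry"))

    return _render_red(t0, rng), _render_red(t1, rng), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

BASE_GFP_VOLUME_UM3 = 4000.0  # control-scale reporter-signal volume
VOLUME_CV = 0.3  # between-fish lognormal coefficient of variation
BASE_GFP_COUNT = 15.0
MIGRATION_AREA_GAIN = 0.32  # fractional area gain from spreading, control
MIGRATION_AREA_SD = 0.12
INTERVAL_SD_UM = 1.0


def generate_cohort(
    n_per_group: int,
    group_conditions: dict[str, str],
    seed: int,
    params: Optional[SceneParams] = None,
    mode: str = "fast",
) -> tuple[pd.DataFrame, list[SyntheticTruth]]:
    """Simulate a measurement table for several condition groups.

    ``group_conditions`` maps group label → condition preset name.  In
    "fast" mode per-fish measurements are drawn from the truth-level
    generative model (no voxel rendering): reporter volume is lognormal
    around the condition's scaled base volume, counts are Poisson, the
    tracking percentages come from the same binomial division and migration
    model the renderer plants, and intervals are normal around the
    condition's interzone gap.  In "render" mode each fish's tracking pair
    is additionally rendered and the division counts come from the rendered
    scene's truth; rendering is meant for small n — the columns mean the
    same thing in both modes.

    Returns a long-format table (sample_id, group, measure, value) plus the
    per-fish truth objects of any rendered scenes.
    """
    if n_per_group < 2:
        raise DomainError(f"n_per_group must be >= 2, got {n_per_group}")
    if mode not in ("fast", "render"):
        raise DomainError(f"mode must be 'fast' or 'render', got {mode!r}")
    base = params if params is not None else SceneParams(seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    truths: list[SyntheticTruth] = []
    sigma = np.sqrt(np.log(1 + VOLUME_CV**2))
    for group, condition in group_conditions.items():
        preset = CONDITION_PRESETS.get(condition)
        if preset is None:
            raise DomainError(f"unknown condition {condition!r} for group {group!r}")
        p_div, mig = _effective(base, condition)
        for i in range(n_per_group):
            sid = f"{group}_{i:03d}"
            volume = BASE_GFP_VOLUME_UM3 * preset.gfp_volume_factor * rng.lognormal(-0.5 * sigma**2, sigma)
            count = rng.poisson(BASE_GFP_COUNT * preset.gfp_count_factor)
            if mode == "render":
                fish_params = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
                _, _, truth = generate_tracking_pair(fish_params, condition, render=True)
                truths.append(truth)
                n0, n1 = truth.true_count_t0, truth.true_count_t1
            else:
                n0 = int(rng.integers(10, 13))
                n1 = n0 + rng.binomial(n0, p_div)
            pct_count = 100.0 * (n1 - n0) / n0
            spread = max(0.0, rng.normal(MIGRATION_AREA_GAIN * mig / base.migration_scale_um, MIGRATION_AREA_SD))
            pct_area = 100.0 * ((n1 / n0) * (1.0 + spread) - 1.0)
            interval = rng.normal(base.interzone_gap_um + preset.interval_shift_um, INTERVAL_SD_UM)
            for measure, value in (
                ("volume_um3", volume),
                ("gfp_count", count),
                ("pct_count_increase", pct_count),
                ("pct_area_increase", pct_area),
                ("medial_interval_um", interval),
            ):
                rows.append({"sample_id": sid, "group": group, "measure": measure, "value": float(value)})
    return pd.DataFrame(rows), truths
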