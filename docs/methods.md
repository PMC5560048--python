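# Methods

This note documents the models, conventions and numerical choices behind
`jointquant`, and what its synthetic validation does and does not show.

## Coordinate and data conventions

Stacks are `(z, channel, y, x)` grids of finite non-negative intensities
with strictly positive voxel sizes `(dz, dy, dx)` in µm. Voxel indices are
0-based; the world position of index `(iz, iy, ix)` is
`origin + index · voxel_size` per axis, i.e. indices map to voxel
*centers*. Files are plain multi-page TIFF (z-major, then channel) with a
mandatory JSON sidecar carrying `voxel_size_um`, `channel_names` and
`origin_um`; no OME parsing, no vendor formats, no registration between
timepoints. ROIs are simple polygons drawn in world (x, y) µm — the
workflow draws them on a maximum-intensity projection — and are extruded
through z, optionally restricted to an inclusive slice interval. Polygon
membership uses the even-odd rule on voxel centers with boundary points
counting as inside; membership is therefore invariant under vertex-order
reversal. The point-in-polygon test is implemented directly (exact
on-segment test plus half-open ray casting) because no dependency
guarantees exactly this boundary contract; shapely serves as the
independent oracle in the tests.

## Otsu thresholding

`otsu_threshold` histograms the input into 256 equal-width bins over the
observed [min, max] (the conventional 8-bit resolution) and returns the
smallest bin edge t maximising the between-class variance
σ²_B(t) = w₀w₁(µ₀−µ₁)², with class statistics computed over bin *left
edges* and foreground defined strictly as intensity > t. The left-edge
convention is exact for integer-valued data whose spacing divides the bin
width and makes the threshold scale-equivariant (scaling all intensities
scales the threshold; voxel membership is unchanged). Constant input has no
threshold and raises; inside `segment_object` a constant ROI instead yields
an empty, flagged object, since strict inequality leaves no foreground.
Whether to clip to 8 bits before thresholding is a genuine free choice in
this family of pipelines; the bin rule above is ours and is pinned by
tests against an exhaustive brute-force maximiser.

## Alpha-shape volumes

The alpha complex of a 3D point set is the subset of its Delaunay
tetrahedralisation whose tetrahedra have circumradius ≤ α; the reported
volume is the sum of retained tetrahedron volumes |det[b−a, c−a, d−a]|/6.
Only the tetrahedron criterion is applied (no per-face test): volume, the
only downstream quantity, depends only on retained tetrahedra. The
automatic radius is the *critical alpha* — the smallest α at which every
input point is a vertex of a retained tetrahedron — found by scanning the
sorted distinct circumradii; this mirrors the documented behaviour of
automatic radius selection in the common alpha-shape implementations.
Near-degenerate (flat) tetrahedra get circumradius +∞ and are never
retained; fewer than four points, or a collinear/coplanar set, raises a
geometry error. Delaunay ties on co-spherical inputs are broken by the
underlying triangulation's deterministic perturbation, so volumes on exact
grids are implementation-defined within the stated tolerances. For
α ≥ max circumradius the complex is the convex hull (cross-checked against
an independent hull-volume computation), volume is non-decreasing in α,
and rigid motions leave it unchanged to 1e-9 relative. One alpha is
computed per segmented object.

### Voxel-center bias

`segment_object` builds the shape on the *centers* of supra-threshold
voxels, mirroring the procedure it reimplements, so the measured volume
under-reports the continuous signal region by roughly half a voxel per
face. The bias is documented, not corrected: a radius-10 µm ball sampled at
1 µm pitch measures ≈ 3671 µm³ against the analytic 4189 µm³ (−12%), with
the convex hull of the same lattice (3955 µm³) as an upper bound; at
0.3 µm pitch the deficit shrinks to ≈ 3.6%. Tolerances in the validation
suite account for this bias at the pitches used.

## Segmentation and census

Within an ROI, the threshold is computed from ROI-interior intensities
only (two regions of one stack are thresholded independently, matching the
region-local workflow), and *all* supra-threshold voxels form a single
object without connected-component splitting. Objects with fewer than four
voxels, or with all voxel centers coplanar (e.g. confined to one slice),
carry volume 0 and are flagged rather than raising, so the pipeline is
total on thin or empty signals.

`detect_nuclei` (an automation of what was originally a manual count)
thresholds the whole channel by Otsu, labels 26-connected components,
discards components below `min_size_vox`, and returns world-µm centroids.
Nuclei closer than about the sum of their apparent radii merge into one
component and are counted once — a documented under-count. The counting
window is an axis-aligned rectangle (default 50 × 80 µm) centered on a
user-supplied anchor, inclusive on the low edge and exclusive on the high
edge so tiled windows never double-count; window orientation relative to
the joint, and anchor placement, are user inputs. Red-cell area is measured
in 2D on the maximum-intensity projection (supra-threshold pixel count ×
dy·dx), matching the projected-area convention; 3D red volume is out of
scope. Percentage increases 100·(v₁−v₀)/v₀ require a positive baseline and
may be negative.

## Morphometrics

Interval measurement follows the drawn-line convention: the caller supplies
scalar edge coordinates of the two elements along an oriented measurement
axis (MC at the lower coordinate), and the signed interval is
`pq_edge − mc_edge` — positive gap, zero abutment, negative overlap.
Automating the anatomical edge definition would invent anatomy, so it is
deliberately left to landmarks; `joint_outline` supports this by tracing
mask boundaries as polygons built from the union of pixel footprints,
which makes the polygon area equal the pixel count × pixel area exactly.
Polyline lengths are Euclidean path sums (rigid-invariant, additive under
concatenation); cell-type ratios are subtype/total lengths in [0, 1] with
domain errors outside it.

## Group statistics

Comparisons follow the two-branch convention: Shapiro–Wilk at α = 0.05 per
group decides normality (the criterion itself is a convention we state
explicitly, since the dispatch rule is usually left implicit); any failing
group — or any group too small to test (n < 3) — routes the whole
comparison to the non-parametric branch. Two groups: Student's pooled t or
Mann–Whitney U (asymptotic, tie-corrected, with an `mw_method` flag for the
exact variant); more: one-way ANOVA or Kruskal–Wallis. Summaries are mean ±
t₀.₉₇₅,ₙ₋₁·s/√n. Dispatch is deterministic given the data. No correction is
applied across separate comparisons — each call is one figure panel's test
— which is a documented limitation, not an oversight. Calibration is
verified by simulation: type-I error of both branches within [0.03, 0.07]
at α = 0.05 and CI coverage within [93%, 97%] at n = 10.

## Synthetic scenes

The generator emulates the imaging this pipeline targets, not the optics:
two x-aligned cartilage rods (radius 8 µm) meet at the field center with a
configurable interzone gap (negative = overlap) in an mCherry channel;
reporter-positive nuclei are isotropic Gaussian blobs (σ = nominal radius
2.5 µm, so the half-max footprint is ≈ 6 µm across) clustered around the
joint in a GFP channel; tracking scenes plant a photoconverted batch of
10–12 cells (drawn uniformly unless fixed) at the medial joint. Noise is
Poisson resampling of the clean signal (gain 1 photon per intensity unit)
plus Gaussian read noise (default sd 20 against a background of 100 and
blob amplitude 1000), then quantisation to uint16; a fixed seed gives
bit-identical stacks. The default noise level was chosen from the physics
of the pipeline itself: Otsu needs a genuinely bimodal ROI histogram, and
exact component counting requires the supra-threshold noise fraction to
stay below the 26-connectivity percolation regime — at several times this
noise level those conditions fail for any parameter setting, which is a
property of the method, not of the generator.

Tracking pairs draw one Bernoulli(division probability) event per cell
(daughters inherit the label and are placed 12 µm outward of the batch
midline) and one anisotropic Gaussian migration displacement per cell
(scale : scale/2 : scale/4 along x : y : z, x being anterior–posterior).
The batch is laid out on a jittered 15 µm grid so automated counting can
resolve cells that a human would separate by eye. With `render=False` the
same event draws are returned as truth without voxel rendering, which is
what the replicate-level calibration checks use. Condition presets scale
division and migration (control 1.0; immobilised 0.2; Wnt16 loss 0.2–0.25)
and, for cohort simulation, reporter volume and count (0.6–0.8) and the
interzone interval shift (−2 µm immobilised, −6 µm Wnt16 loss, the latter
driving the overlap phenotype). These effect sizes are module defaults
chosen to be detectable at realistic sample sizes (n ≈ 10–30 joints per
group); they are synthetic, not estimates of measured biological effects.
`generate_cohort`'s fast mode draws per-fish measurements from the same
truth-level model (lognormal volumes with CV 0.3 around a 4000 µm³ control
base, Poisson counts, binomial divisions, a migration-driven area gain of
0.32 ± 0.12 under control, normal intervals with sd 1 µm); its control
cohorts average a red-cell area increase near +100%, the scale of the real
phenomenon being emulated.

### What passing tests do and do not show

Synthetic validation shows the *pipeline* is correct: thresholds equal
their exhaustive oracle, volumes track planted geometry within stated
tolerances, counts are exact for resolvable nuclei, percentage statistics
match their binomial expectations, and effect directions (control >
immobilised) propagate through the measured outputs. It does not show
robustness to what the generator omits: anisotropic PSF blur, depth-
dependent attenuation, autofluorescence, touching nuclei of irregular
shape, or segmentation of real cartilage morphology. Rendered tracking
scenes under-count divisions when daughters land beside another cell, so
measured count increases are conservative relative to truth; truth-level
outputs are exact.

## Problem sizes in the validation suite

The validation suite and `scripts/acceptance.py` use: 1,000 random
histograms for the Otsu oracle; a 0.3 µm-pitch ball (≈ 155,000 points) for
the analytic volume check, with the 1 µm-pitch bias pinned separately; 50
planted-blob scenes (24×64×64 voxels) for volume recovery and 12 nested
scene triplets for signal-reduction monotonicity; 50 detection scenes
(20×112×160) and 500 truth-level tracking pairs; 2,000 simulations per
statistical branch plus 2,000 coverage draws and 200 dispatch cases; and a
two-pass pipeline run for byte-level determinism. These sizes give
Monte-Carlo error comfortably inside every asserted tolerance.
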