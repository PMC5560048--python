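# jointquant

Quantification of mechanosensitive Wnt-reporter activity and cell behaviour
at the developing zebrafish jaw joint, from calibrated multi-channel 3D
confocal stacks.

During larval jaw-joint morphogenesis, Meckel's cartilage (MC) and the
palatoquadrate (PQ) shape an interlocking joint; canonical Wnt signalling at
the joint is mechanosensitive, and blocking either movement or Wnt16 changes
joint shape and joint-cell behaviour. `jointquant` reimplements, as a tested
and reusable library, the image-quantification and statistics pipeline used
for this kind of experiment:

* **Reporter-signal volume** — within a user-drawn polygon ROI (extruded
  through z), voxels of the nuclear reporter channel (e.g.
  `7xTCF:nlsGFP`) are thresholded by Otsu's method computed over the ROI
  interior, all supra-threshold voxels are treated as one object, and the
  object's volume is the volume of the 3D **alpha shape** of the voxel
  centers at the automatically determined (critical) radius
  α* = min{α : every point is a vertex of a retained tetrahedron}, with
  V = Σ_T |det[b−a, c−a, d−a]|/6 over tetrahedra T with circumradius ≤ α.
* **Cell census** — nuclei as supra-threshold 26-connected 3D components,
  counted in a 50 × 80 µm window anchored at a joint landmark.
* **Photoconverted-population tracking** — counts and combined
  maximum-intensity-projection area of red-Kaede-labelled cells at two
  timepoints, and the percentage increase 100·(v₁−v₀)/v₀ of each (the red
  label is inherited by daughter cells, so the population summarises
  proliferation plus migration).
* **Morphometrics** — signed medial/lateral interzone intervals
  (pq_edge − mc_edge; negative = overlapping elements), polyline lengths,
  and cell-type proportion ratios.
* **Group statistics** — Shapiro–Wilk-dispatched comparisons (Student t /
  Mann–Whitney for two groups, one-way ANOVA / Kruskal–Wallis for more),
  with per-group mean and Student-t 95% CI.
* **Synthetic data** — a ground-truthed generator of two-channel joint
  scenes and paired-timepoint tracking datasets (two cartilage rods with a
  configurable interzone gap, clustered reporter nuclei, a photoconverted
  batch of 10–12 cells with condition-dependent division and migration,
  shot + read noise, uint16 quantisation), so every stage is testable
  without real data.

No raw stacks from the original experiments are publicly deposited, so the
package validates itself against synthetic scenes with known ground truth
and against independent analytic/brute-force oracles.

## Worked example

```python
from jointquant import SceneParams, generate_joint_stack, quantify_region
from jointquant.synthetic_data import joint_roi

params = SceneParams(seed=1, n_gfp_nuclei=1, cluster_sd_um=2.0, nucleus_radius_um=5.0)
stack, truth = generate_joint_stack(params)
report = quantify_region(stack, "GFP", joint_roi(params, half_width_um=18.0), "joint")
print(report.threshold, report.n_voxels, report.volume_um3)
```

Running `python examples/01_reporter_volume.py` (which adds the
ground-truth comparison) prints:

```
Otsu threshold (ROI interior): 342.2 intensity units
supra-threshold voxels:        3921
alpha-shape volume:            2216 um^3
ground-truth hull volume:      2316 um^3
relative error:                -4.3%
```

i.e. the pipeline segments 3921 voxels of the planted blob above the
ROI-local Otsu threshold and measures an alpha-shape volume 4.3% below the
scene's analytic ground truth — the expected small deficit of building the
shape on voxel centers. The other `examples/*.py` scripts walk through the
census, tracking, morphometrics and statistics stages the same way, each
printing measured values next to the planted truth.

A thin CLI mirrors the stages for batch use:

```bash
jointquant simulate --config scene.yaml --out sim/
jointquant volume --stack s.tif --meta s.json --roi joint.json --channel GFP --out report.csv
jointquant run --config run.yaml       # volume -> census -> track -> morph -> stats
```

`run` writes one CSV per stage plus a JSON run manifest; identical configs
reproduce byte-identical outputs.

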