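"""Counting reporter-positive nuclei in the standard window at the joint.

Plants well-separated nuclei, detects them as supra-threshold 26-connected
components, and counts those falling in a 50 x 80 um window anchored at the
joint landmark.
"""

from jointquant import CountWindow, SceneParams, count_in_window, detect_nuclei, generate_joint_stack

params = SceneParams(
    seed=3,
    shape_vox=(20, 112, 160),
    n_gfp_nuclei=8,
    min_nucleus_separation_um=22.0,
    cluster_sd_um=30.0,
    nucleus_radius_um=4.0,
)
stack, truth = generate_joint_stack(params)

detection = detect_nuclei(stack, "GFP", min_size_vox=30)
jx, jy, _ = params.joint_center_um
window = CountWindow(anchor_um=(jx, jy))  # 50 x 80 um by default
in_window = count_in_window(detection.centroids_um, window)

print(f"planted nuclei:          {len(truth.nuclei_centers_um)}")
print(f"detected nuclei:         {detection.count} (threshold {detection.threshold:.1f})")
print(f"in 50x80 um joint window: {in_window}")
print(f"truth count in window:    {truth.count_nuclei_in_window(window)}")
# Detection is exact for resolvable nuclei; abutting nuclei merge into one
# component and are counted once.
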