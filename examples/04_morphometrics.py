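"""Joint morphometrics: signed interzone intervals, lengths and ratios.

The interzone interval is signed along the oriented measurement axis:
positive = gap between the cartilage elements, negative = overlap (the
hallmark of the perturbed joint).
"""

import numpy as np

from jointquant import celltype_ratio, interzone_interval, joint_outline, polyline_length

# medial and lateral interval measurements (edge coordinates in um along the axis)
print(f"medial interval:  {interzone_interval(10.0, 14.0):+.1f} um  (gap)")
print(f"lateral interval: {interzone_interval(10.0, 8.0):+.1f} um  (elements overlap)")

# jaw length along a drawn polyline
jaw_path = np.array([[0.0, 0.0], [120.0, 15.0], [260.0, 40.0], [380.0, 45.0]])
print(f"jaw length:       {polyline_length(jaw_path):.1f} um")

# proportion of the element occupied by intercalating cells
print(f"intercalating-cell ratio: {celltype_ratio(75.0, 300.0):.2f} of element length")

# boundary outline of a 2D element mask, with exact pixel-area bookkeeping
mask = np.zeros((40, 60), dtype=bool)
mask[10:30, 15:45] = True
polys = joint_outline(mask, pixel_size=(0.5, 0.5))
area = 0.5 * abs(np.dot(polys[0][:, 0], np.roll(polys[0][:, 1], -1))
                 - np.dot(polys[0][:, 1], np.roll(polys[0][:, 0], -1)))
print(f"outline polygons: {len(polys)}, outline area {area:.1f} um^2 "
      f"(mask {mask.sum() * 0.25:.1f} um^2)")
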