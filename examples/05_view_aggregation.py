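"""2.5D view aggregation: weighted averaging of per-plane probability maps
with the merged-label sagittal view down-weighted by one half."""

import numpy as np

from neoseg.io import default_phantom_lut
from neoseg.pipeline import aggregate_views

lut = default_phantom_lut()
print("full label set:", lut.names)
print("sagittal (merged) label set:", lut.merged_names)

# one voxel: axial+coronal weakly favour Left-Cortex, sagittal is certain
# of (merged, lateral-blind) white matter
full = np.zeros((7, 1, 1, 1))
full[1] = 0.6   # Left-Cortex
full[0] = 0.4
sag = np.zeros((lut.n_merged, 1, 1, 1))
sag[lut.merge_map[3]] = 1.0  # merged White-Matter

seg = aggregate_views(full, full, sag, lut.merge_array())
print(f"\naggregated label: {seg[0, 0, 0]} ({lut.names[int(seg[0, 0, 0])]})")
print("cortex wins: 0.8 * 0.6 = 0.48 beats the sagittal WM mass 0.2 * (1.0 / 2) = 0.10")
print("per side after the merged probability is split between left and right")
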