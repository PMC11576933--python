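"""Generate a multi-resolution phantom cohort with exact analytic labels.

Shows the label-exactness property: the same head rasterized at 0.5 mm and
1.0 mm agrees exactly at shared voxel centers, with no label resampling.
"""

import numpy as np

from neoseg.phantom import LABEL_NAMES, PhantomSpec, grid_coords, make_cohort, rasterize_phantom

spec = PhantomSpec(resolution_mm=0.5, seed=1)
img, lab, affine = rasterize_phantom(spec)
print(f"phantom at 0.5 mm: volume {img.shape}, labels {sorted(np.unique(lab))}")
for cid in sorted(LABEL_NAMES):
    frac = (lab == cid).mean()
    print(f"  {cid} {LABEL_NAMES[cid]:<20s} {100 * frac:5.1f}% of voxels")

lab_lo = rasterize_phantom(PhantomSpec(resolution_mm=1.0, seed=1))[1]
ax_hi = grid_coords(spec.fov_mm, 0.5)
ax_lo = grid_coords(spec.fov_mm, 1.0)
common = np.isin(np.round(ax_hi, 9), np.round(ax_lo, 9))
agree = (lab[np.ix_(common, common, common)] == lab_lo).mean()
print(f"\nlabel agreement at voxel centers shared by the 0.5 and 1.0 mm grids: {agree:.3f}")
print("(exactly 1.0: labels come from the analytic shape functions, never from resampling)")

manifest = make_cohort(12, resolutions=(0.5, 1.0), seed=0)
print("\ncohort manifest (first rows):")
print(manifest[["subject", "split", "resolution_mm", "rot_deg"]].head().to_string(index=False))
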