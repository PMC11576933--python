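"""The resolution-normalizing 4-DOF latent transform on a feature map.

Builds a smooth test pattern at 0.5 mm, maps it onto the 0.8 mm inner scale
with a rotation + translation, and inverts the transform exactly.
"""

import numpy as np

from neoseg.autodiff import Tensor
from neoseg.geometry import ResolutionSpec, compute_scale_factor
from neoseg.latent import InternalAugParams, LatentTransform

res = ResolutionSpec(res_native=(0.5, 0.5), res_inner=0.8)
print("scale factor SF = res_inner/res_native + alpha:")
print("  alpha=0   ->", compute_scale_factor(res, 0.0))
print("  alpha=0.1 ->", compute_scale_factor(res, 0.1))

x, y = np.meshgrid(np.linspace(0, 1, 32), np.linspace(0, 1, 32), indexing="ij")
pattern = (np.sin(2 * np.pi * x) * np.cos(2 * np.pi * y))[None, None]

lt = LatentTransform(min_inner=8)
params = InternalAugParams(theta=30.0, translation=(2.0, -1.0), alpha=0.0)
inner = lt.forward_transition(Tensor(pattern), [params], res)
back = lt.inverse_transition(inner)

print(f"\nnative 32x32 at 0.5 mm -> inner {inner.shape[2:]} at 0.8 mm (SF = 1.6)")
err = np.abs(back.data - pattern)[..., 5:-5, 5:-5].mean()
print(f"round-trip interior mean abs error: {err:.4f}")
print("(small: the inverse transition restores the native grid almost exactly;")
print(" the residual is bilinear interpolation error)")
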