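"""Affine transforms, sampling grids and resamplers for 2D feature maps.

This is the mathematical core shared by the network-integrated latent
transform and the external augmentation baseline.  Everything here is
plain NumPy and fully deterministic.

Conventions (used consistently throughout the package)
------------------------------------------------------
* Pixel centers sit at integer coordinates, 0-based, in ``(row, col)`` order.
* An :class:`Affine4DOF` stores the *forward* map ``source -> output``.
  Its homogeneous matrix is composed as

      M = T(center) @ Scale @ Rotate(theta) @ T(-center) @ T(translation)

  i.e. the translation is applied first, then rotation and scaling about
  ``center``.
* Positive ``theta`` (degrees) rotates the +row axis towards the +col axis.
* Sampling grids use pull semantics: ``generate_grid(A, out_shape)`` stores,
  for every output pixel, the *source* coordinate ``A^{-1} (i, j, 1)``.
* Out-of-bounds lookups give 0 for images/features and label 0 (background)
  for nearest-neighbour label sampling.
* Nearest-neighbour ties: a coordinate exactly halfway between two pixels
  rounds to the *higher* index (``floor(x + 0.5)``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResolutionSpec",
    "Affine4DOF",
    "SamplingGrid",
    "SF_CLAMP",
    "compute_scale_factor",
    "build_affine",
    "invert_affine",
    "generate_grid",
    "sample_bilinear",
    "sample_nearest",
]

logger = logging.getLogger(__name__)

#: lower clamp for the scale factor; alpha is an unbounded Gaussian draw and a
#: non-positive scale factor would collapse the inner feature map.
SF_CLAMP = 0.05


@dataclass(frozen=True)
class ResolutionSpec:
    """In-plane voxel size of the native image and the normalized inner scale.

    Parameters
    ----------
    res_native : (float, float)
        mm per voxel along (row, col) of the slice.  Anisotropic in-plane
        spacing is allowed.
    res_inner : float
        mm per voxel of the normalized inner scale the latent transform maps
        feature maps onto (default 0.8 mm).
    """

    res_native: tuple[float, float]
    res_inner: float = 0.8

    def __post_init__(self):
        r = np.asarray(self.res_native, dtype=float)
        if r.shape != (2,) or not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError(f"res_native must be two positive floats, got {self.res_native}")
        if not np.isfinite(self.res_inner) or self.res_inner <= 0:
            raise ValueError(f"res_inner must be positive, got {self.res_inner}")
        object.__setattr__(self, "res_native", (float(r[0]), float(r[1])))


@dataclass(frozen=True)
class Affine4DOF:
    """A 4-degree-of-freedom planar affine: isotropic-per-axis scale,
    in-plane rotation, 2D translation (plus the rotation/scaling center).

    ``matrix`` is the 3x3 homogeneous forward map acting on homogeneous
    ``(row, col, 1)`` vectors.
    """

    theta: float
    translation: tuple[float, float]
    scale: tuple[float, float]
    center: tuple[float, float]
    matrix: np.ndarray = field(repr=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(..., 2)`` array of (row, col) points through the affine."""
        pts = np.asarray(points, dtype=float)
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out


@dataclass(frozen=True)
class SamplingGrid:
    """Continuous source coordinates, shape ``(H_out, W_out, 2)``, in source
    pixel units ((row, col), pixel centers at integers)."""

    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[-1] != 2:
            raise ValueError(f"grid coords must have shape (H, W, 2), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("grid coordinates must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def out_shape(self) -> tuple[int, int]:
        return self.coords.shape[0], self.coords.shape[1]


def compute_scale_factor(res: ResolutionSpec, alpha: float = 0.0) -> np.ndarray:
    """Per-axis scale factor ``SF = res_inner / res_native + alpha``.

    ``alpha`` is the Gaussian scale-augmentation perturbation (0 at
    inference).  The result is clamped from below at :data:`SF_CLAMP` with a
    warning; a non-positive factor would be degenerate.
    """
    if not np.isfinite(alpha):
        raise ValueError(f"alpha must be finite, got {alpha}")
    sf = np.array([res.res_inner / r + alpha for r in res.res_native], dtype=float)
    if np.any(sf <= SF_CLAMP):
        warnings.warn(
            f"scale factor {sf} at or below clamp {SF_CLAMP}; clamping", RuntimeWarning,
            stacklevel=2,
        )
        sf = np.maximum(sf, SF_CLAMP)
    return sf


def _translation_matrix(t: np.ndarray) -> np.ndarray:
    m = np.eye(3)
    m[:2, 2] = t
    return m


def build_affine(
    theta: float,
    translation=(0.0, 0.0),
    scale=(1.0, 1.0),
    center=(0.0, 0.0),
) -> Affine4DOF:
    """Build the homogeneous 4-DOF matrix
    ``T(center) @ S @ R(theta) @ T(-center) @ T(translation)``.
    """
    params = np.concatenate(
        [np.atleast_1d(np.asarray(p, dtype=float)) for p in (theta, translation, scale, center)]
    )
    if not np.all(np.isfinite(params)):
        raise ValueError("affine parameters must be finite")
    theta = float(theta)
    translation = tuple(np.asarray(translation, dtype=float))
    scale = tuple(np.asarray(scale, dtype=float))
    center = tuple(np.asarray(center, dtype=float))

    rad = np.deg2rad(theta)
    c, s = np.cos(rad), np.sin(rad)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    sc = np.diag([scale[0], scale[1], 1.0])
    m = (
        _translation_matrix(np.asarray(center))
        @ sc
        @ rot
        @ _translation_matrix(-np.asarray(center))
        @ _translation_matrix(np.asarray(translation))
    )
    return Affine4DOF(theta=theta, translation=translation, scale=scale, center=center, matrix=m)


def invert_affine(a: Affine4DOF) -> Affine4DOF:
    """Exact inverse of a 4-DOF affine (as a raw-matrix ``Affine4DOF``)."""
    if abs(a.scale[0]) < 1e-12 or abs(a.scale[1]) < 1e-12 or abs(np.linalg.det(a.matrix)) < 1e-12:
        raise ValueError("affine is singular and cannot be inverted")
    inv = np.linalg.inv(a.matrix)
    return Affine4DOF(
        theta=-a.theta,
        translation=tuple(inv[:2, 2]),
        scale=(1.0 / a.scale[0], 1.0 / a.scale[1]),
        center=a.center,
        matrix=inv,
    )


def compose(a: Affine4DOF, b: Affine4DOF) -> Affine4DOF:
    """The affine applying ``b`` first, then ``a`` (matrix product a @ b)."""
    return Affine4DOF(
        theta=a.theta + b.theta,
        translation=(0.0, 0.0),
        scale=(a.scale[0] * b.scale[0], a.scale[1] * b.scale[1]),
        center=a.center,
        matrix=a.matrix @ b.matrix,
    )


def generate_grid(a: Affine4DOF, out_shape: tuple[int, int]) -> SamplingGrid:
    """Pull-semantics sampling grid for the forward map ``a``.

    ``coords[i, j]`` is the source-space location that output pixel ``(i, j)``
    reads from, i.e. ``a.matrix^{-1} @ (i, j, 1)``.
    """
    h, w = int(out_shape[0]), int(out_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"output shape must be positive, got {out_shape}")
    inv = np.linalg.inv(a.matrix)
    rows, cols = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    coords = np.stack(
        [
            inv[0, 0] * rows + inv[0, 1] * cols + inv[0, 2],
            inv[1, 0] * rows + inv[1, 1] * cols + inv[1, 2],
        ],
        axis=-1,
    )
    return SamplingGrid(coords=coords)


def _as_4d(x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """View (H,W) / (C,H,W) / (N,C,H,W) input as (N,C,H,W)."""
    x = np.asarray(x)
    orig = x.shape
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    elif x.ndim != 4:
        raise ValueError(f"expected 2D, 3D or 4D array, got shape {orig}")
    return x, orig


def bilinear_pieces(grid: SamplingGrid, src_shape: tuple[int, int]):
    """Corner indices and convex weights for bilinear interpolation with
    zero padding.  Shared by the forward sampler and its gradient.

    Returns ``(idx_r0, idx_c0, wr, wc, inside_r0, inside_r1, inside_c0,
    inside_c1)`` where ``wr``/``wc`` are the fractional weights of the
    *upper* (r0+1 / c0+1) corner.
    """
    h, w = src_shape
    r = grid.coords[..., 0]
    c = grid.coords[..., 1]
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    wr = r - r0
    wc = c - c0
    in_r0 = (r0 >= 0) & (r0 <= h - 1)
    in_r1 = (r0 + 1 >= 0) & (r0 + 1 <= h - 1)
    in_c0 = (c0 >= 0) & (c0 <= w - 1)
    in_c1 = (c0 + 1 >= 0) & (c0 + 1 <= w - 1)
    return r0, c0, wr, wc, in_r0, in_r1, in_c0, in_c1


def sample_bilinear(u: np.ndarray, grid: SamplingGrid) -> np.ndarray:
    """Bilinearly resample ``u`` at the grid's source coordinates.

    ``u`` may be (H, W), (C, H, W) or (N, C, H, W); the same grid is applied
    to every channel of every batch element.  Coordinates outside the source
    extent contribute zeros.
    """
    x, orig = _as_4d(u)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    n, ch, h, w = x.shape
    r0, c0, wr, wc, in_r0, in_r1, in_c0, in_c1 = bilinear_pieces(grid, (h, w))
    ho, wo = grid.out_shape

    out = np.zeros((n, ch, ho, wo), dtype=np.result_type(x.dtype, np.float64))
    for dr, dc, mask_r, mask_c, weight in (
        (0, 0, in_r0, in_c0, (1 - wr) * (1 - wc)),
        (0, 1, in_r0, in_c1, (1 - wr) * wc),
        (1, 0, in_r1, in_c0, wr * (1 - wc)),
        (1, 1, in_r1, in_c1, wr * wc),
    ):
        mask = mask_r & mask_c
        rr = np.clip(r0 + dr, 0, h - 1)
        cc = np.clip(c0 + dc, 0, w - 1)
        vals = x[:, :, rr, cc]  # (N, C, Ho, Wo)
        out += vals * (weight * mask)
    if len(orig) == 2:
        return out[0, 0]
    if len(orig) == 3:
        return out[0]
    return out


def sample_nearest(labels: np.ndarray, grid: SamplingGrid) -> np.ndarray:
    """Nearest-neighbour resampling for integer label maps.

    Half-way coordinates round to the higher index; out-of-range lookups
    return background label 0.
    """
    lab = np.asarray(labels)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError(f"labels must be integer-valued, got dtype {lab.dtype}")
    if lab.ndim != 2:
        raise ValueError(f"labels must be 2D, got shape {lab.shape}")
    h, w = lab.shape
    r = np.floor(grid.coords[..., 0] + 0.5).astype(np.int64)
    c = np.floor(grid.coords[..., 1] + 0.5).astype(np.int64)
    inside = (r >= 0) & (r <= h - 1) & (c >= 0) & (c <= w - 1)
    rr = np.clip(r, 0, h - 1)
    cc = np.clip(c, 0, w - 1)
    out = lab[rr, cc]
    out = np.where(inside, out, np.zeros((), dtype=lab.dtype))
    return out.astype(lab.dtype)


def centered_affine(
    theta: float,
    translation,
    scale,
    in_shape: tuple[int, int],
    out_shape: tuple[int, int] | None = None,
) -> Affine4DOF:
    """4-DOF affine about the geometric center ``((H-1)/2, (W-1)/2)`` of the
    input map, with an extra translation aligning the input center with the
    output center when the shapes differ (as they do for the native -> inner
    transition)."""
    if out_shape is None:
        out_shape = in_shape
    c_in = ((in_shape[0] - 1) / 2.0, (in_shape[1] - 1) / 2.0)
    c_out = ((out_shape[0] - 1) / 2.0, (out_shape[1] - 1) / 2.0)
    a = build_affine(theta, translation, scale, center=c_in)
    if c_out != c_in:
        shift = _translation_matrix(np.asarray(c_out) - np.asarray(c_in))
        a = Affine4DOF(
            theta=a.theta,
            translation=a.translation,
            scale=a.scale,
            center=c_in,
            matrix=shift @ a.matrix,
        )
    return a
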