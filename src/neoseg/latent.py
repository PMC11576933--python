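"""The network-integrated 4-DOF transform module.

During training this module draws per-sample augmentation parameters
(in-plane rotation, 2D translation, and a Gaussian perturbation ``alpha`` of
the scale factor), applies the forward native->inner transition to the
feature maps after the first encoder block, and applies the *exact* inverse
transition before the last decoder block, so predictions always live on the
native voxel grid.  At inference all augmentation parameters are zero and
the module reduces to pure resolution normalization onto the inner scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .geometry import (
    Affine4DOF,
    ResolutionSpec,
    centered_affine,
    compute_scale_factor,
    generate_grid,
    invert_affine,
)

__all__ = [
    "InternalAugRanges",
    "InternalAugParams",
    "sample_internal_params",
    "TransformRecord",
    "LatentTransform",
    "MIN_INNER_SIZE",
]

#: minimum spatial extent of the inner feature map; with four pooling levels
#: below the latent transform, 16 keeps every level non-degenerate.
MIN_INNER_SIZE = 16


@dataclass(frozen=True)
class InternalAugRanges:
    """Sampling ranges for the internal augmentation parameters.

    Defaults mirror the external-augmentation ranges (rotation within
    +/-180 degrees, translation magnitude 0..15 native pixels per axis with
    random sign) so the internal and external arms have comparable
    augmentation strength; ``alpha`` is N(0, 0.1).
    """

    rot_min: float = -180.0
    rot_max: float = 180.0
    trans_min: float = 0.0
    trans_max: float = 15.0
    alpha_sigma: float = 0.1

    def __post_init__(self):
        if self.rot_min > self.rot_max or self.trans_min > self.trans_max:
            raise ValueError(f"invalid augmentation ranges: {self}")
        if self.alpha_sigma < 0:
            raise ValueError("alpha_sigma must be >= 0")


@dataclass(frozen=True)
class InternalAugParams:
    """One draw of the internal 4-DOF augmentation (identity at inference)."""

    theta: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    alpha: float = 0.0

    @classmethod
    def identity(cls) -> "InternalAugParams":
        return cls()


def sample_internal_params(
    cfg: InternalAugRanges, rng: np.random.Generator, training: bool
) -> InternalAugParams:
    """Draw one per-sample set of internal augmentation parameters.

    Translation magnitudes are drawn per axis from ``[trans_min, trans_max]``
    native pixels and given a random sign.  At inference everything is 0.
    """
    if not training:
        return InternalAugParams.identity()
    theta = float(rng.uniform(cfg.rot_min, cfg.rot_max))
    mag = rng.uniform(cfg.trans_min, cfg.trans_max, size=2)
    sign = rng.choice([-1.0, 1.0], size=2)
    alpha = float(rng.normal(0.0, cfg.alpha_sigma))
    return InternalAugParams(
        theta=theta, translation=(float(mag[0] * sign[0]), float(mag[1] * sign[1])), alpha=alpha
    )


@dataclass
class TransformRecord:
    """Bookkeeping for one forward transition: the per-sample affines and the
    shapes needed to build the exact inverse."""

    affines: list[Affine4DOF]
    native_shape: tuple[int, int]
    inner_shape: tuple[int, int]
    res: ResolutionSpec


class LatentTransform:
    """Forward (native -> inner) and inverse (inner -> native) feature-map
    transitions.

    ``allow_spatial=False`` restricts the module to pure scaling (the
    resolution-normalization variant); rotation/translation requests then
    raise.  Every forward transition pushes a :class:`TransformRecord` that
    the paired inverse transition pops — the registry must be empty after a
    complete forward pass.
    """

    def __init__(self, allow_spatial: bool = True, min_inner: int = MIN_INNER_SIZE):
        self.allow_spatial = allow_spatial
        self.min_inner = int(min_inner)
        self._pending: list[TransformRecord] = []

    # -- internals ----------------------------------------------------------
    def _affine_for(
        self,
        params: InternalAugParams,
        res: ResolutionSpec,
        native_shape: tuple[int, int],
        inner_shape: tuple[int, int],
    ) -> Affine4DOF:
        if not self.allow_spatial and (
            params.theta != 0.0 or params.translation != (0.0, 0.0)
        ):
            raise ValueError(
                "this latent transform performs resolution normalization only; "
                "rotation/translation must be zero"
            )
        sf = compute_scale_factor(res, params.alpha)
        # translation is given in native pixels and applied on the native
        # (source) side of the map, so the physical displacement is
        # translation * res_native millimetres at every input resolution
        return centered_affine(
            params.theta, params.translation, (sf[0], sf[1]), native_shape, inner_shape
        )

    def inner_shape_for(self, native_shape: tuple[int, int], res: ResolutionSpec) -> tuple[int, int]:
        """``round(native * SF)`` per axis with the unaugmented scale factor
        (the per-sample ``alpha`` perturbs the sampling, not the grid size,
        so a batch shares one inner shape)."""
        sf = compute_scale_factor(res, 0.0)
        shape = (int(round(native_shape[0] * sf[0])), int(round(native_shape[1] * sf[1])))
        if min(shape) < self.min_inner:
            raise ValueError(
                f"inner shape {shape} below minimum {self.min_inner}; "
                "input too small for the five-level architecture"
            )
        return shape

    # -- transitions ---------------------------------------------------------
    def forward_transition(
        self,
        u: ad.Tensor,
        params: list[InternalAugParams],
        res: ResolutionSpec,
    ) -> ad.Tensor:
        """Map native-space features ``u`` (N, C, H, W) onto the inner scale,
        applying each sample's 4-DOF augmentation."""
        n, c, h, w = u.shape
        if len(params) != n:
            raise ValueError(f"need one parameter draw per sample: {len(params)} != {n}")
        native_shape = (h, w)
        inner_shape = self.inner_shape_for(native_shape, res)
        affines, mats = [], []
        for i in range(n):
            a = self._affine_for(params[i], res, native_shape, inner_shape)
            affines.append(a)
            mats.append(
                ad.grid_sampler_matrix(generate_grid(a, inner_shape), native_shape)
                .astype(u.data.dtype)
            )
        v = ad.grid_sample_batch(u, mats, inner_shape)
        self._pending.append(
            TransformRecord(affines=affines, native_shape=native_shape,
                            inner_shape=inner_shape, res=res)
        )
        return v

    def inverse_transition(self, v: ad.Tensor, record: TransformRecord | None = None) -> ad.Tensor:
        """Map inner-space features back onto the native grid with the exact
        inverse of the recorded per-sample affines."""
        if record is None:
            if not self._pending:
                raise RuntimeError("no recorded forward transition to invert")
            record = self._pending.pop()
        elif record in self._pending:
            self._pending.remove(record)
        n = v.shape[0]
        if n != len(record.affines):
            raise ValueError("batch size does not match the recorded transition")
        if v.shape[2:] != record.inner_shape:
            raise ValueError(
                f"inner shape mismatch: {v.shape[2:]} vs recorded {record.inner_shape}"
            )
        mats = []
        for i in range(n):
            inv = invert_affine(record.affines[i])
            mats.append(
                ad.grid_sampler_matrix(
                    generate_grid(inv, record.native_shape), record.inner_shape
                ).astype(v.data.dtype)
            )
        return ad.grid_sample_batch(v, mats, record.native_shape)

    @property
    def pending(self) -> int:
        """Number of forward transitions still awaiting their inverse."""
        return len(self._pending)
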