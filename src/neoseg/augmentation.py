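"""External augmentation baselines.

Spatial: random 2D affines applied to image/label pairs *before* the
network — the classic alternative to the network-integrated latent
transform.  Labels are resampled either with nearest neighbour (``nn``) or
by bilinear interpolation of their one-hot channels (``soft``), the latter
avoiding nearest-neighbour label artifacts at the cost of soft targets.

Intensity: each training batch is transformed, with probability 0.4, by one
of {bias field, gamma, ghosting, spiking, blurring, Gaussian noise};
labels are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import centered_affine, generate_grid, sample_bilinear, sample_nearest

__all__ = [
    "ExternalAugRanges",
    "IntensityAugConfig",
    "sample_external_params",
    "external_spatial_augment",
    "normalize_soft_labels",
    "intensity_augment",
]


@dataclass(frozen=True)
class ExternalAugRanges:
    """Parameter ranges of the external spatial augmentation: rotation within
    +/-180 degrees, translation magnitude 0..15 px per axis (random sign),
    and — only for arms without resolution normalization — isotropic scaling
    in [0.8, 1.15]."""

    rot_min: float = -180.0
    rot_max: float = 180.0
    trans_min: float = 0.0
    trans_max: float = 15.0
    scale_min: float = 0.8
    scale_max: float = 1.15


def sample_external_params(
    rng: np.random.Generator,
    ranges: ExternalAugRanges = ExternalAugRanges(),
    include_scale: bool = True,
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Draw ``(theta, translation, scale)`` for one slice.

    ``include_scale=False`` (the resolution-normalizing arms, whose latent
    module makes external scaling obsolete) fixes the scale at 1.
    """
    theta = float(rng.uniform(ranges.rot_min, ranges.rot_max))
    mag = rng.uniform(ranges.trans_min, ranges.trans_max, size=2)
    sign = rng.choice([-1.0, 1.0], size=2)
    translation = (float(mag[0] * sign[0]), float(mag[1] * sign[1]))
    if include_scale:
        s = float(rng.uniform(ranges.scale_min, ranges.scale_max))
    else:
        s = 1.0
    return theta, translation, (s, s)


def external_spatial_augment(
    image: np.ndarray,
    labels: np.ndarray,
    params: tuple[float, tuple[float, float], tuple[float, float]],
    mode: str = "nn",
    n_classes: int | None = None,
):
    """Apply one affine draw to an aligned (image, label) slice pair.

    ``mode='nn'`` returns integer labels resampled with nearest neighbour;
    ``mode='soft'`` one-hot-expands the labels and resamples every class
    channel bilinearly, returning a soft label field whose per-pixel channel
    sum is <= 1 (mass may leave the frame).
    """
    if mode not in ("nn", "soft"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError(f"image/labels misaligned: {image.shape} vs {labels.shape}")
    theta, translation, scale = params
    a = centered_affine(theta, translation, scale, image.shape)
    grid = generate_grid(a, image.shape)
    image_t = sample_bilinear(image, grid)
    if mode == "nn":
        return image_t, sample_nearest(labels, grid)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    onehot = np.zeros((n_classes,) + labels.shape)
    np.put_along_axis(onehot, labels[None].astype(np.int64), 1.0, axis=0)
    soft = sample_bilinear(onehot, grid)
    return image_t, soft


def normalize_soft_labels(soft: np.ndarray) -> np.ndarray:
    """Renormalize a soft label field per pixel where the channel sum is
    positive; pixels with zero mass (outside the frame) become pure
    background (class 0)."""
    soft = np.asarray(soft, dtype=float)
    total = soft.sum(axis=0, keepdims=True)
    out = np.divide(soft, total, out=np.zeros_like(soft), where=total > 0)
    empty = total[0] <= 0
    out[0][empty] = 1.0
    return out


# ---------------------------------------------------------------------------
# Intensity augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityAugConfig:
    """Constants of the intensity sub-operations (conventional defaults for
    MRI augmentation toolkits) and the per-batch application probability."""

    probability: float = 0.4
    bias_amplitude: float = 0.3
    log_gamma_range: tuple[float, float] = (-0.3, 0.3)
    ghost_count: tuple[int, int] = (2, 6)
    ghost_intensity: tuple[float, float] = (0.3, 0.8)
    spike_count: tuple[int, int] = (1, 3)
    spike_intensity: tuple[float, float] = (0.2, 0.6)
    blur_sigma: tuple[float, float] = (0.25, 1.5)
    noise_sigma: tuple[float, float] = (0.02, 0.1)


def _bias_field(batch, rng, cfg):
    n, c, h, w = batch.shape
    rr = np.linspace(-1, 1, h)[:, None]
    cc = np.linspace(-1, 1, w)[None, :]
    coeff = rng.uniform(-cfg.bias_amplitude, cfg.bias_amplitude, size=6)
    field = np.exp(
        coeff[0] * rr + coeff[1] * cc + coeff[2] * rr * cc
        + coeff[3] * rr ** 2 + coeff[4] * cc ** 2 + coeff[5]
    )
    return batch * field


def _gamma(batch, rng, cfg):
    g = np.exp(rng.uniform(*cfg.log_gamma_range))
    lo = batch.min()
    span = batch.max() - lo
    if span <= 0:
        return batch
    return ((batch - lo) / span) ** g * span + lo


def _ghosting(batch, rng, cfg):
    n_ghosts = int(rng.integers(cfg.ghost_count[0], cfg.ghost_count[1] + 1))
    strength = rng.uniform(*cfg.ghost_intensity)
    axis = int(rng.integers(2, 4))
    k = np.fft.fft(batch, axis=axis)
    idx = [slice(None)] * batch.ndim
    size = batch.shape[axis]
    lines = np.arange(0, size, max(1, size // max(n_ghosts, 1)))[1:]
    idx[axis] = lines
    k[tuple(idx)] *= 1.0 - strength
    return np.fft.ifft(k, axis=axis).real


def _spiking(batch, rng, cfg):
    n_spikes = int(rng.integers(cfg.spike_count[0], cfg.spike_count[1] + 1))
    strength = rng.uniform(*cfg.spike_intensity)
    k = np.fft.fft2(batch, axes=(2, 3))
    h, w = batch.shape[2:]
    scale = strength * np.abs(k[:, :, 0, 0])
    for _ in range(n_spikes):
        r = int(rng.integers(1, max(h // 2, 2)))
        c = int(rng.integers(1, max(w // 2, 2)))
        k[:, :, r, c] += scale
    return np.fft.ifft2(k, axes=(2, 3)).real


def _blur(batch, rng, cfg):
    sigma = rng.uniform(*cfg.blur_sigma)
    return ndimage.gaussian_filter(batch, sigma=(0, 0, sigma, sigma))


def _gaussian_noise(batch, rng, cfg, sigma=None):
    if sigma is None:
        sigma = rng.uniform(*cfg.noise_sigma)
    return batch + rng.normal(0.0, sigma, size=batch.shape)


_TRANSFORMS = (_bias_field, _gamma, _ghosting, _spiking, _blur, _gaussian_noise)


def intensity_augment(
    batch: np.ndarray,
    rng: np.random.Generator,
    cfg: IntensityAugConfig = IntensityAugConfig(),
) -> np.ndarray:
    """With probability ``cfg.probability``, transform the batch (N, C, H, W)
    by one uniformly chosen intensity operation; otherwise pass through."""
    batch = np.asarray(batch, dtype=float)
    if not np.all(np.isfinite(batch)):
        raise ValueError("batch contains non-finite intensities")
    if rng.uniform() >= cfg.probability:
        return batch
    op = _TRANSFORMS[int(rng.integers(len(_TRANSFORMS)))]
    return op(batch, rng, cfg)
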