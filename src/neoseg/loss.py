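"""Composite weighted logistic + soft-Dice loss with per-pixel weight maps.

The scalar training loss is

    L = - sum_{l,i} w_i * y_{l,i} * log p_{l,i}
        - sum_l  2 * sum_i p_{l,i} y_{l,i} / (sum_i p_{l,i} + sum_i y_{l,i})

with the per-class Dice ratio defined as 0 when its denominator is 0, and a
per-pixel weight

    w_i = w_medianfreq + w_gradient + w_GM + w_WM/Sulci

combining median-frequency class balancing, a label-gradient boundary term,
and two morphological masks that up-weight the partial-volume-affected
outer cortical band and the thin white-matter strands / deep sulci next to
it.  ``y`` may be one-hot or a soft label field (from the soft external
augmentation variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "WeightMap",
    "LossConfig",
    "median_frequency_weights",
    "gradient_weights",
    "pve_weights",
    "build_weight_map",
    "composite_loss",
    "one_hot",
    "LOG_EPS",
]

#: probabilities are clamped at this floor inside the logistic term
LOG_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Scalars multiplying the weight-map components (all default to 1) and
    the structuring-element radius of the morphological cortex masks."""

    gradient_scale: float = 1.0
    gm_scale: float = 1.0
    wm_sulci_scale: float = 1.0
    pve_radius: int = 1


@dataclass(frozen=True)
class WeightMap:
    """Per-pixel loss weights and their four components (same shape)."""

    omega_medianfreq: np.ndarray
    omega_gradient: np.ndarray
    omega_gm: np.ndarray
    omega_wm_sulci: np.ndarray

    @property
    def omega_total(self) -> np.ndarray:
        return self.omega_medianfreq + self.omega_gradient + self.omega_gm + self.omega_wm_sulci

    def __post_init__(self):
        shapes = {
            self.omega_medianfreq.shape,
            self.omega_gradient.shape,
            self.omega_gm.shape,
            self.omega_wm_sulci.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"weight components must share one shape, got {shapes}")
        for name in ("omega_medianfreq", "omega_gradient", "omega_gm", "omega_wm_sulci"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")


def class_weights_median_frequency(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class weights ``median(freq) / freq_c`` over the classes present;
    absent classes get weight 0 (rather than infinity)."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("empty label map")
    counts = np.bincount(lab.ravel(), minlength=n_classes).astype(float)
    freqs = counts / counts.sum()
    present = counts > 0
    med = np.median(freqs[present])
    w = np.zeros(n_classes)
    w[present] = med / freqs[present]
    return w


def median_frequency_weights(labels: np.ndarray, n_classes: int,
                             class_weights: np.ndarray | None = None) -> np.ndarray:
    """Broadcast (pre-computed or per-map) median-frequency class weights to
    a per-pixel map.  Pass ``class_weights`` computed once over the training
    set to use the cached dataset-level statistics."""
    if class_weights is None:
        class_weights = class_weights_median_frequency(labels, n_classes)
    return class_weights[np.asarray(labels)]


def gradient_weights(labels: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Magnitude of the 2D spatial gradient of the label map (central
    differences), nonzero exactly in the band around class boundaries."""
    lab = np.asarray(labels, dtype=float)
    if lab.ndim != 2:
        raise ValueError(f"expected a 2D label slice, got shape {lab.shape}")
    gr, gc = np.gradient(lab)
    return scale * np.hypot(gr, gc)


def pve_weights(
    labels: np.ndarray,
    cortex_ids,
    wm_ids,
    radius: int = 1,
    gm_scale: float = 1.0,
    wm_sulci_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary masks of the partial-volume-affected areas around the cortex.

    Erosion of the cortex union isolates the outer cortical band
    (``omega_GM`` = cortex minus its erosion); dilation reaches into the
    adjacent deep sulci and thin white-matter strands (``omega_WM/Sulci`` =
    dilation minus cortex).  Each mask is multiplied by its scalar weight.
    """
    lab = np.asarray(labels)
    known = set(np.unique(lab).tolist())
    for cid in list(cortex_ids) + list(wm_ids):
        if not isinstance(cid, (int, np.integer)):
            raise ValueError(f"class ids must be integers, got {cid!r}")
    cortex = np.isin(lab, list(cortex_ids))
    if not cortex.any():
        z = np.zeros(lab.shape)
        return z, z.copy()
    selem = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(cortex, selem, iterations=radius)
    dilated = ndimage.binary_dilation(cortex, selem, iterations=radius)
    omega_gm = (cortex & ~eroded).astype(float) * gm_scale
    omega_wm = (dilated & ~cortex).astype(float) * wm_sulci_scale
    return omega_gm, omega_wm


def build_weight_map(
    labels: np.ndarray,
    n_classes: int,
    cortex_ids,
    wm_ids,
    cfg: LossConfig = LossConfig(),
    class_weights: np.ndarray | None = None,
) -> WeightMap:
    """Assemble all four components for one 2D label slice."""
    omega_gm, omega_wm = pve_weights(
        labels, cortex_ids, wm_ids, cfg.pve_radius, cfg.gm_scale, cfg.wm_sulci_scale
    )
    return WeightMap(
        omega_medianfreq=median_frequency_weights(labels, n_classes, class_weights),
        omega_gradient=gradient_weights(labels, cfg.gradient_scale),
        omega_gm=omega_gm,
        omega_wm_sulci=omega_wm,
    )


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode an integer map to ``(n_classes, ...)`` float."""
    lab = np.asarray(labels)
    out = np.zeros((n_classes,) + lab.shape)
    np.put_along_axis(out, lab[None].astype(np.int64), 1.0, axis=0)
    return out


def _safe_dice_sum(p: Tensor, y: np.ndarray, class_axis: int, reduce_axes: tuple) -> Tensor:
    """sum_l 2 * <p, y> / (sum p + sum y), ratio = 0 where the denominator is 0."""
    num = (p * y).sum(axis=reduce_axes)
    den_p = p.sum(axis=reduce_axes)
    den_y = np.sum(y, axis=reduce_axes)
    den = den_p + den_y
    mask = (den.data > 0).astype(float)
    # where den == 0 the numerator is 0 as well; shift the denominator to 1
    # there so the autodiff division is well defined and the term is exactly 0
    safe_den = den + (1.0 - mask)
    return ((num * 2.0) / safe_den * mask).sum()


def composite_loss(
    p: Tensor | np.ndarray,
    y: np.ndarray,
    omega: np.ndarray | WeightMap | None = None,
    reduction: str = "sum",
) -> Tensor:
    """The scalar composite loss.

    Parameters
    ----------
    p : (N, L, H, W) or (L, H, W) probabilities (softmax output).
    y : matching one-hot or soft label field.
    omega : per-pixel weights (N, H, W) / (H, W); ``None`` means 1 everywhere.
    reduction : ``"sum"`` is the raw sum form (logistic summed over pixels,
        Dice summed over classes); ``"balanced"`` divides the logistic term
        by the pixel count and the Dice term by the class count, keeping
        both O(1) regardless of batch size so neither term swamps the other
        during optimization.

    Returns an autodiff scalar; gradients flow through ``p`` only.
    """
    if reduction not in ("sum", "balanced"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if isinstance(p, np.ndarray):
        p = Tensor(p)
    y = np.asarray(y, dtype=p.data.dtype)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if isinstance(omega, WeightMap):
        omega = omega.omega_total
    squeeze = p.ndim == 3
    if squeeze:
        p = p.reshape((1,) + p.shape)
        y = y[None]
    if omega is None:
        w = np.ones((y.shape[0],) + y.shape[2:], dtype=y.dtype)
    else:
        w = np.asarray(omega, dtype=y.dtype)
        if w.ndim == 2:
            w = np.broadcast_to(w, (y.shape[0],) + w.shape)
        if w.shape != (y.shape[0],) + y.shape[2:]:
            raise ValueError(f"weight shape {w.shape} does not match labels {y.shape}")

    logp = ad.log(ad.clamp_min(p, LOG_EPS))
    logistic = -((logp * y) * w[:, None]).sum()
    # soft Dice accumulated per class over all pixels of the batch
    dice = _safe_dice_sum(p, y, class_axis=1, reduce_axes=(0, 2, 3))
    if reduction == "balanced":
        npix = float(np.prod(y.shape) / y.shape[1])
        return logistic * (1.0 / npix) - dice * (1.0 / y.shape[1])
    return logistic - dice


def logistic_term(p: np.ndarray, y: np.ndarray, omega: np.ndarray | None = None) -> float:
    """The logistic part alone (diagnostics/logging)."""
    t = composite_loss(Tensor(np.asarray(p)), y, omega)
    # loss = logistic + dice_term, with dice_term = -sum_l dice_l
    return float(t.data) - dice_term(p, y)


def dice_term(p: np.ndarray, y: np.ndarray) -> float:
    """The (negative) soft-Dice part alone: ``- sum_l dice_l``."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.ndim == 3:
        p, y = p[None], y[None]
    num = 2.0 * (p * y).sum(axis=(0, 2, 3))
    den = p.sum(axis=(0, 2, 3)) + y.sum(axis=(0, 2, 3))
    ratio = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(-ratio.sum())
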