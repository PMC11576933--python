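"""Training and inference orchestration.

Training: 2D slices are extracted per anatomical plane (empty ones
filtered), batched by resolution, optionally augmented externally
(nearest-neighbour or soft labels) and by intensity transforms, and fed to
one of the network variants with the composite weighted loss, Adam
(beta1 = 0.95) and a cosine warm-restart schedule.  Inference: per-slice
forward passes with identity augmentation are reassembled into a
probability volume on the *native* voxel grid, and the three per-plane
volumes are combined by weighted softmax averaging with the sagittal
(merged-label) view down-weighted by one half.

Ablation arms (``variant[+ext|+ext_soft]``):

=================  ========================================================
``pool+ext``       pooling baseline + external augmentation incl. scaling
``pool+ext_soft``  as above with soft (one-hot interpolated) labels
``scale+ext``      resolution normalization + external rotation/translation
``scale+ext_soft`` as above with soft labels
``affine``         the full network-integrated 4-DOF transform, no external
``affine+ext``     4-DOF transform *and* external augmentation
=================  ========================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .augmentation import (
    ExternalAugRanges,
    IntensityAugConfig,
    external_spatial_augment,
    intensity_augment,
    normalize_soft_labels,
    sample_external_params,
)
from .geometry import ResolutionSpec
from .latent import InternalAugParams, InternalAugRanges, sample_internal_params
from .loss import LossConfig, build_weight_map, class_weights_median_frequency, composite_loss, dice_term, one_hot
from .metrics import dsc
from .network import NetworkSpec, SegNet, build_network
from .optim import Adam, cosine_warm_restart_lr

__all__ = [
    "PLANES",
    "ARMS",
    "TrainConfig",
    "SliceSample",
    "extract_slices",
    "slices_from_cohort",
    "lr_schedule",
    "train",
    "predict_plane",
    "aggregate_views",
    "LabelMapping",
    "harmonize_labels",
    "lateralize_background",
]

#: plane name -> volume axis that is sliced away (axes are x, y, z)
PLANES = {"sagittal": 0, "coronal": 1, "axial": 2}

ARMS = ("pool+ext", "pool+ext_soft", "scale+ext", "scale+ext_soft", "affine", "affine+ext")


def parse_arm(arm: str) -> tuple[str, str]:
    """Split an arm name into (variant, external mode in {none, nn, soft})."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if arm.endswith("+ext_soft"):
        return arm[: -len("+ext_soft")], "soft"
    if arm.endswith("+ext"):
        return arm[: -len("+ext")], "nn"
    return arm, "none"


# ---------------------------------------------------------------------------
# Slice extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceSample:
    image: np.ndarray       # (H, W) float
    labels: np.ndarray      # (H, W) int
    res: ResolutionSpec
    subject: str = ""


def extract_slices(
    volume: np.ndarray,
    labels: np.ndarray,
    plane: str,
    spacing=(1.0, 1.0, 1.0),
    merge_array: np.ndarray | None = None,
    subject: str = "",
    res_inner: float = 0.8,
    keep_every: int = 1,
) -> list[SliceSample]:
    """Cut a labelled volume into per-plane 2D slices.

    Slices whose label map is entirely background are dropped.  For the
    sagittal plane pass ``merge_array`` to remap lateralized labels onto the
    merged set (the sagittal view cannot see laterality).  ``keep_every``
    subsamples the remaining slices (desk-scale training).
    """
    volume = np.asarray(volume)
    labels = np.asarray(labels)
    if volume.shape != labels.shape:
        raise ValueError(f"volume/labels misaligned: {volume.shape} vs {labels.shape}")
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    axis = PLANES[plane]
    in_plane = tuple(s for i, s in enumerate(spacing) if i != axis)
    res = ResolutionSpec(res_native=in_plane, res_inner=res_inner)
    out = []
    for k in range(volume.shape[axis]):
        lab = np.take(labels, k, axis=axis)
        if not lab.any():
            continue
        if merge_array is not None:
            lab = merge_array[lab]
        out.append(
            SliceSample(
                image=np.take(volume, k, axis=axis).astype(float),
                labels=lab.astype(np.int64),
                res=res,
                subject=subject,
            )
        )
    return out[::keep_every]


def slices_from_cohort(
    manifest: pd.DataFrame,
    plane: str,
    split: str,
    merge_array: np.ndarray | None = None,
    keep_every: int = 1,
) -> list[SliceSample]:
    """Rasterize every manifest subject of one split and extract its slices."""
    from .phantom import PhantomSpec, rasterize_phantom

    samples: list[SliceSample] = []
    sel = manifest[manifest["split"] == split]
    for _, row in sel.iterrows():
        spec = PhantomSpec.from_dict(json.loads(row["spec_json"]))
        image, labels, _ = rasterize_phantom(spec)
        spacing = (spec.resolution_mm,) * 3
        samples.extend(
            extract_slices(
                image, labels, plane, spacing, merge_array,
                subject=row["subject"], keep_every=keep_every,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    arm: str = "affine"
    plane: str = "coronal"
    n_classes: int = 7
    cortex_ids: tuple = (1, 2)
    wm_ids: tuple = (3, 4)
    filters: int = 64
    in_channels: int = 1
    lr: float = 1e-3
    momentum: float = 0.95        # Adam beta1
    batch_size: int = 16
    epochs: int = 40
    t0: int = 10                  # first cosine restart period (epochs)
    t_mult: int = 2
    patience: int = 10            # early stopping on validation mean DSC
    seed: int = 0
    res_inner: float = 0.8
    min_inner: int = 16
    loss: LossConfig = field(default_factory=LossConfig)
    external_ranges: ExternalAugRanges = field(default_factory=ExternalAugRanges)
    internal_ranges: InternalAugRanges = field(default_factory=InternalAugRanges)
    intensity: IntensityAugConfig = field(default_factory=IntensityAugConfig)
    intensity_enabled: bool = True

    def __post_init__(self):
        parse_arm(self.arm)
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if min(self.lr, self.batch_size, self.epochs, self.t0) <= 0:
            raise ValueError("hyperparameters must be positive")


def lr_schedule(epoch: int, cfg: TrainConfig | None = None) -> float:
    """Cosine annealing with warm restarts at cumulative epochs 10, 30, 70, ...
    (periods t0 * t_mult^k); peak learning rate at every restart."""
    cfg = cfg or TrainConfig()
    return cosine_warm_restart_lr(epoch, base_lr=cfg.lr, t0=cfg.t0, mult=cfg.t_mult)


def _batches(samples: list[SliceSample], batch_size: int, rng: np.random.Generator):
    """Shuffle samples and group them into batches of equal resolution/shape."""
    order = rng.permutation(len(samples))
    buckets: dict[tuple, list[int]] = {}
    for idx in order:
        s = samples[idx]
        key = (s.res.res_native, s.image.shape)
        buckets.setdefault(key, []).append(idx)
        if len(buckets[key]) == batch_size:
            yield [samples[i] for i in buckets.pop(key)]
    for key in sorted(buckets, key=repr):
        yield [samples[i] for i in buckets[key]]


@dataclass
class TrainResult:
    net: SegNet
    history: pd.DataFrame
    best_val_dsc: float
    class_weights: np.ndarray


def _mean_foreground_dsc(pred: np.ndarray, ref: np.ndarray, n_classes: int) -> float:
    scores = [dsc(pred, ref, c) for c in range(1, n_classes)]
    return float(np.mean(scores))


def train(
    train_samples: list[SliceSample],
    val_samples: list[SliceSample],
    cfg: TrainConfig,
) -> TrainResult:
    """Train one network arm on one plane.

    Fully seed-reproducible: weight init, batch order, and every
    augmentation draw derive from ``cfg.seed``.  Raises on NaN loss.
    Early-stops when the validation mean foreground DSC has not improved
    for ``cfg.patience`` evaluations; the best state is restored.
    """
    if not train_samples:
        raise ValueError("empty training set")
    variant, ext_mode = parse_arm(cfg.arm)
    resolutions = {s.res.res_native for s in train_samples}
    if variant in ("scale", "affine") and len(resolutions) < 2:
        raise ValueError(
            f"the {variant!r} arm expects a multi-resolution training set, "
            f"got only {resolutions}"
        )
    rng = np.random.default_rng(cfg.seed)
    spec = NetworkSpec(
        variant=variant,
        n_classes=cfg.n_classes,
        in_channels=cfg.in_channels,
        filters=cfg.filters,
        res_inner=cfg.res_inner,
        min_inner=cfg.min_inner,
        aug=cfg.internal_ranges,
    )
    net = build_network(spec, seed=int(rng.integers(2 ** 31 - 1)))
    opt = Adam(net.parameters(), lr=cfg.lr, betas=(cfg.momentum, 0.999))

    # dataset-level median-frequency class weights, computed once and cached
    all_labels = np.concatenate([s.labels.ravel() for s in train_samples])
    class_weights = class_weights_median_frequency(all_labels, cfg.n_classes)
    set_class_weights(net, class_weights)

    history = []
    best = (-np.inf, None)
    stale = 0
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        ep_logistic = ep_dice = ep_total = 0.0
        n_batches = 0
        for batch in _batches(train_samples, cfg.batch_size, rng):
            loss_t, parts = _train_step(net, opt, batch, cfg, variant, ext_mode, rng)
            if not np.isfinite(loss_t):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"batch {n_batches}; last parts: {parts}"
                )
            ep_total += loss_t
            ep_logistic += parts[0]
            ep_dice += parts[1]
            n_batches += 1
        val_dsc = evaluate_slices(net, val_samples) if val_samples else np.nan
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "loss": ep_total / n_batches,
                "logistic": ep_logistic / n_batches,
                "dice_term": ep_dice / n_batches,
                "val_dsc": val_dsc,
            }
        )
        if val_samples:
            if val_dsc > best[0]:
                best = (val_dsc, net.state_dict())
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best[1] is not None:
        net.load_state_dict(best[1])
    return TrainResult(
        net=net,
        history=pd.DataFrame(history),
        best_val_dsc=float(best[0]) if best[1] is not None else float("nan"),
        class_weights=class_weights,
    )


def _train_step(net, opt, batch, cfg: TrainConfig, variant, ext_mode, rng):
    n_classes = cfg.n_classes
    images, targets, weight_labels = [], [], []
    for s in batch:
        img, lab = s.image, s.labels
        if ext_mode != "none":
            params = sample_external_params(
                rng, cfg.external_ranges, include_scale=(variant == "pool")
            )
            if ext_mode == "nn":
                img, lab = external_spatial_augment(img, lab, params, mode="nn")
                targets.append(one_hot(lab, n_classes))
                weight_labels.append(lab)
            else:
                img, soft = external_spatial_augment(
                    img, lab, params, mode="soft", n_classes=n_classes
                )
                soft = normalize_soft_labels(soft)
                targets.append(soft)
                weight_labels.append(soft.argmax(axis=0))
        else:
            targets.append(one_hot(lab, n_classes))
            weight_labels.append(lab)
        images.append(img)
    x = np.stack(images)[:, None]
    if cfg.intensity_enabled:
        x = intensity_augment(x, rng, cfg.intensity)
    y = np.stack(targets)
    cw = _cached_cw(net, batch, cfg)
    omega = np.stack(
        [
            build_weight_map(
                wl, n_classes, cfg.cortex_ids, cfg.wm_ids, cfg.loss, class_weights=cw
            ).omega_total
            for wl in weight_labels
        ]
    )
    res = batch[0].res
    if variant == "affine":
        params = [sample_internal_params(net.spec.aug, rng, training=True) for _ in batch]
    elif variant == "scale":
        params = [
            InternalAugParams(alpha=float(rng.normal(0.0, net.spec.aug.alpha_sigma)))
            for _ in batch
        ]
    else:
        params = None
    probs = net.forward(x, res=res, params=params, training=True)
    loss = composite_loss(probs, y, omega, reduction="balanced")
    opt.zero_grad()
    loss.backward()
    opt.step()
    d = dice_term(probs.data, y) / n_classes
    total = float(loss.data)
    return total, (total - d, d)


_CW_KEY = "_neoseg_class_weights"


def _cached_cw(net, batch, cfg):
    cw = getattr(net, _CW_KEY, None)
    if cw is None:
        labs = np.concatenate([s.labels.ravel() for s in batch])
        cw = class_weights_median_frequency(labs, cfg.n_classes)
    return cw


def set_class_weights(net: SegNet, weights: np.ndarray):
    """Attach dataset-level median-frequency weights to a network so every
    training step reuses the cached statistics."""
    setattr(net, _CW_KEY, np.asarray(weights, dtype=float))


def evaluate_slices(net: SegNet, samples: list[SliceSample]) -> float:
    """Mean foreground DSC of per-slice argmax predictions (validation)."""
    if not samples:
        return float("nan")
    scores = []
    for s in samples:
        probs = net.forward(s.image[None, None], res=s.res, training=False)
        pred = probs.data[0].argmax(axis=0)
        scores.append(_mean_foreground_dsc(pred, s.labels, net.spec.n_classes))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_plane(
    net: SegNet,
    volume: np.ndarray,
    spacing,
    plane: str,
    batch_size: int = 8,
    internal_params: InternalAugParams | None = None,
) -> np.ndarray:
    """Per-slice inference reassembled into a probability volume
    ``(n_classes, *volume.shape)`` on the native grid (no resampling).

    ``spacing`` must come from the volume's header; it is required — the
    scale transition normalizes by the true voxel size.

    ``internal_params`` (affine variant only) applies a *known* pose
    correction inside the latent transform: the slices are rotated/shifted
    in feature space, processed on the normalized inner scale, and exactly
    un-transformed before the last decoder block, so the output still lands
    on the native grid.  Default is the identity.
    """
    if spacing is None:
        raise ValueError("voxel spacing is required for native-space prediction")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any((not np.isfinite(s)) or s <= 0 for s in spacing):
        raise ValueError(f"invalid spacing {spacing}")
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    axis = PLANES[plane]
    in_plane = tuple(s for i, s in enumerate(spacing) if i != axis)
    res = ResolutionSpec(res_native=in_plane, res_inner=net.spec.res_inner)
    volume = np.asarray(volume, dtype=float)
    n_slices = volume.shape[axis]
    out = np.zeros((net.spec.n_classes,) + volume.shape)
    for start in range(0, n_slices, batch_size):
        ks = range(start, min(start + batch_size, n_slices))
        x = np.stack([np.take(volume, k, axis=axis) for k in ks])[:, None]
        params = [internal_params] * len(ks) if internal_params is not None else None
        probs = net.forward(x, res=res, params=params, training=False).data
        for j, k in enumerate(ks):
            idx = [slice(None)] * 4
            idx[axis + 1] = k
            out[tuple(idx)] = probs[j]
    return out


def aggregate_views(
    axial: np.ndarray,
    coronal: np.ndarray,
    sagittal_merged: np.ndarray,
    merge_array: np.ndarray,
    weights=(1.0, 1.0, 0.5),
) -> np.ndarray:
    """2.5D view aggregation.

    The sagittal network predicts merged (non-lateralized) classes; its
    probability for a merged class is split equally between the two
    lateralized children (laterality is then resolved by the axial/coronal
    views).  The three volumes are combined by a voxelwise weighted mean
    with the sagittal weight halved — weights (1, 1, 0.5) normalized to
    (0.4, 0.4, 0.2) — and the argmax gives the final label volume.
    """
    if axial.shape != coronal.shape:
        raise ValueError(f"misaligned views: {axial.shape} vs {coronal.shape}")
    n_full = axial.shape[0]
    if sagittal_merged.shape[1:] != axial.shape[1:]:
        raise ValueError("sagittal volume misaligned with the other views")
    # redistribute merged probabilities onto the full label set
    counts = np.bincount(merge_array[:n_full], minlength=sagittal_merged.shape[0])
    sagittal_full = sagittal_merged[merge_array[:n_full]] / counts[merge_array[:n_full], None, None, None]
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    combined = w[0] * axial + w[1] * coronal + w[2] * sagittal_full
    return combined.argmax(axis=0).astype(np.int16)


# ---------------------------------------------------------------------------
# Label harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelMapping:
    """Merge/remove/mask protocol between label schemes.

    ``table`` maps every source label to a target label; labels in ``drop``
    go to background; labels in ``mask_by_reference`` are additionally
    zeroed wherever the reference volume is background.
    """

    table: dict[int, int]
    drop: frozenset = frozenset()
    mask_by_reference: frozenset = frozenset()


def harmonize_labels(
    seg: np.ndarray,
    mapping: LabelMapping,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Apply a merge/remove/mask protocol to a segmentation."""
    seg = np.asarray(seg)
    observed = np.unique(seg)
    known = set(mapping.table) | set(mapping.drop)
    unmapped = [int(v) for v in observed if int(v) not in known]
    if unmapped:
        raise ValueError(f"unmapped labels encountered: {unmapped}")
    size = int(observed.max()) + 1
    lut = np.zeros(size, dtype=np.int64)
    for src, dst in mapping.table.items():
        if src < size:
            lut[src] = dst
    for src in mapping.drop:
        if src < size:
            lut[src] = 0
    out = lut[seg]
    if mapping.mask_by_reference:
        if reference is None:
            raise ValueError("mapping has mask-by-reference labels but no reference given")
        masked = np.isin(out, list(mapping.mask_by_reference)) & (np.asarray(reference) == 0)
        out[masked] = 0
    return out


def lateralize_background(
    labels: np.ndarray, background_id: int, left_ids, right_ids, spacing
) -> np.ndarray:
    """Ground-truth preparation utility: split an intracranial background
    label into left/right by the nearest lateralized structure (Euclidean
    distance-transform vote).  Returns a label volume where background
    voxels become ``background_id`` (left) / ``background_id + 1`` (right).
    """
    from scipy import ndimage

    labels = np.asarray(labels)
    lateral = np.isin(labels, list(left_ids) + list(right_ids))
    _, idx = ndimage.distance_transform_edt(
        ~lateral, sampling=spacing, return_indices=True
    )
    nearest = labels[tuple(idx)]
    is_left = np.isin(nearest, list(left_ids))
    out = labels.copy()
    bg = labels == background_id
    out[bg & is_left] = background_id
    out[bg & ~is_left] = background_id + 1
    return out
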