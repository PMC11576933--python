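"""Reproducible desk-scale benchmark experiments.

This module fixes the study conditions for the package's built-in
evaluation: a two-resolution (0.5 / 1.0 mm) phantom cohort with in-plane
head rotations of +/-45 degrees, coronal-plane training of the ablation
arms, held-out slice evaluation, and the rotation-consistency probe.  The
same functions drive both the test suite and ``scripts/acceptance.py``.

Problem sizes (cohort of 57 with 40 training phantoms, 8 network filters,
slice subsampling, epoch budget) are chosen so a full ablation fits in CPU
minutes; docs/methods.md discusses what these scaled-down runs can and
cannot show.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augmentation import ExternalAugRanges
from .latent import InternalAugRanges
from .metrics import dsc
from .phantom import N_CLASSES, PhantomSpec, PoseRanges, make_cohort, rasterize_phantom
from .pipeline import (
    TrainConfig,
    TrainResult,
    predict_plane,
    slices_from_cohort,
    train,
)

__all__ = [
    "DeskScale",
    "ablation_cohort",
    "train_arm",
    "heldout_dsc",
    "rotation_consistency",
    "run_ablation",
]


@dataclass(frozen=True)
class DeskScale:
    """Problem sizes of the desk-scale benchmark."""

    n_subjects: int = 57            # 40 train / 7 val / 10 test
    resolutions: tuple = (0.5, 1.0)
    split_fractions: tuple = (0.7, 0.12, 0.18)
    plane: str = "coronal"
    keep_every_train: int = 6
    keep_every_val: int = 8
    keep_every_test: int = 4
    filters: int = 8
    epochs: int = 18
    #: translation ranges scaled to the miniature phantom frame (the recipe's
    #: 0-15 px corresponds to a few percent of a full-size image)
    trans_px: float = 2.0


DESK = DeskScale()


def ablation_cohort(seed: int, scale: DeskScale = DESK) -> pd.DataFrame:
    """The benchmark cohort: two resolutions, poses rotated +/-45 degrees
    in the coronal plane, disjoint splits."""
    return make_cohort(
        scale.n_subjects,
        resolutions=scale.resolutions,
        pose=PoseRanges(),
        split_fractions=scale.split_fractions,
        seed=seed,
    )


def _train_config(arm: str, seed: int, scale: DeskScale, epochs: int | None) -> TrainConfig:
    return TrainConfig(
        arm=arm,
        plane=scale.plane,
        n_classes=N_CLASSES,
        filters=scale.filters,
        epochs=epochs if epochs is not None else scale.epochs,
        patience=10 ** 6,  # fixed-epoch budget: early stopping disabled
        seed=seed,
        internal_ranges=InternalAugRanges(trans_max=scale.trans_px),
        external_ranges=ExternalAugRanges(trans_max=scale.trans_px),
    )


def train_arm(
    manifest: pd.DataFrame,
    arm: str,
    seed: int,
    scale: DeskScale = DESK,
    epochs: int | None = None,
) -> TrainResult:
    """Train one ablation arm on the cohort's coronal slices."""
    tr = slices_from_cohort(manifest, scale.plane, "train", keep_every=scale.keep_every_train)
    va = slices_from_cohort(manifest, scale.plane, "val", keep_every=scale.keep_every_val)
    return train(tr, va, _train_config(arm, seed, scale, epochs))


def heldout_dsc(net, manifest: pd.DataFrame, scale: DeskScale = DESK) -> float:
    """Mean foreground DSC over held-out test slices at their native poses
    and resolutions."""
    from .pipeline import evaluate_slices

    te = slices_from_cohort(manifest, scale.plane, "test", keep_every=scale.keep_every_test)
    return evaluate_slices(net, te)


def _posed(spec: PhantomSpec, rot_y: float) -> PhantomSpec:
    return PhantomSpec.from_dict(
        {**spec.to_dict(), "rotation_deg": (0.0, rot_y, 0.0), "translation_mm": (0.0, 0.0, 0.0)}
    )


def rotation_consistency(
    net, manifest: pd.DataFrame, n_subjects: int = 2, scale: DeskScale = DESK
) -> float:
    """Rotation-consistency probe: predict each test phantom unrotated and
    rotated 90 degrees in the coronal plane, map the rotated prediction back
    onto the unrotated grid (an exact array rotation), and return the mean
    foreground DSC between the two label volumes.

    1.0 means the segmentation is perfectly equivariant to a 90-degree head
    rotation; the score is limited by how rotation-robust training made the
    network.
    """
    rows = manifest[manifest.split == "test"].iloc[:n_subjects]
    scores = []
    for _, row in rows.iterrows():
        spec = PhantomSpec.from_dict(json.loads(row.spec_json))
        s0, s90 = _posed(spec, 0.0), _posed(spec, 90.0)
        img0, _, _ = rasterize_phantom(s0)
        img90, _, _ = rasterize_phantom(s90)
        spacing = (spec.resolution_mm,) * 3
        p0 = predict_plane(net, img0, spacing, scale.plane).argmax(axis=0)
        p90 = predict_plane(net, img90, spacing, scale.plane).argmax(axis=0)
        back = p90.transpose(2, 1, 0)[::-1]  # exact inverse of the 90 deg pose
        fg = [dsc(back, p0, c) for c in range(1, N_CLASSES)]
        scores.append(float(np.mean(fg)))
    return float(np.mean(scores))


def run_ablation(
    manifest: pd.DataFrame,
    arms=("affine", "affine+ext", "scale+ext", "pool+ext"),
    seeds=(0, 1, 2),
    scale: DeskScale = DESK,
    epochs: int | None = None,
    keep_nets: bool = False,
):
    """Train every (arm, seed) combination and evaluate held-out DSC.

    Returns ``(table, nets)``: a tidy frame with one row per run and, when
    ``keep_nets``, the trained networks keyed by (arm, seed).
    """
    rows, nets = [], {}
    for seed in seeds:
        for arm in arms:
            result = train_arm(manifest, arm, seed, scale, epochs)
            score = heldout_dsc(result.net, manifest, scale)
            rows.append(
                {
                    "arm": arm,
                    "seed": seed,
                    "heldout_dsc": score,
                    "final_train_loss": float(result.history.loss.iloc[-1]),
                }
            )
            if keep_nets:
                nets[(arm, seed)] = result.net
    return pd.DataFrame(rows), nets


def ordering_votes(table: pd.DataFrame) -> dict[str, int]:
    """Per-seed votes for the expected performance orderings
    (ties count in favour, as equality satisfies >=)."""
    votes = {"affine>=scale+ext": 0, "scale+ext>=pool+ext": 0, "affine>=affine+ext": 0}
    for _, grp in table.groupby("seed"):
        d = dict(zip(grp.arm, grp.heldout_dsc))
        votes["affine>=scale+ext"] += d["affine"] >= d["scale+ext"]
        votes["scale+ext>=pool+ext"] += d["scale+ext"] >= d["pool+ext"]
        votes["affine>=affine+ext"] += d["affine"] >= d["affine+ext"]
    return votes
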