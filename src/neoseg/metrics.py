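"""Segmentation evaluation: Dice overlap, average surface distance, and
paired nonparametric method comparison.

ASD convention: symmetric; the surface of a mask is the set of its voxels
with at least one background face-neighbour; distances are exact nearest
neighbour distances between the two surface voxel sets, scaled by the
physical voxel spacing, averaged over both directions' surface voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = ["dsc", "asd", "per_class_scores", "compare_methods"]


def _aligned_masks(pred, ref, class_id):
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"volumes misaligned: {pred.shape} vs {ref.shape}")
    return pred == class_id, ref == class_id


def dsc(pred: np.ndarray, ref: np.ndarray, class_id: int) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)`` in [0, 1].

    Both masks empty -> 1 (perfect agreement on absence); exactly one
    empty -> 0.
    """
    a, b = _aligned_masks(pred, ref, class_id)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask voxels with >= 1 background face-neighbour."""
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, struct, border_value=0)
    return np.argwhere(mask & ~eroded)


def asd(pred: np.ndarray, ref: np.ndarray, class_id: int, spacing) -> float:
    """Symmetric average surface distance in millimetres.

    Undefined (returns NaN) when either mask is empty.
    """
    a, b = _aligned_masks(pred, ref, class_id)
    if not a.any() or not b.any():
        return float("nan")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (a.ndim,):
        raise ValueError(f"spacing must have {a.ndim} entries, got {spacing.shape}")
    sa = _surface_voxels(a) * spacing
    sb = _surface_voxels(b) * spacing
    d_ab, _ = cKDTree(sb).query(sa)
    d_ba, _ = cKDTree(sa).query(sb)
    return float(np.concatenate([d_ab, d_ba]).mean())


def per_class_scores(
    pred: np.ndarray, ref: np.ndarray, class_ids, spacing
) -> pd.DataFrame:
    """DSC and ASD for each class id, as a tidy frame."""
    rows = []
    for cid in class_ids:
        rows.append(
            {
                "class_id": int(cid),
                "dsc": dsc(pred, ref, cid),
                "asd_mm": asd(pred, ref, cid, spacing),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    table: pd.DataFrame  # group, statistic, p_raw, p_adj, reject
    alpha: float


def compare_methods(
    scores_a: dict[str, np.ndarray] | pd.DataFrame,
    scores_b: dict[str, np.ndarray] | pd.DataFrame,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test per structure group with
    Benjamini-Hochberg step-up correction across the family.

    ``scores_a``/``scores_b`` map group names to paired per-subject scores
    (same order).  Groups whose paired differences are all zero have an
    undefined test; they are flagged (``p_raw`` NaN, never rejected) and
    excluded from the BH family.
    """
    if isinstance(scores_a, pd.DataFrame):
        scores_a = {c: scores_a[c].to_numpy() for c in scores_a.columns}
    if isinstance(scores_b, pd.DataFrame):
        scores_b = {c: scores_b[c].to_numpy() for c in scores_b.columns}
    if set(scores_a) != set(scores_b):
        raise ValueError("the two methods must report the same groups")
    rows = []
    for group in scores_a:
        a = np.asarray(scores_a[group], dtype=float)
        b = np.asarray(scores_b[group], dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError(f"group {group!r}: paired 1D samples required")
        if a.size < 5:
            raise ValueError(f"group {group!r}: need >= 5 pairs, got {a.size}")
        if np.allclose(a, b):
            rows.append({"group": group, "statistic": np.nan, "p_raw": np.nan,
                         "all_zero": True})
            continue
        res = stats.wilcoxon(a, b, alternative="two-sided")
        rows.append({"group": group, "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue), "all_zero": False})
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    table["reject"] = False
    tested = ~table["all_zero"]
    if tested.any():
        reject, p_adj, _, _ = multipletests(
            table.loc[tested, "p_raw"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        table.loc[tested, "p_adj"] = p_adj
        table.loc[tested, "reject"] = reject
    return ComparisonResult(table=table, alpha=alpha)
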