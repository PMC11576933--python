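"""Analytic multi-resolution head phantoms with exact labels.

Each phantom is a nested set of analytic shapes in canonical millimetre
coordinates — a folded cortical ribbon wrapped around an ellipsoidal
white-matter core containing lateralized subcortical blobs — posed by a 3D
rotation and translation and rasterized on a voxel grid of the requested
resolution.  Labels are produced *only* by evaluating the shape functions at
voxel centers of the posed grid: they are exact at every pose and
resolution, and no label volume is ever resampled from another.

The voxel grid is symmetric and odd-sized (centers at ``k * res`` around the
head center), so grids at 0.5 and 1.0 mm share voxel centers at integer
millimetres and axis-aligned 90-degree rotations of a spec correspond
exactly to array rotations of its rasterization.

Label protocol (lateralized, with a left/right pair for every structure):
0 background, 1/2 left/right cortex, 3/4 left/right white matter,
5/6 left/right subcortical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec",
    "PoseRanges",
    "LABEL_NAMES",
    "CORTEX_IDS",
    "WM_IDS",
    "SUBCORTICAL_IDS",
    "N_CLASSES",
    "rasterize_phantom",
    "sample_spec",
    "make_cohort",
    "grid_coords",
]

LABEL_NAMES = {
    0: "Background",
    1: "Left-Cortex",
    2: "Right-Cortex",
    3: "Left-White-Matter",
    4: "Right-White-Matter",
    5: "Left-Subcortical",
    6: "Right-Subcortical",
}
CORTEX_IDS = (1, 2)
WM_IDS = (3, 4)
SUBCORTICAL_IDS = (5, 6)
N_CLASSES = 7

#: default per-class intensity means (arbitrary units, T2w-like contrast)
DEFAULT_MEANS = {0: 0.05, 1: 0.55, 2: 0.55, 3: 0.85, 4: 0.85, 5: 0.70, 6: 0.70}


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of one synthetic head."""

    radii_mm: tuple[float, float, float] = (7.2, 6.0, 5.6)
    ribbon_thickness_mm: float = 2.2
    fold_frequency: int = 4
    fold_amplitude_mm: float = 0.6
    #: lateralized blobs: ((cx, cy, cz), radius), side taken from sign(cx)
    subcortical: tuple = (((-2.6, 0.3, 0.0), 2.3), ((2.6, 0.3, 0.0), 2.3))
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    resolution_mm: float = 1.0
    fov_mm: float = 20.0
    intensity_means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    noise_sigma: float = 0.04
    bias_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.ribbon_thickness_mm < 2 * self.resolution_mm * 0.999:
            raise ValueError(
                f"ribbon thickness {self.ribbon_thickness_mm} mm must be >= twice "
                f"the voxel size {self.resolution_mm} mm"
            )
        extent = max(self.radii_mm) + self.fold_amplitude_mm + max(
            abs(t) for t in self.translation_mm
        )
        if extent > self.fov_mm / 2 - self.resolution_mm:
            raise ValueError(
                f"structures (extent {extent:.1f} mm) leave the field of view "
                f"({self.fov_mm} mm at {self.resolution_mm} mm)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["intensity_means"] = {str(k): v for k, v in self.intensity_means.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["intensity_means"] = {int(k): float(v) for k, v in d["intensity_means"].items()}
        for key in ("radii_mm", "rotation_deg", "translation_mm"):
            d[key] = tuple(d[key])
        d["subcortical"] = tuple((tuple(c), r) for c, r in d["subcortical"])
        return cls(**d)


def grid_coords(fov_mm: float, res_mm: float) -> np.ndarray:
    """Symmetric odd-length axis of voxel-center coordinates (mm)."""
    half = int(np.floor(fov_mm / (2 * res_mm)))
    return np.arange(-half, half + 1) * res_mm


def _rotation_matrix(rotation_deg) -> np.ndarray:
    """World rotation R = Rz @ Ry @ Rx (intrinsic x, then y, then z)."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def _labels_at(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Evaluate the analytic label function at world points (..., 3)."""
    r = _rotation_matrix(spec.rotation_deg)
    canon = (points - np.asarray(spec.translation_mm)) @ r  # R^-1 = R^T applied row-wise
    # snap numerically-zero coordinates so laterality ties at the midplane
    # resolve identically at every pose
    canon[np.abs(canon) < 1e-9] = 0.0
    cx, cy, cz = canon[..., 0], canon[..., 1], canon[..., 2]
    a, b, c = spec.radii_mm
    n = np.sqrt((cx / a) ** 2 + (cy / b) ** 2 + (cz / c) ** 2)
    r_mean = (a + b + c) / 3.0
    azimuth = np.arctan2(cy, cx)
    elevation = np.arctan2(cz, np.hypot(cx, cy))
    fold = (spec.fold_amplitude_mm / r_mean) * np.sin(
        spec.fold_frequency * azimuth
    ) * np.cos(spec.fold_frequency * elevation)
    n_out = 1.0 + fold
    n_wm = n_out - spec.ribbon_thickness_mm / r_mean

    right = cx >= 0
    labels = np.zeros(cx.shape, dtype=np.int16)
    cortex = (n > n_wm) & (n <= n_out)
    labels[cortex] = np.where(right[cortex], 2, 1)
    wm = n <= n_wm
    labels[wm] = np.where(right[wm], 4, 3)
    for center, radius in spec.subcortical:
        center = np.asarray(center, dtype=float)
        inside = wm & (np.linalg.norm(canon - center, axis=-1) <= radius)
        labels[inside] = 6 if center[0] >= 0 else 5
    return labels


def rasterize_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize one phantom.

    Returns ``(image, labels, affine)``: the intensity volume (per-class
    means x smooth multiplicative bias + Gaussian noise), the exact integer
    label volume, and the 4x4 voxel-to-world affine.  Deterministic given
    ``spec.seed``.
    """
    ax = grid_coords(spec.fov_mm, spec.resolution_mm)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    points = np.stack([x, y, z], axis=-1)
    labels = _labels_at(points, spec)

    lut = np.zeros(max(spec.intensity_means) + 1)
    for k, v in spec.intensity_means.items():
        lut[k] = v
    image = lut[labels]

    rng = np.random.default_rng(spec.seed)
    if spec.bias_amplitude > 0:
        coeff = rng.uniform(-1, 1, size=3)
        half = spec.fov_mm / 2
        bias = np.exp(
            spec.bias_amplitude * (coeff[0] * x + coeff[1] * y + coeff[2] * z) / half
        )
        image = image * bias
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    affine = np.diag([spec.resolution_mm] * 3 + [1.0])
    affine[:3, 3] = ax[0]  # first voxel center at -(n-1)/2 * res
    return image.astype(np.float64), labels, affine


@dataclass(frozen=True)
class PoseRanges:
    """Uniform sampling ranges for phantom pose (degrees / mm).

    The default varies the in-plane rotation of coronal slices (about the
    anterior-posterior axis, +/-45 degrees) plus small translations — the
    head-position variability regime the latent transform targets.
    """

    rot_x: tuple[float, float] = (0.0, 0.0)
    rot_y: tuple[float, float] = (-45.0, 45.0)
    rot_z: tuple[float, float] = (0.0, 0.0)
    trans: tuple[float, float] = (-0.7, 0.7)


def sample_spec(
    rng: np.random.Generator,
    resolution_mm: float,
    pose: PoseRanges = PoseRanges(),
    fov_mm: float = 20.0,
) -> PhantomSpec:
    """Draw one subject: jittered anatomy (so class frequencies vary across
    phantoms) plus a pose from the configured ranges."""
    # clearly anisotropic in-plane extents: head orientation stays
    # identifiable from a single slice at any rotation
    radii = tuple(r * rng.uniform(0.95, 1.05) for r in (7.2, 6.0, 5.6))
    rotation = (
        float(rng.uniform(*pose.rot_x)),
        float(rng.uniform(*pose.rot_y)),
        float(rng.uniform(*pose.rot_z)),
    )
    translation = tuple(float(rng.uniform(*pose.trans)) for _ in range(3))
    blobs = []
    for sign in (-1.0, 1.0):
        center = (
            sign * rng.uniform(2.3, 2.9),
            rng.uniform(-0.5, 0.5),
            rng.uniform(-0.5, 0.5),
        )
        blobs.append((center, float(rng.uniform(2.0, 2.5))))
    return PhantomSpec(
        radii_mm=radii,
        ribbon_thickness_mm=float(rng.uniform(2.1, 2.5)),
        fold_frequency=int(rng.integers(3, 6)),
        fold_amplitude_mm=float(rng.uniform(0.45, 0.65)),
        subcortical=tuple(blobs),
        rotation_deg=rotation,
        translation_mm=translation,
        resolution_mm=resolution_mm,
        fov_mm=fov_mm,
        seed=int(rng.integers(2 ** 31 - 1)),
    )


def make_cohort(
    n: int,
    resolutions=(0.5, 1.0),
    pose: PoseRanges = PoseRanges(),
    split_fractions=(0.7, 0.15, 0.15),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate a cohort manifest with balanced resolutions and disjoint
    train/val/test splits; optionally rasterize everything to NIfTI on disk.

    The manifest holds one row per subject (id, split, resolution, pose and
    the full JSON spec) and is itself written to ``out_dir/manifest.tsv``
    when an output directory is given.
    """
    if n < 3:
        raise ValueError("need at least 3 subjects for three splits")
    fr = np.asarray(split_fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise ValueError(f"split fractions must be 3 nonnegative numbers summing to 1, got {split_fractions}")
    rng = np.random.default_rng(seed)
    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)

    rows = []
    for i in range(n):
        res = float(resolutions[i % len(resolutions)])
        spec = sample_spec(rng, res, pose)
        rows.append(
            {
                "subject": f"sub-{i:03d}",
                "split": splits[i],
                "resolution_mm": res,
                "rot_deg": spec.rotation_deg,
                "spec_json": json.dumps(spec.to_dict()),
            }
        )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        from .io import write_volume  # local import to avoid a cycle

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row in rows:
            spec = PhantomSpec.from_dict(json.loads(row["spec_json"]))
            image, labels, affine = rasterize_phantom(spec)
            write_volume(out_dir / f"{row['subject']}_image.nii.gz", image, affine)
            write_volume(out_dir / f"{row['subject']}_labels.nii.gz", labels, affine)
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
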