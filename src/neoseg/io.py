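"""Volume, lookup-table, checkpoint and config I/O.

NIfTI volumes are read and written with nibabel; voxel spacing always comes
from the header and is never silently defaulted — the native-resolution
contract of the whole pipeline depends on it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .network import NetworkSpec, SegNet, build_network

__all__ = [
    "read_volume",
    "write_volume",
    "LookupTable",
    "read_lut",
    "write_lut",
    "default_phantom_lut",
    "save_checkpoint",
    "load_checkpoint",
    "read_config",
    "write_config",
]


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray, tuple[str, ...]]:
    """Load a NIfTI volume.

    Returns ``(array, spacing_mm, affine, orientation_codes)``.  Degenerate
    or missing header spacing raises; 1 mm is never assumed.
    """
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: header voxel spacing {zooms} is missing or degenerate")
    data = np.asanyarray(img.dataobj)
    axcodes = nib.aff2axcodes(img.affine)
    return data, tuple(float(z) for z in zooms), np.asarray(img.affine), axcodes


def write_volume(path, array: np.ndarray, affine: np.ndarray):
    """Write an array + affine as NIfTI; integer arrays keep an integer dtype."""
    arr = np.asarray(array)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int16)
    else:
        arr = arr.astype(np.float32)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
    img.header.set_zooms(np.abs(np.diag(affine)[:3]))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Lookup tables
# ---------------------------------------------------------------------------

LEFT_PREFIX = "Left-"
RIGHT_PREFIX = "Right-"


@dataclass(frozen=True)
class LookupTable:
    """Validated segmentation lookup table.

    ``names``/``colors`` index by label id; ``lateral_pairs`` maps each left
    id to its right counterpart; ``merge_map`` maps every full label id onto
    the merged (non-lateralized) id space used by the sagittal network.
    """

    names: dict[int, str]
    colors: dict[int, tuple[int, int, int]]
    lateral_pairs: dict[int, int]
    merge_map: dict[int, int]
    merged_names: dict[int, str]

    @property
    def ids(self) -> list[int]:
        return sorted(self.names)

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @property
    def n_merged(self) -> int:
        return len(self.merged_names)

    def merge_array(self) -> np.ndarray:
        """Vectorized full -> merged id lookup."""
        out = np.zeros(max(self.names) + 1, dtype=np.int64)
        for k, v in self.merge_map.items():
            out[k] = v
        return out


def _build_lut(frame: pd.DataFrame) -> LookupTable:
    ids = frame["id"].astype(int).tolist()
    names = frame["name"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate label ids in lookup table")
    if len(set(names)) != len(names):
        raise ValueError("duplicate label names in lookup table")
    name_by_id = dict(zip(ids, names))
    colors = {
        i: (int(r), int(g), int(b))
        for i, r, g, b in zip(ids, frame["R"], frame["G"], frame["B"])
    }
    # derive lateral pairs from the Left-/Right- name convention
    by_name = {n: i for i, n in name_by_id.items()}
    lateral_pairs: dict[int, int] = {}
    for i, n in name_by_id.items():
        if n.startswith(LEFT_PREFIX):
            partner = RIGHT_PREFIX + n[len(LEFT_PREFIX):]
            if partner not in by_name:
                raise ValueError(f"label {n!r} has no matching {partner!r}")
            lateral_pairs[i] = by_name[partner]
        elif n.startswith(RIGHT_PREFIX):
            partner = LEFT_PREFIX + n[len(RIGHT_PREFIX):]
            if partner not in by_name:
                raise ValueError(f"label {n!r} has no matching {partner!r}")
    merge_map: dict[int, int] = {}
    merged_names: dict[int, str] = {}
    base_to_merged: dict[str, int] = {}
    for i, n in name_by_id.items():
        base = n
        for prefix in (LEFT_PREFIX, RIGHT_PREFIX):
            if n.startswith(prefix):
                base = n[len(prefix):]
        if base not in base_to_merged:
            mid = len(base_to_merged)
            base_to_merged[base] = mid
            merged_names[mid] = base
        merge_map[i] = base_to_merged[base]
    return LookupTable(
        names=name_by_id,
        colors=colors,
        lateral_pairs=lateral_pairs,
        merge_map=merge_map,
        merged_names=merged_names,
    )


def read_lut(path) -> LookupTable:
    """Read a FreeSurfer-style tab-separated lookup table
    (columns: id, name, R, G, B)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "name", "R", "G", "B"}
    if not required.issubset(frame.columns):
        raise ValueError(f"lookup table must have columns {sorted(required)}, got {list(frame.columns)}")
    return _build_lut(frame)


def write_lut(path, names: dict[int, str], colors: dict[int, tuple[int, int, int]] | None = None):
    rng = np.random.default_rng(0)
    rows = []
    for i in sorted(names):
        color = colors[i] if colors else tuple(int(c) for c in rng.integers(0, 256, 3))
        rows.append({"id": i, "name": names[i], "R": color[0], "G": color[1], "B": color[2]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_phantom_lut() -> LookupTable:
    """The lookup table matching the synthetic phantom label protocol."""
    from .phantom import LABEL_NAMES

    frame = pd.DataFrame(
        [
            {"id": i, "name": n, "R": 30 * i % 256, "G": 90 * i % 256, "B": 150 * i % 256}
            for i, n in LABEL_NAMES.items()
        ]
    )
    return _build_lut(frame)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_checkpoint(net: SegNet, path, seed: int | None = None,
                    config: dict | None = None, train_state: dict | None = None):
    """Write weights + network spec + provenance as one ``.npz`` file."""
    meta = {
        "spec": net.spec.to_dict(),
        "seed": seed,
        "config": config or {},
        "config_hash": config_hash(config or {}),
        "train_state": train_state or {},
    }
    state = net.state_dict()
    blob = json.dumps(meta, default=str).encode()
    np.savez(str(path), __meta__=np.frombuffer(blob, dtype=np.uint8), **state)


def load_checkpoint(path, spec: NetworkSpec | None = None) -> tuple[SegNet, dict]:
    """Rebuild a network from a checkpoint.

    If ``spec`` is given it must match the stored spec exactly; a mismatch
    (e.g. loading scale-variant weights into an affine-variant spec) is
    refused.
    """
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    stored_spec = NetworkSpec.from_dict(meta["spec"])
    if spec is not None and spec != stored_spec:
        raise ValueError(
            f"checkpoint spec mismatch: stored {stored_spec} vs requested {spec}"
        )
    net = build_network(stored_spec)
    net.load_state_dict(state)
    return net, meta


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Flat key/value config (YAML syntax, one level)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def write_config(path, cfg: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
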