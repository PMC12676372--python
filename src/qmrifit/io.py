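"""File I/O: NIfTI volumes, HDF5 k-space containers, edge lists, YAML configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core import AcquisitionGrid, BoundSpec, ValidationError
from .regularizers import GraphAdjacency

__all__ = [
    "load_config",
    "read_edge_list",
    "read_kspace",
    "read_volume",
    "write_edge_list",
    "write_kspace",
    "write_volume",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_volume(path, data, affine=None) -> None:
    affine = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_edge_list(path, n_vertices=None) -> GraphAdjacency:
    """Two-column whitespace-separated 0-based integer edge list.

    Strictly 0-based — no 1-based auto-detection; a negative index or a
    non-integer token is an error naming the offending line.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-integer vertex index") from None
            edges.append((i, j))
    return GraphAdjacency.from_edges(np.asarray(edges, dtype=int).reshape(-1, 2), n_vertices)


def write_edge_list(path, adjacency: GraphAdjacency) -> None:
    np.savetxt(path, adjacency.edges, fmt="%d")


def write_kspace(path, kspace, coils, mask_u) -> None:
    """Store complex k-space, coil maps and the sampling mask in HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(kspace, dtype=complex))
        f.create_dataset("coils", data=np.asarray(coils, dtype=complex))
        f.create_dataset("mask_u", data=np.asarray(mask_u, dtype=bool))


def read_kspace(path):
    with h5py.File(path, "r") as f:
        return f["kspace"][()], f["coils"][()], f["mask_u"][()]


_CONFIG_KEYS = {
    "model", "grid", "bounds", "init", "options", "regularizers", "seed",
    "noise_sd", "algorithm", "output",
}


def load_config(path) -> dict:
    """Load a run config (YAML); unknown top-level keys are an error."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "grid" in cfg:
        cfg["grid"] = AcquisitionGrid({k: np.asarray(v, dtype=float) for k, v in cfg["grid"].items()})
    if "bounds" in cfg:
        cfg["bounds"] = BoundSpec({k: tuple(v) for k, v in cfg["bounds"].items()})
    return cfg
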