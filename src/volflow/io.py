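"""Volume file I/O and run manifests.

Supported volume formats: NIfTI-1 (``.nii`` / ``.nii.gz``, via nibabel) and
NumPy archives (``.npz`` with a ``volume`` array and optional ``spacing``).
Values round-trip exactly for integer-valued data; voxel spacing is carried
when the format stores it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .errors import ShapeError, VolflowError


@dataclass
class VolumeRecord:
    """A 3D volume plus its acquisition metadata."""

    data: np.ndarray                       # (w, h, d)
    voxel_spacing: Optional[tuple] = None  # (sx, sy, sz) in mm
    source_path: Optional[str] = None
    intensity_units: str = "HU"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(
                f"VolumeRecord expects a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_spacing is not None:
            self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
            if any(s <= 0 for s in self.voxel_spacing):
                raise ValueError("voxel spacing must be positive")


def read_volume(path) -> VolumeRecord:
    """Read a NIfTI or NPZ volume file into a :class:`VolumeRecord`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ShapeError(f"{path}: expected 3D payload, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return VolumeRecord(np.asarray(data), spacing, str(path))
    if name.endswith(".npz"):
        with np.load(path) as archive:
            if "volume" not in archive:
                raise VolflowError(f"{path}: NPZ archive lacks a 'volume' array")
            data = archive["volume"]
            if data.ndim != 3:
                raise ShapeError(f"{path}: expected 3D payload, got shape {data.shape}")
            spacing = tuple(archive["spacing"]) if "spacing" in archive else None
        return VolumeRecord(data, spacing, str(path))
    raise VolflowError(f"unrecognized volume format: {path.name}")


def write_volume(record: VolumeRecord, path) -> None:
    """Write a volume to NIfTI or NPZ, creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        spacing = record.voxel_spacing or (1.0, 1.0, 1.0)
        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(record.data, affine), str(path))
    elif name.endswith(".npz"):
        arrays = {"volume": record.data}
        if record.voxel_spacing is not None:
            arrays["spacing"] = np.asarray(record.voxel_spacing)
        np.savez(path, **arrays)
    else:
        raise VolflowError(f"unrecognized volume format: {path.name}")


def load_volume_dir(directory, suffixes=(".nii", ".nii.gz", ".npz")) -> list:
    """All volumes in a directory, sorted by filename for determinism."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.name.lower().endswith(tuple(suffixes)))
    if not paths:
        raise VolflowError(f"no volume files found in {directory}")
    return [read_volume(p) for p in paths]


def file_sha256(path, limit_bytes: int = 1 << 26) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        while chunk := f.read(1 << 20):
            h.update(chunk)
            if f.tell() > limit_bytes:
                break
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    command: str
    config: dict
    seed: Optional[int]
    package_version: str
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timestamp: str = ""

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "package_version": self.package_version,
            "input_hashes": self.input_hashes,
            "outputs": self.outputs,
            "timestamp": self.timestamp or time.strftime(
                "%Y-%m-%dT%H:%M:%S", time.gmtime()),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
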