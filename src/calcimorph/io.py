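"""NIfTI-1 volume I/O, CSV round-trips, configuration and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import DimensionalityError
from .grids import AttenuationVolume, BinaryMask, ClusterLabelMap
from .phantoms import AttenuationParams, CohortConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_label_map",
    "write_label_map",
    "load_config",
    "config_to_dict",
    "sha256_digest",
]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _grid_from(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return spacing, origin


def _load_3d(path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise DimensionalityError(
            f"{path}: expected a single 3D volume, got shape {shape}"
        )
    return img


def read_volume(path) -> AttenuationVolume:
    """Read a 3D attenuation volume; anisotropic spacing is preserved."""
    img = _load_3d(path)
    spacing, origin = _grid_from(img)
    return AttenuationVolume(
        values=np.asanyarray(img.dataobj).astype(np.float32),
        voxel_spacing_mm=spacing,
        origin_mm=origin,
    )


def write_volume(volume: AttenuationVolume, path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float32),
        _affine(volume.voxel_spacing_mm, volume.origin_mm),
    )
    img.header.set_zooms(volume.voxel_spacing_mm)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    img = _load_3d(path)
    spacing, origin = _grid_from(img)
    return BinaryMask(
        values=np.asanyarray(img.dataobj) > 0,
        voxel_spacing_mm=spacing,
        origin_mm=origin,
    )


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.voxel_spacing_mm, mask.origin_mm)
    )
    nib.save(img, str(path))


def read_label_map(path, connectivity: int = 26) -> ClusterLabelMap:
    img = _load_3d(path)
    spacing, origin = _grid_from(img)
    return ClusterLabelMap(
        labels=np.asanyarray(img.dataobj).astype(np.int32),
        connectivity=connectivity,
        voxel_spacing_mm=spacing,
        origin_mm=origin,
    )


def write_label_map(labels: ClusterLabelMap, path) -> None:
    img = nib.Nifti1Image(
        labels.labels.astype(np.int32),
        _affine(labels.voxel_spacing_mm, labels.origin_mm),
    )
    nib.save(img, str(path))


def load_config(path) -> dict:
    """Load a JSON or YAML pipeline configuration document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def cohort_config_from_dict(doc: dict) -> CohortConfig:
    """Build a CohortConfig from a mapping mirroring its field names."""
    kwargs = dict(doc)
    if "attenuation_params" in kwargs and isinstance(kwargs["attenuation_params"], dict):
        kwargs["attenuation_params"] = AttenuationParams(**kwargs["attenuation_params"])
    return CohortConfig(**kwargs)


def config_to_dict(config: CohortConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["target_spearman"] = np.asarray(config.target_spearman).tolist()
    return doc


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
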