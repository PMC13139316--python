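"""Grid containers: attenuation volumes, binary masks and cluster label maps.

All containers share the same grid contract: a 3D array, per-axis voxel
spacing in millimetres, and the world coordinate (mm) of the centre of
voxel (0, 0, 0).  World coordinates of voxel (i, j, k) are
``origin + index * spacing`` with 0-based indices and no axis flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GridMismatchError, IntegrityError

__all__ = [
    "AttenuationVolume",
    "BinaryMask",
    "ClusterLabelMap",
    "check_same_grid",
]

_CONNECTIVITIES = (6, 18, 26)


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class _Grid:
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxel_spacing_mm = _as_triple(self.voxel_spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing_mm}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World-mm centres for an (n, 3) array of voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.voxel_spacing_mm)


@dataclass
class AttenuationVolume(_Grid):
    """3D scalar attenuation field in Hounsfield units."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1)))

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("attenuation values must be a non-empty 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "AttenuationVolume":
        return replace(self, values=values)


@dataclass
class BinaryMask(_Grid):
    """3D boolean grid on the same lattice as its source volume."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=bool))

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask values must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return replace(self, values=values)


@dataclass
class ClusterLabelMap(_Grid):
    """Integer-labelled 3D grid: 0 = background, 1..K = clusters.

    Labels are consecutive, ordered by decreasing component volume with
    ties broken by the lexicographically smallest voxel index, so output
    is deterministic across runs and platforms.
    """

    labels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.int32))
    connectivity: int = 26

    def __post_init__(self):
        super().__post_init__()
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.connectivity not in _CONNECTIVITIES:
            raise ValueError(f"connectivity must be one of {_CONNECTIVITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    def validate(self) -> None:
        """Check the label-consecutiveness invariant; raise IntegrityError."""
        present = np.unique(self.labels)
        present = present[present > 0]
        if self.labels.min(initial=0) < 0:
            raise IntegrityError("negative labels present")
        expected = np.arange(1, len(present) + 1)
        if not np.array_equal(present, expected):
            raise IntegrityError(
                f"labels are not consecutive 1..K: found {present.tolist()}"
            )


def check_same_grid(a, b, what: str = "grids") -> None:
    """Raise GridMismatchError unless a and b share shape, spacing and origin."""
    if a.shape != b.shape:
        raise GridMismatchError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.voxel_spacing_mm, b.voxel_spacing_mm):
        raise GridMismatchError(
            f"{what}: spacing mismatch {a.voxel_spacing_mm} vs {b.voxel_spacing_mm}"
        )
    if not np.allclose(a.origin_mm, b.origin_mm):
        raise GridMismatchError(f"{what}: origin mismatch {a.origin_mm} vs {b.origin_mm}")
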