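import numpy as np
import pandas as pd
import pytest

from calcimorph.phantoms import CohortConfig, generate_cohort
from calcimorph.segmentation import (
    label_components,
    morphological_clean,
    threshold_calcium,
)
from calcimorph.morphometry import compute_cluster_features


def make_ball(radius_voxels: int, spacing: float = 1.0, pad: int = 2) -> np.ndarray:
    """Boolean ball of the given radius in voxels, centred in its grid."""
    n = 2 * radius_voxels + 1 + 2 * pad
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n))
    r2 = sum((idx[d] - c) ** 2 for d in range(3))
    return r2 <= radius_voxels**2


def make_ellipsoid(semi_axes_voxels, pad: int = 2) -> np.ndarray:
    """Boolean axis-aligned ellipsoid with semi-axes in voxel units."""
    semi = np.asarray(semi_axes_voxels, dtype=float)
    shape = (2 * np.ceil(semi).astype(int) + 1 + 2 * pad).tolist()
    c = (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape)
    q = sum(((idx[d] - c[d]) / semi[d]) ** 2 for d in range(3))
    return q <= 1.0


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-plaque phantom cohort shared across tests (generation is the
    expensive step; all consumers treat it as read-only)."""
    config = CohortConfig(n_plaques=12, seed=42)
    volumes, truth = generate_cohort(config)
    return config, volumes, truth


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    config, volumes, truth = small_cohort
    frames = []
    for pid, vol in zip(truth["plaque_id"].unique(), volumes):
        labels = label_components(morphological_clean(threshold_calcium(vol)))
        frames.append(compute_cluster_features(labels, vol, plaque_id=pid))
    return pd.concat(frames, ignore_index=True)
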