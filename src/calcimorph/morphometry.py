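"""Per-cluster geometric and density descriptors, and per-plaque aggregates.

Descriptors per cluster:

* volume (mm³) — voxel count × voxel volume, exact by construction;
* maximum / minimum linear dimension (mm) from a near-minimal oriented
  bounding box, and their ratio (aspect ratio, overall elongation);
* eccentricity — an elongation index from the inertia tensor of the
  voxel centres, sqrt(λ1/λ3) − 1 with λ1 ≥ λ2 ≥ λ3 the eigenvalues of
  the second central moment.  Zero for a sphere; unlike aspect ratio it
  responds to local surface asymmetries (lobes, protrusions) because
  every voxel contributes to the moments, not only the extremes;
* compactness — a sphere-normalised surface/volume index
  A^{3/2} / (6 √π V) with A from a marching-cubes isosurface: exactly 1
  for a continuum sphere, larger for any other shape;
* mean attenuation μ (HU) and attenuation heterogeneity σ (HU, sample
  SD with the n−1 denominator; single-voxel clusters report σ = 0);
* centroid in world millimetres.

Eccentricity and compactness ranges in clinical cohorts exceed the
[0, 1) range of the classical ellipse eccentricity and sphericity
indices; both formulas here are elongation/irregularity indices on open
scales (0 and 1 at the sphere limit respectively) chosen to match that
behaviour.  See docs/methods.md for the full rationale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .errors import IntegrityError
from .grids import AttenuationVolume, ClusterLabelMap, check_same_grid

__all__ = [
    "FEATURE_COLUMNS",
    "PLAQUE_COLUMNS",
    "oriented_bounding_box",
    "eccentricity",
    "compactness",
    "attenuation_stats",
    "compute_cluster_features",
    "aggregate_plaques",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "plaque_id",
    "cluster_id",
    "volume_mm3",
    "dim_max_mm",
    "dim_min_mm",
    "aspect_ratio",
    "eccentricity",
    "compactness",
    "mu_hu",
    "sigma_hu",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "n_voxels",
]

PLAQUE_COLUMNS = [
    "plaque_id",
    "n_clusters",
    "total_volume_mm3",
    "mean_cluster_volume_mm3",
    "mean_eccentricity",
    "mean_compactness",
    "mean_mu_hu",
    "mean_sigma_hu",
    "is_multi",
]


def _pca_frame(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    return vecs  # columns orthonormal


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _extents(points: np.ndarray, frame: np.ndarray) -> np.ndarray:
    proj = points @ frame
    return proj.max(axis=0) - proj.min(axis=0)


def _min_rect_frame(points: np.ndarray, normal: np.ndarray) -> np.ndarray | None:
    """Frame (columns) whose third axis is `normal` and whose in-plane axes
    minimise the 2D bounding-rectangle area of the projected points.

    The optimal rectangle of a convex polygon is aligned with one of its
    edges (rotating-calipers argument), so only hull-edge directions are
    scanned.
    """
    u, v = _plane_basis(normal)
    q = points @ np.column_stack([u, v])
    spread = q.max(axis=0) - q.min(axis=0)
    if np.any(spread < 1e-12):  # degenerate projection: any in-plane frame works
        return np.column_stack([u, v, normal / np.linalg.norm(normal)])
    try:
        hull2 = ConvexHull(q)
    except QhullError:
        return np.column_stack([u, v, normal / np.linalg.norm(normal)])
    verts = q[hull2.vertices]
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    lengths = np.linalg.norm(edges, axis=1)
    edges = edges[lengths > 1e-12] / lengths[lengths > 1e-12, None]
    best_area, best = np.inf, None
    for c, s in edges:
        e1 = np.array([c, s])
        e2 = np.array([-s, c])
        w = np.ptp(q @ e1)
        h = np.ptp(q @ e2)
        if w * h < best_area:
            best_area = w * h
            best = (e1, e2)
    e1, e2 = best
    a1 = e1[0] * u + e1[1] * v
    a2 = e2[0] * u + e2[1] * v
    n = normal / np.linalg.norm(normal)
    return np.column_stack([a1, a2, n])


def oriented_bounding_box(
    voxel_centers: np.ndarray, spacing: tuple[float, float, float] | float = 1.0
) -> tuple[float, float, float]:
    """Near-minimal oriented bounding-box dimensions (mm), sorted descending.

    Candidate orientations are the grid axes, the principal-component
    frame, and for each convex-hull facet normal the frame pairing that
    normal with the in-plane rotation minimising the 2D footprint; the
    minimum-volume box wins.  Each extent is padded by one mean voxel
    spacing, so a single voxel has positive dimensions and a defined
    aspect ratio.
    """
    pts = np.atleast_2d(np.asarray(voxel_centers, dtype=float))
    if pts.size == 0:
        raise ValueError("oriented_bounding_box requires at least one point")
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    pad = float(np.mean(np.broadcast_to(np.asarray(spacing, dtype=float), (3,))))

    frames: list[np.ndarray] = [np.eye(3), _pca_frame(pts)]
    if len(pts) >= 4:
        try:
            hull = ConvexHull(pts)
            hull_pts = pts[hull.vertices]
            normals = hull.equations[:, :3]
            # deduplicate near-parallel facet normals to bound the scan
            seen: list[np.ndarray] = []
            for nrm in normals:
                nrm = nrm / np.linalg.norm(nrm)
                if any(abs(nrm @ s) > 1 - 1e-9 for s in seen):
                    continue
                seen.append(nrm)
                frame = _min_rect_frame(hull_pts, nrm)
                if frame is not None:
                    frames.append(frame)
        except QhullError:
            pass
    hull_eval = pts if len(pts) < 4 else None

    best_vol, best_ext = np.inf, None
    eval_pts = hull_eval if hull_eval is not None else pts
    for frame in frames:
        ext = _extents(eval_pts, frame)
        vol = float(np.prod(ext + pad))
        if vol < best_vol:
            best_vol, best_ext = vol, ext
    dims = np.sort(best_ext + pad)[::-1]
    return (float(dims[0]), float(dims[1]), float(dims[2]))


def eccentricity(
    voxel_centers: np.ndarray, spacing: tuple[float, float, float] | float = 1.0
) -> float:
    """Inertia-tensor elongation index sqrt(λ1/λ3) − 1; 0 for a sphere.

    The per-voxel self-moment spacing²/12 per axis is always included:
    it is the exact second moment of a voxel's own cube of material and
    regularises single-voxel and planar clusters (λ3 > 0 always).
    """
    pts = np.atleast_2d(np.asarray(voxel_centers, dtype=float))
    if pts.size == 0:
        raise ValueError("eccentricity requires at least one point")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts) + np.diag(sp**2 / 12.0)
    lam = np.linalg.eigvalsh(cov)
    return float(np.sqrt(lam[-1] / lam[0]) - 1.0)


def _voxel_face_area(component: np.ndarray, spacing: np.ndarray) -> float:
    area = 0.0
    face = [spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1]]
    padded = np.pad(component, 1)
    for ax in range(3):
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += np.count_nonzero(diff) * face[ax]
    return float(area)


def compactness(
    component_mask: np.ndarray, spacing: tuple[float, float, float] | float = 1.0
) -> float:
    """Sphere-normalised surface index A^{3/2} / (6 √π V); 1 for a sphere.

    The surface area A comes from a marching-cubes isosurface at the 0.5
    level of the (zero-padded) indicator field.  Components thinner than
    2 voxels along some axis cannot be meshed reliably; they fall back
    to the summed exposed voxel-face area with a logged warning.
    """
    comp = np.asarray(component_mask).astype(bool)
    n_vox = int(comp.sum())
    if n_vox == 0:
        raise ValueError("compactness requires a non-empty component")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    volume = n_vox * float(np.prod(sp))

    bbox_extent = [int(a.max() - a.min() + 1) for a in np.nonzero(comp)]
    if min(bbox_extent) < 2:
        logger.warning(
            "component thinner than 2 voxels along an axis; "
            "falling back to voxel-face surface area"
        )
        area = _voxel_face_area(comp, sp)
    else:
        padded = np.pad(comp, 1).astype(np.float32)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
        area = float(measure.mesh_surface_area(verts, faces))
    return float(area**1.5 / (6.0 * np.sqrt(np.pi) * volume))


def attenuation_stats(
    component_mask: np.ndarray, volume: AttenuationVolume | np.ndarray
) -> tuple[float, float]:
    """Cluster mean attenuation μ and heterogeneity σ (sample SD, n−1).

    Single-voxel components report σ = 0 by convention.
    """
    comp = np.asarray(component_mask).astype(bool)
    values = volume.values if isinstance(volume, AttenuationVolume) else np.asarray(volume)
    if comp.shape != values.shape:
        raise IntegrityError(
            f"component mask shape {comp.shape} != volume shape {values.shape}"
        )
    hu = values[comp]
    if hu.size == 0:
        raise ValueError("attenuation_stats requires a non-empty component")
    mu = float(hu.mean())
    sigma = 0.0 if hu.size == 1 else float(hu.std(ddof=1))
    return mu, sigma


@dataclass
class _Component:
    label: int
    slices: tuple[slice, slice, slice]
    mask: np.ndarray  # cropped


def _iter_components(labels: ClusterLabelMap):
    objects = ndimage.find_objects(labels.labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            raise IntegrityError(f"label {k} missing (labels not consecutive)")
        yield _Component(k, sl, labels.labels[sl] == k)


def compute_cluster_features(
    labels: ClusterLabelMap,
    volume: AttenuationVolume,
    plaque_id: str = "P001",
    validate: bool = True,
) -> pd.DataFrame:
    """One feature row per labelled cluster, ordered by label.

    With ``validate`` (default) the label map's structural invariants
    are re-checked: labels consecutive 1..K and each label a single
    connected component under the map's stated connectivity.
    """
    check_same_grid(labels, volume, "labels vs volume")
    if validate:
        labels.validate()
    sp = np.asarray(labels.voxel_spacing_mm)
    vox_vol = labels.voxel_volume_mm3
    rows = []
    for comp in _iter_components(labels):
        if validate:
            from .segmentation import _CONN_RANK  # local import avoids cycle

            n_sub = measure.label(
                comp.mask, connectivity=_CONN_RANK[labels.connectivity]
            ).max()
            if n_sub != 1:
                raise IntegrityError(
                    f"label {comp.label} splits into {n_sub} connected components"
                )
        idx = np.argwhere(comp.mask) + [s.start for s in comp.slices]
        centers = labels.world_coordinates(idx)
        dmax, _dmid, dmin = oriented_bounding_box(centers, labels.voxel_spacing_mm)
        mu, sigma = attenuation_stats(comp.mask, volume.values[comp.slices])
        centroid = centers.mean(axis=0)
        n_vox = int(comp.mask.sum())
        rows.append(
            {
                "plaque_id": plaque_id,
                "cluster_id": comp.label,
                "volume_mm3": n_vox * vox_vol,
                "dim_max_mm": dmax,
                "dim_min_mm": dmin,
                "aspect_ratio": dmax / dmin,
                "eccentricity": eccentricity(centers, sp),
                "compactness": compactness(comp.mask, sp),
                "mu_hu": mu,
                "sigma_hu": sigma,
                "centroid_x_mm": centroid[0],
                "centroid_y_mm": centroid[1],
                "centroid_z_mm": centroid[2],
                "n_voxels": n_vox,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def aggregate_plaques(features: pd.DataFrame) -> pd.DataFrame:
    """Per-plaque aggregation: counts, totals, means, single-vs-multi flag."""
    if features.empty:
        return pd.DataFrame(columns=PLAQUE_COLUMNS)
    grouped = features.groupby("plaque_id", sort=True)
    out = pd.DataFrame(
        {
            "n_clusters": grouped.size(),
            "total_volume_mm3": grouped["volume_mm3"].sum(),
            "mean_cluster_volume_mm3": grouped["volume_mm3"].mean(),
            "mean_eccentricity": grouped["eccentricity"].mean(),
            "mean_compactness": grouped["compactness"].mean(),
            "mean_mu_hu": grouped["mu_hu"].mean(),
            "mean_sigma_hu": grouped["sigma_hu"].mean(),
        }
    ).reset_index()
    out["is_multi"] = out["n_clusters"] >= 2
    return out[PLAQUE_COLUMNS]
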