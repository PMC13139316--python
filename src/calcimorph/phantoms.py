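"""Synthetic CT phantom cohorts of calcified plaque clusters.

Generates attenuation volumes with known ground truth so that every
downstream stage — thresholding, labelling, morphometry, statistics —
can be validated without clinical data.  Each plaque is a small HU grid
containing 1–4 ellipsoidal calcification clusters (optionally lobed to
create local surface asymmetry), each with a dense core and less dense
periphery realised as a linear attenuation ramp on normalised interior
depth, on a soft-tissue background, plus Gaussian noise.

Cross-cluster statistical structure (the couplings between cluster
volume, elongation and core attenuation) is imposed with a Gaussian
copula: target Spearman rank correlations are converted to Pearson
correlations via r = 2 sin(π ρs / 6) (exact for bivariate normal
margins), a multivariate normal sample is drawn, and each column is
mapped through its marginal quantile function.  Because the mapping is
strictly monotone per column, the target rank correlations survive any
choice of marginals.

Ground-truth axis lengths are FULL axis lengths (2 x semi-axes), so
they compare directly with oriented-bounding-box dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConfigurationError, GeometryError
from .grids import AttenuationVolume, BinaryMask

__all__ = [
    "CohortConfig",
    "GROUND_TRUTH_COLUMNS",
    "spearman_to_pearson",
    "sample_coupled_parameters",
    "build_cluster_mask",
    "fill_attenuation",
    "generate_cohort",
]

GROUND_TRUTH_COLUMNS = [
    "plaque_id",
    "cluster_id",
    "true_volume_mm3",
    "true_axis_a_mm",
    "true_axis_b_mm",
    "true_axis_c_mm",
    "true_center_x_mm",
    "true_center_y_mm",
    "true_center_z_mm",
    "true_core_hu",
    "true_edge_hu",
    "n_lobes",
]

_PARAM_NAMES = ("volume", "elongation", "core_hu")


def _default_target_spearman() -> np.ndarray:
    # couplings over (volume, elongation, core attenuation)
    return np.array(
        [
            [1.0, 0.8, 0.5],
            [0.8, 1.0, 0.4],
            [0.5, 0.4, 1.0],
        ]
    )


@dataclass
class AttenuationParams:
    """Attenuation model: per-cluster core HU marginal, fixed periphery/background."""

    core_hu_median: float = 560.0
    core_hu_sigma: float = 250.0
    core_hu_bounds: tuple[float, float] = (300.0, 1200.0)
    edge_hu: float = 250.0
    noise_sd_hu: float = 20.0
    background_hu: float = 60.0


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a clinical carotid CTA cohort: 107 plaques, 81%
    single-cluster (probabilities over counts 1..4), lognormal cluster
    volumes with median ~172 mm³ and wide IQR (truncated to what fits a
    96³ x 0.6 mm grid), elongation uniform on [1.2, 3.5] (median ~2.3),
    dense cores around 560 HU ramping to a 250 HU periphery so cluster
    mean attenuation lands near 400 HU, and planted Spearman couplings
    {volume-elongation 0.8, volume-core 0.5, elongation-core 0.4}.
    """

    n_plaques: int = 107
    cluster_count_probs: tuple[float, ...] = (0.81, 0.12, 0.05, 0.02)
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    target_spearman: np.ndarray = field(default_factory=_default_target_spearman)
    volume_lognormal_params: tuple[float, float] = (5.150, 1.687)
    volume_bounds_mm3: tuple[float, float] = (5.0, 1500.0)
    elongation_range: tuple[float, float] = (1.2, 3.5)
    attenuation_params: AttenuationParams = field(default_factory=AttenuationParams)
    lobe_count_probs: tuple[float, ...] = (0.7, 0.2, 0.1)
    lobe_offset_frac: float = 0.35
    multi_size_bias: float = 2.5
    hu_threshold: float = 130.0
    seed: int = 0

    def __post_init__(self):
        self.target_spearman = np.asarray(self.target_spearman, dtype=float)
        for name, probs in (
            ("cluster_count_probs", self.cluster_count_probs),
            ("lobe_count_probs", self.lobe_count_probs),
        ):
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be non-negative and sum to 1")
        ts = self.target_spearman
        if ts.ndim != 2 or ts.shape[0] != ts.shape[1]:
            raise ConfigurationError("target_spearman must be square")
        if not np.allclose(ts, ts.T) or not np.allclose(np.diag(ts), 1.0):
            raise ConfigurationError("target_spearman must be symmetric with unit diagonal")
        if np.any(np.abs(ts) > 1):
            raise ConfigurationError("target_spearman entries must lie in [-1, 1]")
        _copula_correlation(ts, names=_PARAM_NAMES)  # raises if not positive definite
        ap = self.attenuation_params
        if isinstance(ap, dict):
            ap = self.attenuation_params = AttenuationParams(**ap)
        if not ap.background_hu < self.hu_threshold:
            raise ConfigurationError(
                "background HU must be strictly below the segmentation threshold"
            )
        if not min(ap.core_hu_bounds) > self.hu_threshold:
            raise ConfigurationError(
                "core HU must be strictly above the segmentation threshold"
            )
        if self.n_plaques < 1:
            raise ConfigurationError("n_plaques must be >= 1")


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Gaussian-copula conversion r = 2 sin(π ρs / 6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def _copula_correlation(
    target_spearman: np.ndarray, names: Sequence[str] | None = None
) -> np.ndarray:
    r = spearman_to_pearson(target_spearman)
    np.fill_diagonal(r, 1.0)
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        pair = _offending_pair(r, names)
        raise ConfigurationError(
            "implied Gaussian-copula correlation matrix is not positive definite; "
            f"offending pair: {pair}"
        ) from None
    return r


def _offending_pair(r: np.ndarray, names: Sequence[str] | None) -> str:
    k = r.shape[0]
    names = list(names) if names is not None else [f"var{i}" for i in range(k)]
    if len(names) != k:
        names = [f"var{i}" for i in range(k)]
    best = None
    for i in range(k):
        for j in range(i + 1, k):
            trial = r.copy()
            trial[i, j] = trial[j, i] = 0.0
            try:
                np.linalg.cholesky(trial)
                return f"({names[i]}, {names[j]})"
            except np.linalg.LinAlgError:
                if best is None or abs(r[i, j]) > abs(r[best[0], best[1]]):
                    best = (i, j)
    i, j = best if best is not None else (0, 1)
    return f"({names[i]}, {names[j]})"


def sample_coupled_parameters(
    n: int,
    target_spearman: np.ndarray,
    marginals: Sequence[Callable[[np.ndarray], np.ndarray]],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n rows with the target Spearman structure via a Gaussian copula.

    ``marginals`` are quantile functions (inverse CDFs) applied to the
    copula's uniform coordinates; each must be strictly increasing so
    ranks — and hence the Spearman structure — are preserved.
    """
    ts = np.asarray(target_spearman, dtype=float)
    k = ts.shape[0]
    if len(marginals) != k:
        raise ValueError("need one marginal quantile function per variable")
    r = _copula_correlation(ts)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(r)
    z = rng.standard_normal((n, k)) @ chol.T
    u = stats.norm.cdf(z)
    cols = [np.asarray(marginals[j](u[:, j]), dtype=float) for j in range(k)]
    return np.column_stack(cols)


def _voxel_center_grids(shape, spacing, origin):
    axes = [origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(shape, spacing, origin, center, semi_axes, axes_order=(0, 1, 2)):
    """Boolean grid of an axis-aligned ellipsoid; semi-axes permuted onto grid axes."""
    gx, gy, gz = _voxel_center_grids(shape, spacing, origin)
    semi = np.asarray(semi_axes, dtype=float)[list(axes_order)]
    q = (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    )
    return q <= 1.0


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def build_cluster_mask(
    axis_lengths_mm: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    n_lobes: int = 1,
    lobe_offset_frac: float = 0.35,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    voxel_spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6),
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int | np.random.Generator = 0,
    axes_order: tuple[int, int, int] = (0, 1, 2),
) -> BinaryMask:
    """Union of a primary ellipsoid and ``n_lobes - 1`` offset sub-lobes.

    ``axis_lengths_mm`` are semi-axes a >= b >= c of the primary
    ellipsoid.  Additional lobes are scaled by 0.6 and displaced by
    ``lobe_offset_frac * a`` along seeded random directions; the union
    is guaranteed a single 26-connected component (directions are
    redrawn on the rare failure).  Lobes create the local surface
    asymmetries that raise eccentricity without changing aspect ratio
    much.
    """
    a, b, c = (float(v) for v in axis_lengths_mm)
    if not (a >= b >= c > 0):
        raise ValueError(f"axis lengths must satisfy a >= b >= c > 0, got {(a, b, c)}")
    if n_lobes < 1:
        raise ValueError("n_lobes must be >= 1")
    shape = tuple(int(s) for s in grid_shape)
    spacing = np.broadcast_to(np.asarray(voxel_spacing_mm, dtype=float), (3,))
    origin = np.broadcast_to(np.asarray(origin_mm, dtype=float), (3,))
    center = np.asarray(center_mm, dtype=float)

    # reach = primary semi-axis + worst-case lobe excursion
    reach = a * (1.0 + (lobe_offset_frac + 0.6 if n_lobes > 1 else 0.0))
    lo = origin + spacing  # >= 1 voxel margin
    hi = origin + (np.asarray(shape) - 2) * spacing
    if np.any(center - reach < lo) or np.any(center + reach > hi):
        raise GeometryError(
            "cluster (including lobes) does not fit inside the grid with a "
            "1-voxel margin; enlarge the grid or shrink the cluster"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = _ellipsoid_mask(shape, spacing, origin, center, (a, b, c), axes_order)
    if not base.any():
        raise GeometryError("ellipsoid too small to cover any voxel centre")
    for _ in range(n_lobes - 1):
        for _attempt in range(20):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            lobe_center = center + lobe_offset_frac * a * direction
            lobe = _ellipsoid_mask(
                shape, spacing, origin, lobe_center,
                (0.6 * a, 0.6 * b, 0.6 * c), axes_order,
            )
            candidate = base | lobe
            _, n_comp = ndimage.label(candidate, structure=_STRUCT26)
            if n_comp == 1:
                base = candidate
                break
        else:
            raise GeometryError("could not place a connected lobe after 20 attempts")
    return BinaryMask(values=base, voxel_spacing_mm=tuple(spacing), origin_mm=tuple(origin))


def _depth_ramp(mask_values: np.ndarray, spacing) -> np.ndarray:
    """Depth-ordered ramp in (0, 1): ~0 at the surface, ~1 at the deepest
    interior voxel of each connected component.

    The ramp is the within-component quantile (average-tie rank) of the
    Euclidean interior depth — equal-volume shells rather than a linear
    function of raw depth.  Monotone in depth, so the dense-core /
    light-periphery gradient is preserved, while every component's ramp
    averages exactly 1/2: a cluster's mean attenuation becomes
    (edge + core)/2 independent of its size, elongation or voxelization,
    which keeps the attenuation readout faithful to the sampled core
    density across the whole size range.  A raw-depth ramp instead makes
    small, coarsely voxelized components read systematically core-like.
    """
    depth = ndimage.distance_transform_edt(mask_values, sampling=spacing)
    labels, n = ndimage.label(mask_values, structure=_STRUCT26)
    out = np.zeros_like(depth)
    for k in range(1, n + 1):
        sel = labels == k
        d = depth[sel]
        out[sel] = (stats.rankdata(d, method="average") - 0.5) / d.size
    return out


def fill_attenuation(
    mask: BinaryMask,
    mu_core: float,
    mu_edge: float,
    noise_sd: float,
    background: float,
    seed: int | np.random.Generator = 0,
) -> AttenuationVolume:
    """Attenuation volume with a dense core and less dense periphery.

    Inside the mask HU rises monotonically with interior depth from
    ``mu_edge`` at the surface to ``mu_core`` at the deepest voxel of
    each component (mineralised cores are denser than recently
    deposited peripheral mineral), following the equal-volume-shell
    depth ramp of :func:`_depth_ramp`; outside, HU = ``background``.
    Gaussian noise of SD ``noise_sd`` is added everywhere.
    """
    if not (mu_core >= mu_edge > background):
        raise ValueError("require mu_core >= mu_edge > background")
    if not mask.values.any():
        raise ValueError("fill_attenuation requires a non-empty mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ramp = _depth_ramp(mask.values, mask.voxel_spacing_mm)
    hu = np.full(mask.shape, float(background))
    hu[mask.values] = mu_edge + (mu_core - mu_edge) * ramp[mask.values]
    if noise_sd > 0:
        hu = hu + rng.normal(0.0, noise_sd, size=mask.shape)
    return AttenuationVolume(
        values=hu, voxel_spacing_mm=mask.voxel_spacing_mm, origin_mm=mask.origin_mm
    )


def _truncated_quantile(ppf, lo: float, hi: float, cdf) -> Callable[[np.ndarray], np.ndarray]:
    """Restrict a quantile function to [lo, hi] by rescaling the uniform
    coordinate — strictly monotone, so rank couplings are untouched."""
    u_lo, u_hi = float(cdf(lo)), float(cdf(hi))

    def q(u: np.ndarray) -> np.ndarray:
        return ppf(u_lo + np.asarray(u) * (u_hi - u_lo))

    return q


def default_marginals(config: CohortConfig) -> list[Callable[[np.ndarray], np.ndarray]]:
    """Quantile functions for (volume mm³, elongation, core HU)."""
    mu_log, sd_log = config.volume_lognormal_params
    vol_dist = stats.lognorm(s=sd_log, scale=np.exp(mu_log))
    vol_q = _truncated_quantile(
        vol_dist.ppf, *config.volume_bounds_mm3, cdf=vol_dist.cdf
    )
    e_lo, e_hi = config.elongation_range

    def elong_q(u):
        return e_lo + np.asarray(u) * (e_hi - e_lo)

    ap = config.attenuation_params
    core_dist = stats.norm(loc=ap.core_hu_median, scale=ap.core_hu_sigma)
    core_q = _truncated_quantile(core_dist.ppf, *ap.core_hu_bounds, cdf=core_dist.cdf)
    return [vol_q, elong_q, core_q]


def _semi_axes_from(volume_mm3: float, elongation: float) -> tuple[float, float, float]:
    # a = e*c, b = sqrt(a*c): V = 4/3 π a b c = 4/3 π e^{3/2} c³
    c = (3.0 * volume_mm3 / (4.0 * np.pi * elongation**1.5)) ** (1.0 / 3.0)
    a = elongation * c
    b = float(np.sqrt(a * c))
    return float(a), float(b), float(c)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[AttenuationVolume], pd.DataFrame]:
    """Generate one attenuation volume per plaque plus a ground-truth table.

    Cluster counts follow ``cluster_count_probs``; per-cluster (volume,
    elongation, core HU) triples come from the Gaussian-copula sampler.
    Multi-cluster plaques receive clusters preferentially from the
    small-volume end of the SAME sampled population (selection weight
    decreasing with volume rank, exponent ``multi_size_bias``; the
    default 2.5 gives multi-cluster plaques a ~4.5x smaller median
    per-plaque mean cluster volume).  Because the
    sampled (volume, elongation, core) triples themselves are untouched,
    the planted cross-cluster couplings are preserved exactly while the
    single-versus-multi size contrast emerges from allocation — echoing
    the coalescence account of calcification growth, in which large
    single deposits arise from merged small ones.  Clusters within a
    plaque are placed with >= 2 voxels separation so the labeller
    resolves them.  Fully reproducible from ``config.seed``.
    """
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(config.seed)
    counts = rng.choice(
        np.arange(1, len(config.cluster_count_probs) + 1),
        size=config.n_plaques,
        p=np.asarray(config.cluster_count_probs, dtype=float),
    )
    n_total = int(counts.sum())
    params = sample_coupled_parameters(
        n_total, config.target_spearman, default_marginals(config), seed=rng
    )
    lobe_counts = rng.choice(
        np.arange(1, len(config.lobe_count_probs) + 1),
        size=n_total,
        p=np.asarray(config.lobe_count_probs, dtype=float),
    )

    # size-biased allocation of sampled clusters to multi-cluster plaques
    n_multi_slots = int(counts[counts >= 2].sum())
    vol_rank = stats.rankdata(params[:, 0])  # 1..n ascending
    weights = ((n_total - vol_rank + 0.5) / n_total) ** config.multi_size_bias
    if n_multi_slots > 0:
        multi_rows = rng.choice(
            n_total, size=n_multi_slots, replace=False, p=weights / weights.sum()
        )
    else:
        multi_rows = np.array([], dtype=int)
    single_rows = np.setdiff1d(np.arange(n_total), multi_rows)
    rng.shuffle(multi_rows)
    rng.shuffle(single_rows)
    multi_iter, single_iter = iter(multi_rows.tolist()), iter(single_rows.tolist())

    spacing = np.broadcast_to(np.asarray(config.voxel_spacing_mm, dtype=float), (3,))
    shape = np.asarray(config.grid_shape, dtype=int)
    extent = shape * spacing
    ap = config.attenuation_params

    volumes: list[AttenuationVolume] = []
    records: list[dict] = []
    width = max(3, len(str(config.n_plaques)))
    for p in range(config.n_plaques):
        k = int(counts[p])
        plaque_id = f"P{p + 1:0{width}d}"
        rows = [next(multi_iter) if k > 1 else next(single_iter) for _ in range(k)]
        cluster_params = params[rows]
        cluster_lobes = lobe_counts[rows]

        geometries = []
        for ci in range(k):
            vol_mm3, elong, core = cluster_params[ci]
            semi = _semi_axes_from(vol_mm3, elong)
            order = tuple(rng.permutation(3))
            geometries.append((semi, order, float(core), int(cluster_lobes[ci])))

        placed = _place_clusters(geometries, extent, spacing, config.lobe_offset_frac, rng)

        plaque_mask = np.zeros(tuple(shape), dtype=bool)
        ramp_hu = np.full(tuple(shape), float(ap.background_hu))
        for ci, ((semi, order, core, nl), center) in enumerate(zip(geometries, placed)):
            cluster = build_cluster_mask(
                semi,
                center,
                n_lobes=nl,
                lobe_offset_frac=config.lobe_offset_frac,
                grid_shape=tuple(shape),
                voxel_spacing_mm=tuple(spacing),
                seed=rng,
                axes_order=order,
            )
            if (plaque_mask & cluster.values).any():
                raise GeometryError("internal error: clusters overlap after placement")
            ramp = _depth_ramp(cluster.values, spacing)
            sel = cluster.values
            ramp_hu[sel] = ap.edge_hu + (core - ap.edge_hu) * ramp[sel]
            plaque_mask |= sel
            a, b, c = semi
            # realized volume of the built mask (includes lobes), not the
            # analytic primary-ellipsoid volume: recovery tests then measure
            # segmentation fidelity rather than voxelization error
            records.append(
                {
                    "plaque_id": plaque_id,
                    "cluster_id": ci + 1,
                    "true_volume_mm3": int(sel.sum()) * float(np.prod(spacing)),
                    "true_axis_a_mm": 2 * a,
                    "true_axis_b_mm": 2 * b,
                    "true_axis_c_mm": 2 * c,
                    "true_center_x_mm": center[0],
                    "true_center_y_mm": center[1],
                    "true_center_z_mm": center[2],
                    "true_core_hu": core,
                    "true_edge_hu": ap.edge_hu,
                    "n_lobes": nl,
                }
            )
        hu = ramp_hu
        if ap.noise_sd_hu > 0:
            hu = hu + rng.normal(0.0, ap.noise_sd_hu, size=tuple(shape))
        volumes.append(
            AttenuationVolume(
                values=hu, voxel_spacing_mm=tuple(spacing), origin_mm=(0.0, 0.0, 0.0)
            )
        )
    ground_truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    return volumes, ground_truth


def _place_clusters(geometries, extent, spacing, lobe_offset_frac, rng, max_tries=500):
    """Sample cluster centres so each fits the grid and surfaces are >= 2
    voxels apart (conservative bounding-sphere criterion)."""
    margin_sep = 2.0 * float(spacing.max())
    radii = []
    for semi, order, _core, nl in geometries:
        a = semi[0]
        reach = a * (1.0 + (lobe_offset_frac + 0.6 if nl > 1 else 0.0))
        radii.append(reach)
    for _attempt in range(max_tries):
        centers = []
        ok = True
        for reach in radii:
            lo = reach + 2.0 * spacing
            hi = extent - reach - 2.0 * spacing
            if np.any(hi <= lo):
                raise GeometryError(
                    "cluster too large for the grid; increase grid_shape or "
                    "tighten volume_bounds_mm3"
                )
            centers.append(rng.uniform(lo, hi))
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
                if gap < margin_sep:
                    ok = False
        if ok:
            return centers
    raise GeometryError(
        "could not place clusters with the required separation after "
        f"{max_tries} attempts; try a larger grid"
    )
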